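"""Volume, sidecar and configuration I/O.

Volumes are written as multi-page TIFF (one page per B-scan) or NIfTI,
always accompanied by a JSON metadata sidecar (``<volume file>.json``)
holding the full fan-beam description: angle grids, depth pixel pitch,
reference-arm stage position, protocol, geometry, seed and rendering
metadata.  The sidecar schema is versioned (``"schema_version": 1``)
and units are embedded in the field names.  Write -> read round-trips
are lossless for both backends.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from .eye_model import eye_from_config
from .protocol import ScanProtocol
from .scan_geometry import ScanGeometry
from .synthetic import FanVolume, Lesion, SyntheticScene

__all__ = [
    "FormatError",
    "write_volume",
    "read_volume",
    "load_config",
    "scene_from_config",
    "geometry_from_config",
    "protocol_from_config",
]

SCHEMA_VERSION = 1


class FormatError(RuntimeError):
    """Missing sidecar, schema mismatch, or inconsistent shapes."""


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def write_volume(vol: FanVolume, path: str | Path) -> tuple[Path, Path]:
    """Write a volume plus its JSON sidecar; the backend follows the
    extension (.tif/.tiff -> multi-page TIFF, .nii -> NIfTI).  Returns
    (volume path, sidecar path)."""
    path = Path(path)
    intensity = np.ascontiguousarray(vol.intensity, dtype=np.float32)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, intensity, photometric="minisblack")
    elif suffix == ".nii" or path.name.lower().endswith(".nii.gz"):
        import nibabel as nib

        nib.save(nib.Nifti1Image(intensity, np.eye(4)), str(path))
    else:
        raise FormatError(f"unsupported volume format {path.suffix!r}; use .tif or .nii")

    sidecar = _sidecar_path(path)
    doc = {
        "schema_version": SCHEMA_VERSION,
        "kind": vol.kind,
        "shape": list(intensity.shape),
        "dtype": str(intensity.dtype),
        "alpha_fast_deg": vol.alpha_fast_deg.tolist(),
        "alpha_slow_deg": vol.alpha_slow_deg.tolist(),
        "depth_pixel_pitch_um_optical": float(vol.depth_pixel_pitch_um),
        "reference_arm_position_mm": float(vol.reference_arm_position_mm),
        "seed": int(vol.seed),
        "protocol": _jsonable(asdict(vol.protocol)),
        "geometry": _jsonable(asdict(vol.geom)),
        "meta": _jsonable(vol.meta),
    }
    sidecar.write_text(json.dumps(doc, indent=1, sort_keys=True))
    return path, sidecar


def read_volume(path: str | Path) -> FanVolume:
    """Read a volume written by :func:`write_volume`; the sidecar must be
    present and consistent with the array shape."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing sidecar {sidecar}")
    try:
        doc = json.loads(sidecar.read_text())
    except json.JSONDecodeError as err:
        raise FormatError(f"corrupted sidecar {sidecar}: {err}") from err
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise FormatError(
            f"unsupported sidecar schema version {doc.get('schema_version')!r}"
        )

    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        intensity = np.asarray(tifffile.imread(path))
    elif suffix == ".nii" or path.name.lower().endswith(".nii.gz"):
        import nibabel as nib

        intensity = np.asarray(nib.load(str(path)).dataobj)
    else:
        raise FormatError(f"unsupported volume format {path.suffix!r}")

    if list(intensity.shape) != doc["shape"]:
        raise FormatError(
            f"array shape {intensity.shape} does not match sidecar {doc['shape']}"
        )
    protocol = ScanProtocol(**doc["protocol"])
    geom = ScanGeometry(**doc["geometry"])
    return FanVolume(
        intensity=intensity.astype(np.float32),
        alpha_fast_deg=np.asarray(doc["alpha_fast_deg"]),
        alpha_slow_deg=np.asarray(doc["alpha_slow_deg"]),
        depth_pixel_pitch_um=doc["depth_pixel_pitch_um_optical"],
        reference_arm_position_mm=doc["reference_arm_position_mm"],
        protocol=protocol,
        geom=geom,
        seed=doc["seed"],
        kind=doc["kind"],
        meta=doc["meta"],
    )


# ---------------------------------------------------------------------------
# configuration


def load_config(path: str | Path) -> dict:
    """Load a YAML (or JSON — YAML is a superset) run configuration."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise FormatError(f"config {path} must be a mapping")
    return doc


def geometry_from_config(block: dict, eye=None) -> ScanGeometry:
    """Geometry from a config block.

    Either explicit ``{radius_mm, pivot_offset_mm, fov_deg, medium_index}``
    or ``{pivot_at_iris: true, fov_deg}`` derived from the eye.
    """
    block = dict(block)
    fov = float(block.pop("fov_deg", 140.0))
    if block.pop("pivot_at_iris", False):
        if eye is None:
            raise FormatError("pivot_at_iris geometry needs an eye block")
        return ScanGeometry.for_eye(eye, pivot_at_iris=True, fov_deg=fov,
                                    medium_index=block.get("medium_index"))
    return ScanGeometry(
        radius_mm=float(block["radius_mm"]),
        pivot_offset_mm=float(block.get("pivot_offset_mm", 0.0)),
        pivot_half_angle_max_deg=fov / 2.0,
        medium_index=float(block.get("medium_index", 1.357)),
    )


def protocol_from_config(block: dict | None) -> ScanProtocol:
    if not block:
        return ScanProtocol.acquisition()
    return ScanProtocol(**block)


def scene_from_config(doc: dict) -> SyntheticScene:
    """Scene from a full run config (eye / geometry / scene blocks)."""
    eye = eye_from_config(doc.get("eye", {"preset": "gullstrand_newborn"}))
    geom = geometry_from_config(doc.get("geometry", {"pivot_at_iris": True}), eye=eye)
    sc = dict(doc.get("scene", {}))
    lesions = tuple(Lesion(**row) for row in sc.pop("lesions", []))
    layers = sc.pop("layers", None)
    if layers is not None:
        from .synthetic import Layer

        layers = tuple(Layer(**row) for row in layers)
    seed = int(doc.get("seed", sc.pop("seed", 0)))
    return SyntheticScene(eye=eye, geom=geom, layers=layers, lesions=lesions,
                          seed=seed, **sc)
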