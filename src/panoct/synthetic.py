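"""Seeded generator of fan-beam OCT volumes (retina, cornea, phantom).

Volumes carry the statistical structure the downstream biometry and
morphometry assume:

* layered reflectivity on a spherical retina — each layer is a
  concentric sphere at an optical depth offset below the inner surface;
* pivot-at-iris fan-beam sampling, uniform in galvanometer (pivot)
  angle on both axes;
* lesions as ellipsoidal caps elevating the whole layer stack inward
  (toward the pivot), with ground truth stored as normal height;
* depth-dependent sensitivity roll-off ``10**(-rolloff_db_per_mm * z / 10)``;
* fully developed speckle as multiplicative unit-mean exponential noise;
* a recorded reference-arm stage position that fixes where a given
  optical path appears on the depth axis:
  ``z_mm = OPL_from_apex + datum_offset - opl_factor * stage``.

The depth axis is *optical* path; geometric elevations are multiplied
by the medium index when rendered.  Identical ``(scene, protocol,
seed)`` produce bit-identical volumes; seeds are explicit fields, no
global random state is touched.

The autofocus hill-climbing search used during alignment lives here
too (:func:`autofocus_hill_climb`), operating on any scalar
image-brightness metric of the focus setting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .eye_model import SchematicEye
from .protocol import ScanProtocol
from .scan_geometry import (
    ScanGeometry,
    chord_length,
    phantom_ring_angles,
    ray_direction,
    required_imaging_depth,
)

__all__ = [
    "Layer",
    "Lesion",
    "SyntheticScene",
    "FanVolume",
    "default_layers",
    "generate_retina_volume",
    "generate_cornea_volume",
    "generate_phantom_volume",
    "en_face_projection",
    "autofocus_hill_climb",
    "reference_arm_for_surface_depth",
]

SPECKLE_MODES = ("none", "multiplicative-exponential")


@dataclass(frozen=True)
class Layer:
    """Retinal layer: optical depth offset (um) below the inner surface
    and reflectivity in arbitrary linear units."""

    name: str
    offset_um_optical: float
    reflectivity: float

    def __post_init__(self) -> None:
        if self.offset_um_optical < 0:
            raise ValueError("layer offsets are measured downward, must be >= 0")
        if self.reflectivity < 0:
            raise ValueError("reflectivity must be >= 0")


@dataclass(frozen=True)
class Lesion:
    """Ellipsoidal-cap lesion on the spherical retina.

    Positioned by the central angle of its apex from the posterior pole
    and an azimuth about the visual axis.  ``length_mm >= width_mm`` are
    geodesic extents along the principal surface axes (length along the
    meridian by default, rotated by ``orientation_deg`` in the tangent
    plane); ``height_mm`` is the maximum elevation along the local
    surface normal, pointing inward (toward the pivot).
    """

    center_central_angle_deg: float
    azimuth_deg: float
    length_mm: float
    width_mm: float
    height_mm: float
    orientation_deg: float = 0.0
    profile: str = "ellipsoidal-cap"

    def __post_init__(self) -> None:
        if not self.width_mm > 0 or self.length_mm < self.width_mm:
            raise ValueError("lesion extents must satisfy length >= width > 0")
        if not self.height_mm > 0:
            raise ValueError("lesion height must be > 0")
        if self.profile != "ellipsoidal-cap":
            raise ValueError(f"unknown lesion profile {self.profile!r}")


def default_layers(eye: SchematicEye) -> tuple[Layer, ...]:
    """Three-layer reflectivity stack for a schematic eye: inner surface
    (ILM), a mid-retina band, and the RPE — the brightest layer — at the
    optical depth given by the eye's retinal segment."""
    rt = [s for s in eye.segments if s.name == "RT"]
    rpe_um = (rt[0].opl_mm if rt else 0.15 * 1.346) * 1000.0
    return (
        Layer("ILM", 0.0, 0.40),
        Layer("mid", rpe_um / 2.0, 0.25),
        Layer("RPE", rpe_um, 1.0),
    )


@dataclass(frozen=True)
class SyntheticScene:
    """Scene description consumed by the generators.

    The default noise settings model a realistic clinical acquisition
    (fully developed speckle over a -30 dB incoherent floor with a mild
    0.5 dB/mm sensitivity roll-off); set ``speckle_mode="none"``,
    ``rolloff_db_per_mm=0`` for noiseless geometry studies.
    """

    eye: SchematicEye
    geom: ScanGeometry
    layers: tuple[Layer, ...] | None = None
    lesions: tuple[Lesion, ...] = ()
    speckle_mode: str = "multiplicative-exponential"
    rolloff_db_per_mm: float = 0.5
    noise_floor: float = 1e-3
    seed: int = 0
    datum_offset_mm: float = 1.0  # image depth of zero apex-referenced OPL at stage 0
    opl_factor: float = 1.0  # stage travel (mm) -> OPL (mm)

    def __post_init__(self) -> None:
        if self.speckle_mode not in SPECKLE_MODES:
            raise ValueError(f"speckle_mode must be one of {SPECKLE_MODES}")
        if self.rolloff_db_per_mm < 0 or self.noise_floor < 0:
            raise ValueError("rolloff and noise floor must be >= 0")

    @property
    def layer_stack(self) -> tuple[Layer, ...]:
        return self.layers if self.layers is not None else default_layers(self.eye)


@dataclass
class FanVolume:
    """3-D OCT intensity in fan-beam coordinates.

    ``intensity`` is indexed ``(slow angle, fast angle, depth sample)``
    and matches the protocol shape ``(n_bscans, n_ascans_per_bscan,
    samples_per_ascan)``.  ``meta`` holds the sidecar metadata,
    including ``pivot_opl_at_zero_depth_mm`` (the constant O0 such that
    a scatterer at chord distance t from the pivot appears at depth
    ``z_mm = medium_index * t - O0``), the recorded noise floor and any
    rendering warnings.
    """

    intensity: np.ndarray
    alpha_fast_deg: np.ndarray
    alpha_slow_deg: np.ndarray
    depth_pixel_pitch_um: float
    reference_arm_position_mm: float
    protocol: ScanProtocol
    geom: ScanGeometry
    seed: int
    kind: str = "retina"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = (
            self.protocol.n_bscans,
            self.protocol.n_ascans_per_bscan,
            self.protocol.samples_per_ascan,
        )
        if tuple(self.intensity.shape) != expected:
            raise ValueError(
                f"intensity shape {self.intensity.shape} does not match protocol {expected}"
            )
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")

    @property
    def n_depth(self) -> int:
        return self.intensity.shape[2]

    @property
    def depth_window_mm(self) -> float:
        return self.n_depth * self.depth_pixel_pitch_um / 1000.0


# ---------------------------------------------------------------------------
# geometry helpers


def _angle_grid(half_angle_deg: float, n: int) -> np.ndarray:
    if n == 1:
        return np.zeros(1)
    return np.linspace(-half_angle_deg, half_angle_deg, n)


def _solve_ray_t(a: float, dz, rho) -> np.ndarray:
    """Distance along a unit ray from the pivot (0,0,a) to the sphere of
    radius rho about the origin; dz is the ray direction's z component."""
    disc = (a * dz) ** 2 + rho * rho - a * a
    return -a * dz + np.sqrt(np.maximum(disc, 0.0))


def _lesion_frame(lesion: Lesion) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Apex direction and tangent axes (length axis, width axis)."""
    b = math.radians(lesion.center_central_angle_deg)
    p = math.radians(lesion.azimuth_deg)
    c = np.array([math.sin(b) * math.cos(p), math.sin(b) * math.sin(p), -math.cos(b)])
    e_beta = np.array([math.cos(b) * math.cos(p), math.cos(b) * math.sin(p), math.sin(b)])
    e_phi = np.array([-math.sin(p), math.cos(p), 0.0])
    o = math.radians(lesion.orientation_deg)
    e1 = math.cos(o) * e_beta + math.sin(o) * e_phi
    e2 = -math.sin(o) * e_beta + math.cos(o) * e_phi
    return c, e1, e2


def lesion_elevation(lesions, u: np.ndarray, radius_mm: float) -> np.ndarray:
    """Inward elevation (mm) at unit surface directions ``u`` (..., 3).

    Each lesion contributes an ellipsoidal cap
    ``h * sqrt(1 - (x/L2)**2 - (y/W2)**2)`` in geodesic tangent
    coordinates (x, y) about its apex on the sphere of ``radius_mm``.
    """
    e = np.zeros(u.shape[:-1])
    for les in lesions:
        c, e1, e2 = _lesion_frame(les)
        cosp = np.clip(u @ c, -1.0, 1.0)
        psi = np.arccos(cosp)
        t = u - cosp[..., None] * c
        tn = np.linalg.norm(t, axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            tw = np.where(tn[..., None] > 0, t / np.maximum(tn, 1e-300)[..., None], 0.0)
        s = radius_mm * psi  # geodesic distance from the apex
        x = s * (tw @ e1)
        y = s * (tw @ e2)
        q = 1.0 - (x / (les.length_mm / 2.0)) ** 2 - (y / (les.width_mm / 2.0)) ** 2
        e += les.height_mm * np.sqrt(np.clip(q, 0.0, None))
    return e


def _intersect_elevated(geom: ScanGeometry, D: np.ndarray, rho: float,
                        lesions, ref_radius: float) -> np.ndarray:
    """Chord distance from the pivot to the layer sphere of radius ``rho``
    displaced inward by the lesion field.

    The elevation is looked up where the ray meets the undeformed layer
    sphere and applied *along the ray* with exact radial magnitude (the
    chord is re-solved for radius ``rho - e``), so the rendered sample
    sits exactly ``e`` above the sphere.  No self-occlusion is modelled
    — at oblique incidence a steep-rimmed cap would shadow its far
    flank, and shadow artifacts are outside the generator's scope — so
    the footprint boundary stays exact at every scan angle while
    interior samples are advected slightly toward the pivot.
    """
    a = geom.pivot_offset_mm
    dz = D[..., 2]
    t = _solve_ray_t(a, dz, rho)
    if not lesions:
        return t
    P = np.array([0.0, 0.0, a])
    pts = P + t[..., None] * D
    u = pts / np.linalg.norm(pts, axis=-1, keepdims=True)
    e = lesion_elevation(lesions, u, ref_radius)
    return _solve_ray_t(a, dz, rho - e)


# ---------------------------------------------------------------------------
# rendering core


def _deposit(vol: np.ndarray, z_mm: np.ndarray, weight, pitch_um: float,
             rolloff_db_per_mm: float) -> int:
    """Splat one surface into the volume with linear (two-pixel) axial
    interpolation and sensitivity roll-off.  Returns the number of
    A-scans whose surface fell outside the depth window."""
    nz = vol.shape[2]
    w = np.broadcast_to(np.asarray(weight, dtype=float), z_mm.shape).copy()
    if rolloff_db_per_mm > 0:
        w = w * 10.0 ** (-rolloff_db_per_mm * np.clip(z_mm, 0.0, None) / 10.0)
    idx = z_mm * 1000.0 / pitch_um
    i0 = np.floor(idx).astype(np.int64)
    frac = idx - i0
    ok = (i0 >= 0) & (i0 < nz - 1)
    ns, nf = z_mm.shape
    rows = (np.arange(ns)[:, None] * nf + np.arange(nf)[None, :]) * nz
    flat = vol.reshape(-1)
    np.add.at(flat, (rows + i0)[ok], (w * (1.0 - frac))[ok])
    np.add.at(flat, (rows + i0 + 1)[ok], (w * frac)[ok])
    return int(np.count_nonzero(~ok))


def _apply_noise(vol: np.ndarray, speckle_mode: str, noise_floor: float,
                 seed: int) -> None:
    """Multiplicative exponential speckle plus noise floor, in place.

    With speckle enabled the floor also fluctuates exponentially (an
    incoherent background); without it a constant pedestal is added.
    One B-scan at a time to bound the temporary-array footprint.
    """
    rng = np.random.default_rng(seed)
    if speckle_mode == "multiplicative-exponential":
        for s in range(vol.shape[0]):
            sl = vol[s]
            sl *= rng.exponential(1.0, size=sl.shape)
            if noise_floor > 0:
                sl += noise_floor * rng.exponential(1.0, size=sl.shape)
    elif noise_floor > 0:
        vol += noise_floor


def _base_meta(scene_like: dict, O0: float, warnings: list[str]) -> dict:
    meta = {"schema_version": 1, "pivot_opl_at_zero_depth_mm": float(O0),
            "warnings": list(warnings)}
    meta.update(scene_like)
    return meta


# ---------------------------------------------------------------------------
# generators


def generate_retina_volume(scene: SyntheticScene, protocol: ScanProtocol,
                           reference_arm_position_mm: float,
                           depth_pixel_pitch_um: float = 5.0) -> FanVolume:
    """Render a retina volume in fan-beam coordinates.

    Layer k is a sphere concentric with the eye at geometric radius
    ``r + offset_um / (1000 * n)`` (deeper layers farther from the
    centre), deformed inward by the scene's lesions.  The depth at which
    a surface point at chord distance t from the pivot appears is

        z_mm = n * t - O0,
        O0   = opl_factor * stage + n * L(0) - datum_offset - OPL_ILM,

    so the central inner-surface A-scan lands at
    ``datum_offset + OPL_ILM - opl_factor * stage`` — consistent with the
    cornea generator, which anchors zero apex-referenced OPL at
    ``datum_offset`` for stage 0.  A warning is recorded when the
    required imaging depth (plus the layer stack) exceeds the depth
    window.
    """
    geom = scene.geom
    n = geom.medium_index
    r = geom.radius_mm
    af = _angle_grid(geom.pivot_half_angle_max_deg, protocol.n_ascans_per_bscan)
    as_ = _angle_grid(geom.pivot_half_angle_max_deg, protocol.n_bscans)
    D = ray_direction(af[None, :], as_[:, None])

    opl_ilm = scene.eye.opl_mm(include_retina=False)
    L0 = chord_length(geom, 0.0)
    O0 = (scene.opl_factor * reference_arm_position_mm + n * L0
          - scene.datum_offset_mm - opl_ilm)

    layers = scene.layer_stack
    # lesion footprints are defined on the outermost (RPE) layer sphere,
    # the surface morphometry measures on; inner layers share the same
    # angular footprint
    ref_radius = r + max(l.offset_um_optical for l in layers) / 1000.0 / n
    window_mm = protocol.samples_per_ascan * depth_pixel_pitch_um / 1000.0
    warnings: list[str] = []
    span = required_imaging_depth(geom)[1] + max(l.offset_um_optical for l in layers) / 1000.0
    if span > window_mm:
        warnings.append(
            f"required imaging depth {span:.2f} mm exceeds the {window_mm:.2f} mm window; "
            "peripheral retina may be clipped"
        )

    vol = np.zeros((protocol.n_bscans, protocol.n_ascans_per_bscan,
                    protocol.samples_per_ascan))
    dropped = 0
    for layer in layers:
        rho = r + layer.offset_um_optical / 1000.0 / n
        t = _intersect_elevated(geom, D, rho, scene.lesions, ref_radius)
        z = n * t - O0
        dropped += _deposit(vol, z, layer.reflectivity, depth_pixel_pitch_um,
                            scene.rolloff_db_per_mm)
    if dropped and not warnings:
        warnings.append(f"{dropped} surface samples fell outside the depth window")
    _apply_noise(vol, scene.speckle_mode, scene.noise_floor, scene.seed)

    meta = _base_meta(
        {
            "noise_floor": scene.noise_floor,
            "speckle_mode": scene.speckle_mode,
            "rolloff_db_per_mm": scene.rolloff_db_per_mm,
            "datum_offset_mm": scene.datum_offset_mm,
            "opl_factor": scene.opl_factor,
            "opl_ilm_mm": opl_ilm,
            "surface_depth_center_mm": scene.datum_offset_mm + opl_ilm
            - scene.opl_factor * reference_arm_position_mm,
            "layer_offsets_um": [l.offset_um_optical for l in layers],
            "fovea_index": (protocol.n_bscans // 2, protocol.n_ascans_per_bscan // 2),
        },
        O0, warnings)
    return FanVolume(vol.astype(np.float32), af, as_, depth_pixel_pitch_um,
                     reference_arm_position_mm, protocol, geom, scene.seed,
                     kind="retina", meta=meta)


def generate_cornea_volume(scene: SyntheticScene, protocol: ScanProtocol,
                           reference_arm_position_mm: float,
                           depth_pixel_pitch_um: float = 5.0,
                           corneal_sag_mm: float = 0.25,
                           reflectivity: float = 1.0) -> FanVolume:
    """Render the anterior-segment (cornea) volume for the P1 biometry arm.

    A single bright convex surface whose apex — the minimum-depth A-scan
    at the scan centre — sits at ``datum_offset - opl_factor * stage``,
    i.e. the apex-referenced OPL origin.  Moving the stage by ds shifts
    the apex by exactly ``opl_factor * ds``.
    """
    geom = scene.geom
    af = _angle_grid(geom.pivot_half_angle_max_deg, protocol.n_ascans_per_bscan)
    as_ = _angle_grid(geom.pivot_half_angle_max_deg, protocol.n_bscans)
    z_apex = scene.datum_offset_mm - scene.opl_factor * reference_arm_position_mm
    a_norm = geom.pivot_half_angle_max_deg
    sag = corneal_sag_mm * ((af[None, :] / a_norm) ** 2 + (as_[:, None] / a_norm) ** 2)
    z = z_apex + sag

    vol = np.zeros((protocol.n_bscans, protocol.n_ascans_per_bscan,
                    protocol.samples_per_ascan))
    warnings: list[str] = []
    dropped = _deposit(vol, z, reflectivity, depth_pixel_pitch_um,
                       scene.rolloff_db_per_mm)
    if dropped:
        warnings.append(f"{dropped} corneal surface samples fell outside the depth window")
    _apply_noise(vol, scene.speckle_mode, scene.noise_floor, scene.seed)

    meta = _base_meta(
        {
            "noise_floor": scene.noise_floor,
            "speckle_mode": scene.speckle_mode,
            "rolloff_db_per_mm": scene.rolloff_db_per_mm,
            "datum_offset_mm": scene.datum_offset_mm,
            "opl_factor": scene.opl_factor,
            "apex_depth_mm": z_apex,
        },
        float("nan"), warnings)
    return FanVolume(vol.astype(np.float32), af, as_, depth_pixel_pitch_um,
                     reference_arm_position_mm, protocol, geom, scene.seed,
                     kind="cornea", meta=meta)


def generate_phantom_volume(phantom_radius_mm: float, ring_interval_deg: float,
                            ring_height_mm: float, geom: ScanGeometry,
                            protocol: ScanProtocol,
                            depth_pixel_pitch_um: float = 18.0,
                            ring_width_deg: float = 3.0,
                            ring_boost: float = 1.0,
                            rolloff_db_per_mm: float = 1.0,
                            noise_floor: float = 1e-3,
                            speckle_mode: str = "none",
                            seed: int = 0,
                            n_rings: int = 7) -> FanVolume:
    """Render the FOV-calibration phantom: a sphere with circular rings
    extruded inward at fixed central-angle intervals.

    Ring k sits at central half-angle ``k * ring_interval / 2`` (adjacent
    rings ``ring_interval`` apart measured from the phantom centre C);
    its elevation and reflectivity boost make it stand out in the
    en-face projection at the pivot-angle radius predicted by
    :func:`panoct.scan_geometry.phantom_ring_angles`.
    """
    pg = replace(geom, radius_mm=phantom_radius_mm,
                 pivot_offset_mm=min(geom.pivot_offset_mm, phantom_radius_mm))
    rings, omitted = phantom_ring_angles(phantom_radius_mm, ring_interval_deg,
                                         pg, n_rings=n_rings)
    n = pg.medium_index
    af = _angle_grid(pg.pivot_half_angle_max_deg, protocol.n_ascans_per_bscan)
    as_ = _angle_grid(pg.pivot_half_angle_max_deg, protocol.n_bscans)
    D = ray_direction(af[None, :], as_[:, None])

    a = pg.pivot_offset_mm
    P = np.array([0.0, 0.0, a])
    t = _solve_ray_t(a, D[..., 2], phantom_radius_mm)
    pts = P + t[..., None] * D
    u = pts / np.linalg.norm(pts, axis=-1, keepdims=True)
    beta = np.rad2deg(np.arccos(np.clip(-u[..., 2], -1.0, 1.0)))

    elev = np.zeros_like(beta)
    for ring in rings:
        if ring.ring_index == 0:
            continue
        d = np.abs(beta - ring.central_angle_deg)
        inside = d < ring_width_deg / 2.0
        elev = np.where(
            inside,
            np.maximum(elev, ring_height_mm
                       * np.cos(np.pi * d / ring_width_deg) ** 2),
            elev,
        )
    refl = 1.0 + ring_boost * (elev > 0)

    # iterate the ray onto the extruded surface
    for _ in range(3):
        t = _solve_ray_t(a, D[..., 2], phantom_radius_mm - elev)
        pts = P + t[..., None] * D
        u = pts / np.linalg.norm(pts, axis=-1, keepdims=True)
        beta = np.rad2deg(np.arccos(np.clip(-u[..., 2], -1.0, 1.0)))

    L0 = chord_length(pg, 0.0)
    depth_span = required_imaging_depth(pg)[1] + n * ring_height_mm
    z_center = depth_span + 0.5
    O0 = n * L0 - z_center
    z = n * t - O0

    vol = np.zeros((protocol.n_bscans, protocol.n_ascans_per_bscan,
                    protocol.samples_per_ascan))
    warnings: list[str] = []
    window_mm = protocol.samples_per_ascan * depth_pixel_pitch_um / 1000.0
    if z_center + 0.5 > window_mm:
        warnings.append(
            f"phantom depth span {z_center:.2f} mm exceeds the {window_mm:.2f} mm window"
        )
    _deposit(vol, z, refl, depth_pixel_pitch_um, rolloff_db_per_mm)
    _apply_noise(vol, speckle_mode, noise_floor, seed)

    meta = _base_meta(
        {
            "noise_floor": noise_floor,
            "speckle_mode": speckle_mode,
            "rolloff_db_per_mm": rolloff_db_per_mm,
            "phantom_radius_mm": phantom_radius_mm,
            "ring_interval_deg": ring_interval_deg,
            "ring_height_mm": ring_height_mm,
            "rings": [tuple(r) for r in rings],
            "rings_omitted": [(r.ring_index, r.central_angle_deg) for r in omitted],
            "surface_depth_center_mm": z_center,
        },
        O0, warnings)
    return FanVolume(vol.astype(np.float32), af, as_, depth_pixel_pitch_um, 0.0,
                     protocol, pg, seed, kind="phantom", meta=meta)


def reference_arm_for_surface_depth(scene: SyntheticScene, target_depth_mm: float,
                                    surface: str = "retina") -> float:
    """Stage position placing the chosen surface at a target image depth.

    ``surface="cornea"`` targets the corneal apex (zero apex-referenced
    OPL); ``surface="retina"`` targets the central inner retinal surface
    (apex-referenced OPL = OPL to the ILM).
    """
    opl = 0.0 if surface == "cornea" else scene.eye.opl_mm(include_retina=False)
    return (scene.datum_offset_mm + opl - target_depth_mm) / scene.opl_factor


# ---------------------------------------------------------------------------
# en-face projection and autofocus


def en_face_projection(vol: FanVolume, method: str = "mean") -> np.ndarray:
    """Reduce a volume over depth into a 2-D en-face image in angle
    coordinates, shape ``(n_bscans, n_ascans_per_bscan)``."""
    if method == "mean":
        return vol.intensity.mean(axis=2)
    if method == "max":
        return vol.intensity.max(axis=2)
    raise ValueError(f"unknown projection method {method!r}; use 'mean' or 'max'")


def autofocus_hill_climb(metric, start: float, step: float,
                         max_iter: int = 100, tol: float = 1e-3,
                         bounds: tuple[float, float] | None = None) -> float:
    """Classic hill-climbing autofocus over a scalar brightness metric.

    Steps in the improving direction, reverses and halves the step on a
    metric decrease, and stops when the step drops below ``tol`` or
    ``max_iter`` evaluations are spent.  For a unimodal metric the
    result lies within the final step of the argmax.
    """
    if not step > 0:
        raise ValueError("step must be > 0")

    def _eval(x: float) -> float:
        v = float(metric(x))
        if not math.isfinite(v):
            raise ValueError(f"autofocus metric returned a non-finite value at {x}")
        return v

    def _clamp(x: float) -> float:
        if bounds is not None:
            return min(max(x, bounds[0]), bounds[1])
        return x

    x = _clamp(start)
    fx = _eval(x)
    direction = 1.0
    for _ in range(max_iter):
        if step < tol:
            break
        xn = _clamp(x + direction * step)
        if xn == x:  # pinned at a bound
            direction = -direction
            step /= 2.0
            continue
        fn = _eval(xn)
        if fn > fx:
            x, fx = xn, fn
        else:
            direction = -direction
            step /= 2.0
    return x
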