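"""Ideal-sphere scan geometry for pivot-scanned wide-field OCT.

The eyeball is modelled as a sphere of radius ``r`` centred at C (the
origin).  The posterior pole sits at axial coordinate ``-r`` and the
scanning pivot P at ``+a`` on the axis (``a`` = ``pivot_offset_mm``,
0 <= a <= r).  A ray leaving P at half-angle ``alpha`` from the
posterior direction meets the sphere after a chord

    L(alpha) = a*cos(alpha) + sqrt(r**2 - a**2 * sin(alpha)**2).

Two field-of-view conventions coexist in wide-field imaging and are
kept explicit throughout:

* *pivot convention* (this instrument): the full angle ``theta = 2*alpha_max``
  swept by the beam about P — "FOV" unqualified means this one;
* *centre convention* (Optos / RetCam): the angle ``beta`` subtended at C
  by the imaged retina; ``beta_half = central_angle(geom, alpha)``.

For a pivot on the sphere (a = r) the inscribed-angle theorem gives
``beta_half = 2*alpha`` exactly, which is why a contact probe pivoting
on the iris plane nearly doubles the centre-referenced field.

Angles are degrees at every public interface (radians internally);
lengths are mm.  All operations are vectorised over the angle argument.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ScanGeometry",
    "RetinaHit",
    "RingAngle",
    "chord_length",
    "central_angle",
    "pivot_angle_for_central_angle",
    "required_imaging_depth",
    "bscan_depth_profile",
    "vignetting_limit",
    "phantom_ring_angles",
    "ray_direction",
    "retina_hit",
]

#: anterior chamber reach (corneal thickness + anterior chamber depth) of the
#: newborn schematic eye, used to place the pivot on the iris plane by default
_NEWBORN_IRIS_DEPTH_MM = 0.75 + 1.85


@dataclass(frozen=True)
class ScanGeometry:
    """Spherical-eye scan geometry.

    Parameters
    ----------
    radius_mm:
        Sphere (eye or phantom) radius ``r``.
    pivot_offset_mm:
        Distance ``a`` of the scanning pivot P anterior of the centre C
        along the visual axis; ``a = 0`` puts the pivot at C (desktop
        convention), ``a = r`` on the sphere surface.
    pivot_half_angle_max_deg:
        Largest pivot half-angle ``alpha_max`` the scanner reaches;
        the (pivot-convention) FOV is ``2 * alpha_max``.
    medium_index:
        Mean refractive index used to convert geometric depth to the
        optical depth the OCT image records.
    """

    radius_mm: float
    pivot_offset_mm: float
    pivot_half_angle_max_deg: float = 70.0
    medium_index: float = 1.357

    def __post_init__(self) -> None:
        if not self.radius_mm > 0:
            raise ValueError(f"radius must be > 0, got {self.radius_mm}")
        if not 0 <= self.pivot_offset_mm <= self.radius_mm:
            raise ValueError(
                "pivot offset must satisfy 0 <= a <= r, got "
                f"a={self.pivot_offset_mm}, r={self.radius_mm}"
            )
        if not 0 < self.pivot_half_angle_max_deg < 90:
            raise ValueError(
                f"pivot half-angle max must lie in (0, 90) deg, got {self.pivot_half_angle_max_deg}"
            )
        if not self.medium_index >= 1:
            raise ValueError(f"medium index must be >= 1, got {self.medium_index}")

    @property
    def fov_deg(self) -> float:
        """Pivot-convention field of view, ``theta = 2 * alpha_max``."""
        return 2.0 * self.pivot_half_angle_max_deg

    @property
    def pivot_point(self) -> np.ndarray:
        return np.array([0.0, 0.0, self.pivot_offset_mm])

    @classmethod
    def for_eye(cls, eye, pivot_at_iris: bool = True, fov_deg: float = 140.0,
                medium_index: float | None = None) -> "ScanGeometry":
        """Geometry for a schematic eye: ``r`` = half the axial length; by
        default the pivot sits on the iris plane, ``a = r - (CT + ACD)``."""
        r = eye.total_length_mm / 2.0
        if pivot_at_iris:
            iris = sum(
                s.thickness_mm for s in eye.segments if s.name in ("CT", "ACD")
            ) or _NEWBORN_IRIS_DEPTH_MM
            a = max(r - iris, 0.0)
        else:
            a = 0.0
        n = eye.n_avg if medium_index is None else medium_index
        return cls(r, a, fov_deg / 2.0, n)


class RetinaHit(NamedTuple):
    """Ray/retina intersection for one pivot half-angle."""

    pivot_half_angle_deg: float
    chord_length_mm: float
    central_angle_deg: float
    point_mm: np.ndarray  # 3-D, in the meridional plane y = 0


class RingAngle(NamedTuple):
    """One phantom calibration ring."""

    ring_index: int
    central_angle_deg: float
    pivot_half_angle_deg: float


def _chord(r: float, a: float, alpha_rad) -> np.ndarray:
    s = a * np.sin(alpha_rad)
    return a * np.cos(alpha_rad) + np.sqrt(r * r - s * s)


def chord_length(geom: ScanGeometry, alpha_deg) -> np.ndarray | float:
    """Chord length L(alpha) from the pivot to the retina, mm.

    ``L(0) = a + r``; for ``a > 0`` L decreases monotonically on
    [0, 90] deg.  Accepts scalars or arrays, |alpha| <= 180 deg.
    """
    alpha = np.asarray(alpha_deg, dtype=float)
    if np.any(np.abs(alpha) > 180):
        raise ValueError("pivot half-angle must satisfy |alpha| <= 180 deg")
    out = _chord(geom.radius_mm, geom.pivot_offset_mm, np.deg2rad(alpha))
    return float(out) if out.ndim == 0 else out


def central_angle(geom: ScanGeometry, alpha_deg) -> np.ndarray | float:
    """Centre-referenced half-angle beta_half reached at pivot half-angle alpha.

    ``cos(beta_half) = (L*cos(alpha) - a) / r`` — the angle at C between the
    hit point and the posterior pole.  ``beta_half >= alpha`` with equality
    iff the pivot is at the centre (a = 0); for a = r, ``beta_half = 2*alpha``.
    """
    alpha = np.asarray(alpha_deg, dtype=float)
    if np.any(np.abs(alpha) > 180):
        raise ValueError("pivot half-angle must satisfy |alpha| <= 180 deg")
    rad = np.deg2rad(np.abs(alpha))
    L = _chord(geom.radius_mm, geom.pivot_offset_mm, rad)
    c = (L * np.cos(rad) - geom.pivot_offset_mm) / geom.radius_mm
    out = np.rad2deg(np.arccos(np.clip(c, -1.0, 1.0)))
    return float(out) if out.ndim == 0 else out


def pivot_angle_for_central_angle(geom: ScanGeometry, beta_half_deg: float) -> float:
    """Pivot half-angle producing a given centre-referenced half-angle.

    Inverse of :func:`central_angle` on [0, 90] deg pivot angle, solved by
    bracketed root finding to < 1e-9 deg.  Raises if ``beta_half`` exceeds
    the largest reachable central angle (at alpha = 90 deg).
    """
    if beta_half_deg < 0:
        raise ValueError("central half-angle must be >= 0")
    beta_max = central_angle(geom, 90.0)
    if beta_half_deg > beta_max + 1e-12:
        raise ValueError(
            f"central half-angle {beta_half_deg:.6g} deg unreachable; "
            f"maximum for this geometry is {beta_max:.6g} deg (at alpha = 90 deg)"
        )
    if beta_half_deg == 0:
        return 0.0

    def f(alpha):
        return central_angle(geom, alpha) - beta_half_deg

    hi = min(90.0, beta_half_deg) if geom.pivot_offset_mm > 0 else beta_half_deg
    # beta >= alpha always, so alpha = beta is an upper bracket (f(hi) >= 0)
    if f(hi) < 0:  # pragma: no cover - only if beta_half ~ beta_max numerically
        hi = 90.0
    return float(brentq(f, 0.0, hi, xtol=1e-12, rtol=8.9e-16))


def required_imaging_depth(geom: ScanGeometry) -> tuple[float, float]:
    """Axial depth needed to hold the whole retina in one B-scan.

    Geometric value ``max_{|alpha| <= alpha_max} (L(0) - L(alpha))``
    (the central-vs-peripheral chord difference) and its optical
    counterpart (times ``medium_index``).  Zero when the pivot is at the
    centre; non-decreasing in both ``a`` and ``alpha_max``.
    """
    # L is monotone non-increasing in |alpha| on [0, 90], so the maximum
    # difference is attained at alpha_max (verified against a dense grid
    # in the tests).
    L0 = chord_length(geom, 0.0)
    geo = L0 - chord_length(geom, geom.pivot_half_angle_max_deg)
    geo = max(geo, 0.0)
    return geo, geo * geom.medium_index


def bscan_depth_profile(geom: ScanGeometry, alphas_deg) -> np.ndarray:
    """Optical depth displacement of the retina across a B-scan.

    ``(L(0) - L(alpha)) * medium_index`` per pivot half-angle — the curve
    the retina traces relative to the central A-scan.  Symmetric in
    ``+/-alpha``; its maximum equals the optical
    :func:`required_imaging_depth` when evaluated out to ``alpha_max``.
    """
    alphas = np.asarray(alphas_deg, dtype=float)
    if np.any(np.abs(alphas) > geom.pivot_half_angle_max_deg + 1e-9):
        raise ValueError("angles exceed the geometry's pivot half-angle maximum")
    L0 = chord_length(geom, 0.0)
    return (L0 - _chord(geom.radius_mm, geom.pivot_offset_mm,
                        np.deg2rad(np.abs(alphas)))) * geom.medium_index


def vignetting_limit(geom: ScanGeometry, iris_plane_offset_mm: float,
                     pupil_radius_mm: float) -> float:
    """Largest pivot half-angle (deg) whose ray clears the pupil.

    The iris plane sits ``iris_plane_offset_mm`` anterior of C; a ray from
    the pivot crosses it at transverse distance ``|a - h| * tan(alpha)``,
    so vignetting starts at ``alpha = arctan(pupil_radius / |a - h|)``.
    Returns ``alpha_max`` (no vignetting inside the scan range) when the
    pivot lies on the iris plane or the limit exceeds the scan range.
    """
    if not pupil_radius_mm > 0:
        raise ValueError("pupil radius must be > 0")
    gap = abs(geom.pivot_offset_mm - iris_plane_offset_mm)
    if gap == 0:
        return geom.pivot_half_angle_max_deg
    alpha_v = np.rad2deg(np.arctan(pupil_radius_mm / gap))
    return float(min(alpha_v, geom.pivot_half_angle_max_deg))


def phantom_ring_angles(phantom_radius_mm: float, ring_interval_deg: float,
                        geom: ScanGeometry, n_rings: int = 7,
                        ) -> tuple[list[RingAngle], list[RingAngle]]:
    """Calibration-ring table for a spherical phantom eye.

    Ring ``k`` (k = 0 .. n_rings; 0 is the posterior-pole mark) lies at
    central half-angle ``k * ring_interval/2`` — adjacent rings are
    ``ring_interval`` apart measured from the phantom centre across both
    hemi-meridians.  Each ring is mapped to the pivot half-angle at which
    it appears in the scan.  Returns ``(rings, omitted)`` where
    ``omitted`` lists rings beyond the reachable field (pivot angle NaN).
    """
    if not ring_interval_deg > 0:
        raise ValueError("ring interval must be > 0")
    pg = replace(geom, radius_mm=phantom_radius_mm,
                 pivot_offset_mm=min(geom.pivot_offset_mm, phantom_radius_mm))
    beta_reach = central_angle(pg, pg.pivot_half_angle_max_deg)
    rings: list[RingAngle] = []
    omitted: list[RingAngle] = []
    for k in range(0, n_rings + 1):
        beta = k * ring_interval_deg / 2.0
        if beta <= beta_reach + 1e-12:
            alpha = pivot_angle_for_central_angle(pg, beta)
            rings.append(RingAngle(k, beta, alpha))
        else:
            omitted.append(RingAngle(k, beta, float("nan")))
    return rings, omitted


def ray_direction(alpha_fast_deg, alpha_slow_deg) -> np.ndarray:
    """Unit ray direction for a two-axis pivot scan.

    Fast and slow galvanometer angles compose as orthogonal rotations of
    the posterior direction (0, 0, -1):

        D = (sin af, cos af * sin as, -cos af * cos as)

    The effective half-angle from the axis obeys
    ``cos(alpha_eff) = cos(af) * cos(as)``.  Broadcasts over inputs;
    returns an array with a trailing axis of length 3.
    """
    af = np.deg2rad(np.asarray(alpha_fast_deg, dtype=float))
    al = np.deg2rad(np.asarray(alpha_slow_deg, dtype=float))
    af, al = np.broadcast_arrays(af, al)
    return np.stack(
        [np.sin(af), np.cos(af) * np.sin(al), -np.cos(af) * np.cos(al)], axis=-1
    )


def retina_hit(geom: ScanGeometry, alpha_deg: float) -> RetinaHit:
    """Full intersection record for a meridional ray (y = 0 plane)."""
    L = chord_length(geom, alpha_deg)
    beta = central_angle(geom, alpha_deg)
    rad = np.deg2rad(alpha_deg)
    point = geom.pivot_point + L * np.array([np.sin(rad), 0.0, -np.cos(rad)])
    return RetinaHit(float(alpha_deg), float(L), float(beta), point)
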