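"""Schematic eyes and optical-path / geometric-length conversion.

OCT ranging measures *optical* path length (OPL).  Converting an OPL
measured along the visual axis into a geometric length (GL) requires
the thickness-weighted mean refractive index of the traversed ocular
media,

    n_avg = (sum_i n_i * d_i) / (sum_i d_i),        GL = OPL / n_avg,

where ocular segment *i* (cornea, aqueous, lens, vitreous, retina) has
geometric thickness ``d_i`` (mm) and group refractive index ``n_i``.
For the newborn Gullstrand schematic eye shipped as the
``"gullstrand_newborn"`` preset this gives n_avg = 1.357 (3 d.p.) over
a 17.45 mm axial length measured to the retinal pigment epithelium.

Custom eyes (e.g. adult) can be constructed from a list of segments or
loaded from a YAML/JSON config block (see :func:`eye_from_config`).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "OcularSegment",
    "SchematicEye",
    "GULLSTRAND_NEWBORN",
    "PRESETS",
    "get_preset",
    "average_refractive_index",
    "total_axial_length",
    "opl_to_geometric",
    "geometric_to_opl",
    "eye_from_config",
    "scaled_newborn_eye",
]

#: canonical segment labels, anterior to posterior
SEGMENT_NAMES = ("CT", "ACD", "LT", "VCD", "RT")

#: label of the retinal-thickness segment (excluded in ILM-referenced mode)
RETINA_SEGMENT = "RT"


@dataclass(frozen=True)
class OcularSegment:
    """One ocular segment: a slab of thickness ``thickness_mm`` (geometric,
    mm) with group refractive index ``index`` (dimensionless)."""

    name: str
    thickness_mm: float
    index: float

    def __post_init__(self) -> None:
        if not self.thickness_mm > 0:
            raise ValueError(
                f"segment {self.name!r}: thickness must be > 0, got {self.thickness_mm}"
            )
        if not 1.0 < self.index < 2.0:
            raise ValueError(
                f"segment {self.name!r}: refractive index must lie in (1, 2), got {self.index}"
            )

    @property
    def opl_mm(self) -> float:
        """Optical thickness ``n_i * d_i`` in mm."""
        return self.thickness_mm * self.index


@dataclass(frozen=True)
class SchematicEye:
    """Ordered stack of :class:`OcularSegment` (anterior to posterior).

    ``axial_length_mm`` is the sum of segment thicknesses (the geometric
    axial length, by default to the RPE, i.e. including the retinal
    segment) and ``n_avg`` the thickness-weighted mean index.
    """

    segments: tuple[OcularSegment, ...]

    def __post_init__(self) -> None:
        if len(self.segments) == 0:
            raise ValueError("a SchematicEye needs at least one segment")

    # -- derived quantities -------------------------------------------------

    @property
    def total_length_mm(self) -> float:
        return sum(s.thickness_mm for s in self.segments)

    @property
    def n_avg(self) -> float:
        return average_refractive_index(self)

    def axial_length_mm(self, include_retina: bool = True) -> float:
        """Geometric axial length; ``include_retina=False`` stops at the
        ILM (the ultrasound convention) instead of the RPE."""
        return sum(
            s.thickness_mm
            for s in self.segments
            if include_retina or s.name != RETINA_SEGMENT
        )

    def opl_mm(self, include_retina: bool = True) -> float:
        """Optical path length of the stack, apex to RPE (or to the ILM
        with ``include_retina=False``)."""
        return sum(
            s.opl_mm
            for s in self.segments
            if include_retina or s.name != RETINA_SEGMENT
        )

    def n_avg_to(self, include_retina: bool = True) -> float:
        """Mean index over the segments entering the chosen reference."""
        return self.opl_mm(include_retina) / self.axial_length_mm(include_retina)

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_segments(cls, rows) -> "SchematicEye":
        """Build from an iterable of ``(name, thickness_mm, index)`` tuples
        or ``{"name", "thickness_mm", "index"}`` mappings."""
        segs = []
        for row in rows:
            if isinstance(row, OcularSegment):
                segs.append(row)
            elif isinstance(row, dict):
                segs.append(
                    OcularSegment(row["name"], float(row["thickness_mm"]), float(row["index"]))
                )
            else:
                name, d, n = row
                segs.append(OcularSegment(str(name), float(d), float(n)))
        return cls(tuple(segs))


#: Newborn Gullstrand schematic eye (corneal thickness, anterior chamber
#: depth, lens thickness, vitreous chamber depth, retinal thickness).
GULLSTRAND_NEWBORN = SchematicEye.from_segments(
    [
        ("CT", 0.75, 1.377),
        ("ACD", 1.85, 1.336),
        ("LT", 3.7, 1.43),
        ("VCD", 11.0, 1.334),
        ("RT", 0.15, 1.346),
    ]
)

PRESETS: dict[str, SchematicEye] = {"gullstrand_newborn": GULLSTRAND_NEWBORN}


def get_preset(name: str) -> SchematicEye:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown eye preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


def average_refractive_index(eye: SchematicEye) -> float:
    """Thickness-weighted mean refractive index of the eye.

    Returns ``(sum n_i * d_i) / (sum d_i)`` at full floating precision;
    round to 3 d.p. for display.  Bounded by the extreme segment indices
    and invariant under splitting a segment into sub-segments with the
    same index.
    """
    if len(eye.segments) == 0:  # defensive; type invariant forbids this
        raise ValueError("cannot average over an empty segment list")
    d = eye.total_length_mm
    return sum(s.opl_mm for s in eye.segments) / d


def total_axial_length(eye: SchematicEye, include_retina: bool = True) -> float:
    """Geometric axial length in mm (sum of segment thicknesses)."""
    return eye.axial_length_mm(include_retina)


def opl_to_geometric(opl_mm: float, n_avg: float) -> float:
    """Convert an optical path length (mm) to geometric length, GL = OPL / n_avg."""
    if not opl_mm > 0:
        raise ValueError(f"OPL must be > 0, got {opl_mm}")
    if not n_avg > 1:
        raise ValueError(f"n_avg must exceed 1, got {n_avg}")
    return opl_mm / n_avg


def geometric_to_opl(gl_mm: float, n_avg: float) -> float:
    """Convert a geometric length (mm) to optical path length, OPL = GL * n_avg."""
    if not gl_mm > 0:
        raise ValueError(f"GL must be > 0, got {gl_mm}")
    if not n_avg > 1:
        raise ValueError(f"n_avg must exceed 1, got {n_avg}")
    return gl_mm * n_avg


def eye_from_config(obj) -> SchematicEye:
    """Build an eye from a config block.

    Accepts ``{"preset": name}`` or ``{"segments": [{name, thickness_mm,
    index}, ...]}`` (or a bare list of segment rows).
    """
    if isinstance(obj, SchematicEye):
        return obj
    if isinstance(obj, dict):
        if "preset" in obj:
            return get_preset(obj["preset"])
        if "segments" in obj:
            return SchematicEye.from_segments(obj["segments"])
        raise ValueError("eye config needs a 'preset' or 'segments' key")
    return SchematicEye.from_segments(obj)


def scaled_newborn_eye(axial_length_mm: float) -> SchematicEye:
    """Newborn schematic eye rescaled to a target axial length (to RPE).

    Only the vitreous chamber depth is adjusted — the convention used for
    eye-growth modelling, where anterior segment dimensions change little
    compared with vitreous elongation.
    """
    delta = axial_length_mm - GULLSTRAND_NEWBORN.total_length_mm
    rows = []
    for s in GULLSTRAND_NEWBORN.segments:
        d = s.thickness_mm + delta if s.name == "VCD" else s.thickness_mm
        rows.append((s.name, d, s.index))
    eye = SchematicEye.from_segments(rows)
    return eye
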