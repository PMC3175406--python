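"""Three-source mixing geometry in δ¹³C/δ¹⁵N diet space.

The consumer's collagen records trophically enriched values: collagen sits
0.8-1.3 ‰ above the diet in δ¹³C and 3-5 ‰ in δ¹⁵N.  Subtracting a point
offset (range midpoints by default) maps the mean hominid collagen value
into diet space — the "mixture".  Three food sources span the mixing
triangle: a fixed freshwater-fish signature (source 1, high δ¹⁵N), a
herbivore-meat signature averaged from the faunal types' per-type means
(source 2, high δ¹³C), and a plant signature derived from the herbivore
source by subtracting the herbivore-over-plant enrichment (source 3, low on
both axes).  Two geometry modes exist: ``average`` places vertices at the
source means; ``extended`` pushes each vertex one standard deviation
outward, away from the mixture, on each axis.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from statistics import mean
from typing import Iterable, Sequence

import numpy as np

from .records import HERBIVORE_TAXA, IsotopeRecord, Taxon

__all__ = [
    "FractionationOffsets",
    "COLLAGEN_DIET_OFFSETS",
    "HERBIVORE_PLANT_OFFSETS",
    "SourceName",
    "SourceProvenance",
    "SourceSignature",
    "HominidCondition",
    "MixturePoint",
    "GeometryMode",
    "MixingGeometry",
    "MissingSourceError",
    "MissingMixtureError",
    "DegenerateGeometryError",
    "diet_space_mixture",
    "herbivore_source",
    "estimate_plant_source",
    "build_geometry",
    "triangle_area",
    "barycentric_coordinates",
]


@dataclass(frozen=True)
class FractionationOffsets:
    """Diet-to-consumer trophic enrichment, per mil.

    ``dC_point`` / ``dN_point`` are the scalar offsets used in computation;
    the ranges record the literature spread and bound the points, so
    sensitivity runs at the endpoints are a config change away.
    """

    dC_range: tuple = (0.8, 1.3)
    dN_range: tuple = (3.0, 5.0)
    dC_point: float = 1.05
    dN_point: float = 4.0

    def __post_init__(self) -> None:
        for lo_hi, point, name in (
            (self.dC_range, self.dC_point, "dC"),
            (self.dN_range, self.dN_point, "dN"),
        ):
            lo, hi = lo_hi
            if hi < lo:
                raise ValueError(f"{name}_range is reversed")
            if not (lo <= point <= hi):
                raise ValueError(f"{name}_point {point} outside range {lo_hi}")


#: Collagen sits this far above the diet (the default mapping into diet space).
COLLAGEN_DIET_OFFSETS = FractionationOffsets()
#: Alternative preset: herbivore collagen over plants (≈5 ‰ C, 3-5 ‰ N).
HERBIVORE_PLANT_OFFSETS = FractionationOffsets(
    dC_range=(5.0, 5.0), dN_range=(3.0, 5.0), dC_point=5.0, dN_point=4.0
)


class SourceName(str, enum.Enum):
    FISH = "fish"
    MEAT = "meat"
    PLANTS = "plants"


class SourceProvenance(str, enum.Enum):
    LITERATURE = "literature"
    DERIVED_FROM_HERBIVORES = "derived_from_herbivores"


@dataclass(frozen=True)
class SourceSignature:
    """A food source's mean ± SD signature in diet space."""

    name: SourceName
    mean_d13C: float
    sd_d13C: float
    mean_d15N: float
    sd_d15N: float
    provenance: SourceProvenance = SourceProvenance.LITERATURE

    def __post_init__(self) -> None:
        object.__setattr__(self, "name", SourceName(self.name))
        object.__setattr__(self, "provenance", SourceProvenance(self.provenance))
        if self.sd_d13C < 0 or self.sd_d15N < 0:
            raise ValueError("standard deviations must be non-negative")

    @property
    def mean(self) -> tuple[float, float]:
        return (self.mean_d13C, self.mean_d15N)


class HominidCondition(str, enum.Enum):
    WHOLE = "whole_hominids"
    ASSOCIATED = "associated_hominids"


@dataclass(frozen=True)
class MixturePoint:
    """Fractionation-corrected mean hominid diet point."""

    d13C: float
    d15N: float
    n_hominids: int
    condition: HominidCondition = HominidCondition.WHOLE

    def __post_init__(self) -> None:
        object.__setattr__(self, "condition", HominidCondition(self.condition))
        if self.n_hominids < 1:
            raise ValueError("a mixture needs at least one hominid record")

    @property
    def point(self) -> tuple[float, float]:
        return (self.d13C, self.d15N)


class MissingSourceError(ValueError):
    pass


class MissingMixtureError(ValueError):
    pass


class DegenerateGeometryError(ValueError):
    pass


def diet_space_mixture(
    hominid_records: Sequence[IsotopeRecord],
    offsets: FractionationOffsets = COLLAGEN_DIET_OFFSETS,
    condition: HominidCondition = HominidCondition.WHOLE,
) -> MixturePoint:
    """Mean hominid collagen point translated into diet space.

    Condition filtering (whole vs fauna-associated hominids) happens
    upstream; ``condition`` only labels the result.
    """
    records = list(hominid_records)
    if not records:
        raise MissingMixtureError(
            f"no hominid records for condition {HominidCondition(condition).value}"
        )
    return MixturePoint(
        d13C=mean(r.d13C for r in records) - offsets.dC_point,
        d15N=mean(r.d15N for r in records) - offsets.dN_point,
        n_hominids=len(records),
        condition=condition,
    )


def herbivore_source(
    records: Iterable[IsotopeRecord],
    included_types: Iterable[Taxon],
    dn_shift_sd: float = 0.0,
) -> SourceSignature:
    """Herbivore/meat source as the unweighted average of per-type means.

    Each included faunal type contributes its own mean and SD with equal
    weight regardless of sample size, so a heavily sampled species cannot
    dominate the signature.  ``dn_shift_sd`` shifts the source δ¹⁵N mean by
    that many source-SDs (the ±1 SD sensitivity conditions).  Types with a
    single record contribute SD 0.
    """
    included = [Taxon(t) for t in included_types]
    if not included:
        raise MissingSourceError("herbivore source needs at least one faunal type")
    bad = [t for t in included if t not in HERBIVORE_TAXA]
    if bad:
        raise MissingSourceError(
            f"non-herbivore taxa in herbivore source: {[t.value for t in bad]}"
        )
    by_type: dict[Taxon, list[IsotopeRecord]] = {t: [] for t in included}
    for r in records:
        if r.taxon in by_type:
            by_type[r.taxon].append(r)
    missing = [t.value for t, rs in by_type.items() if not rs]
    if missing:
        raise MissingSourceError(f"no records for faunal type(s): {missing}")

    def _stats(values: list[float]) -> tuple[float, float]:
        arr = np.asarray(values, float)
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        return float(arr.mean()), sd

    c_stats = [_stats([r.d13C for r in rs]) for rs in by_type.values()]
    n_stats = [_stats([r.d15N for r in rs]) for rs in by_type.values()]
    mean_c = mean(m for m, _ in c_stats)
    sd_c = mean(s for _, s in c_stats)
    mean_n = mean(m for m, _ in n_stats)
    sd_n = mean(s for _, s in n_stats)
    return SourceSignature(
        name=SourceName.MEAT,
        mean_d13C=mean_c,
        sd_d13C=sd_c,
        mean_d15N=mean_n + dn_shift_sd * sd_n,
        sd_d15N=sd_n,
        provenance=SourceProvenance.DERIVED_FROM_HERBIVORES,
    )


def estimate_plant_source(
    herbivore: SourceSignature,
    plant_offsets: FractionationOffsets = COLLAGEN_DIET_OFFSETS,
) -> SourceSignature:
    """Plant source from the herbivore source minus the enrichment offsets.

    The SD is carried through unchanged — derivation shifts the mean but the
    spread of the underlying herbivore signal is the only spread available.
    """
    return SourceSignature(
        name=SourceName.PLANTS,
        mean_d13C=herbivore.mean_d13C - plant_offsets.dC_point,
        sd_d13C=herbivore.sd_d13C,
        mean_d15N=herbivore.mean_d15N - plant_offsets.dN_point,
        sd_d15N=herbivore.sd_d15N,
        provenance=SourceProvenance.DERIVED_FROM_HERBIVORES,
    )


class GeometryMode(str, enum.Enum):
    EXTENDED = "extended"
    AVERAGE = "average"


def triangle_area(vertices: Sequence[Sequence[float]]) -> float:
    (x1, y1), (x2, y2), (x3, y3) = vertices
    return abs((x2 - x1) * (y3 - y1) - (x3 - x1) * (y2 - y1)) / 2.0


def barycentric_coordinates(
    vertices: Sequence[Sequence[float]], point: Sequence[float]
) -> np.ndarray:
    """Barycentric coordinates of ``point`` w.r.t. a triangle (may be
    negative outside the hull).  Raises on a degenerate triangle."""
    v = np.asarray(vertices, float)
    a = np.vstack([v.T, np.ones(3)])
    b = np.array([point[0], point[1], 1.0])
    if abs(np.linalg.det(a)) < 1e-12:
        raise DegenerateGeometryError("collinear source vertices")
    return np.linalg.solve(a, b)


@dataclass(frozen=True)
class MixingGeometry:
    """Three source vertices (fish, meat, plants order) plus the mixture.

    ``mixture_inside`` reports whether the mixture falls within the
    triangle (up to a small barycentric tolerance); ``roles_ok`` reports
    whether the vertices respect the expected source roles (fish highest
    δ¹⁵N, meat highest δ¹³C, plants lowest on both axes).  Neither is an
    error by itself: an outside mixture yields an infeasible enumeration
    downstream, never a silent clip.
    """

    vertices: tuple  # ((x,y) fish, (x,y) meat, (x,y) plants)
    sources: tuple  # the three SourceSignatures the vertices came from
    mixture: MixturePoint
    mode: GeometryMode
    sd_multiplier: float = 1.0
    mixture_inside: bool = True
    roles_ok: bool = True
    role_notes: tuple = ()

    @property
    def area(self) -> float:
        return triangle_area(self.vertices)

    def barycentric(self) -> np.ndarray:
        return barycentric_coordinates(self.vertices, self.mixture.point)


def _check_roles(vertices: Sequence[Sequence[float]]) -> tuple[bool, tuple]:
    (fx, fy), (mx, my), (px, py) = vertices
    notes = []
    if not (fy > my and fy > py):
        notes.append("fish vertex does not have the highest d15N")
    if not (mx > fx and mx > px):
        notes.append("meat vertex does not have the highest d13C")
    if not (px < fx and px < mx and py < fy and py < my):
        notes.append("plants vertex is not lowest in both isotopes")
    return (not notes, tuple(notes))


def build_geometry(
    fish: SourceSignature,
    meat: SourceSignature,
    plants: SourceSignature,
    mixture: MixturePoint,
    mode: GeometryMode = GeometryMode.EXTENDED,
    sd_multiplier: float = 1.0,
    containment_tol: float = 1e-9,
) -> MixingGeometry:
    """Place the three source vertices around the mixture.

    ``average`` mode puts vertices at the source means.  ``extended`` mode
    pushes each vertex coordinate ``sd_multiplier`` SDs outward away from
    the mixture on each axis (sign(0) treated as +1), spanning the largest
    source variability around the mixture.
    """
    mode = GeometryMode(mode)
    srcs = (fish, meat, plants)
    if [s.name for s in srcs] != [SourceName.FISH, SourceName.MEAT, SourceName.PLANTS]:
        raise ValueError("sources must be passed in (fish, meat, plants) order")
    if mode is GeometryMode.AVERAGE:
        vertices = tuple(s.mean for s in srcs)
    else:
        mx, my = mixture.point

        def _out(value: float, sd: float, toward: float) -> float:
            sign = 1.0 if value - toward >= 0 else -1.0
            return value + sd_multiplier * sd * sign

        vertices = tuple(
            (_out(s.mean_d13C, s.sd_d13C, mx), _out(s.mean_d15N, s.sd_d15N, my))
            for s in srcs
        )
    if triangle_area(vertices) <= 0.0:
        raise DegenerateGeometryError("source vertices are collinear")
    bary = barycentric_coordinates(vertices, mixture.point)
    inside = bool(np.all(bary >= -containment_tol))
    roles_ok, notes = _check_roles(vertices)
    return MixingGeometry(
        vertices=vertices,
        sources=srcs,
        mixture=mixture,
        mode=mode,
        sd_multiplier=sd_multiplier,
        mixture_inside=inside,
        roles_ok=roles_ok,
        role_notes=notes,
    )
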