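"""Feasible three-source diet proportions by exhaustive simplex enumeration.

The mixing model walks every composition (a, b, c) on an integer grid with
a + b + c = 1/increment, predicts the mixture each composition would
produce as the proportion-weighted average of the source vertices, and
keeps those whose predicted mixture matches the observed one within a
per-mil mass-balance tolerance.  The retained set of proportion vectors is
summarised per source (mean, min, max, 1st/99th percentiles).  For the
determined case (three sources, two isotopes) the exact barycentric
solution is also available and serves as an internal cross-check.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .sources import MixingGeometry, SourceName, barycentric_coordinates

__all__ = [
    "DeviationMetric",
    "EnumerationSettings",
    "ProportionVector",
    "ContributionSummary",
    "FeasibleSet",
    "BarycentricSolution",
    "enumerate_feasible",
    "exact_three_source_solution",
    "summarize_contributions",
    "simplex_grid",
]

SOURCE_ORDER = (SourceName.FISH, SourceName.MEAT, SourceName.PLANTS)


class DeviationMetric(str, enum.Enum):
    PER_ISOTOPE_MAX = "per_isotope_max"
    EUCLIDEAN = "euclidean"


@dataclass(frozen=True)
class EnumerationSettings:
    """Controls for the grid search.

    increment: simplex step (1 % by default; 1/increment must be integral).
    tolerance: mass-balance tolerance in per mil (0.1 ‰ by default).
    deviation_metric: how predicted-vs-observed deviation is collapsed
        across the two isotopes.
    """

    increment: float = 0.01
    tolerance: float = 0.1
    deviation_metric: DeviationMetric = DeviationMetric.PER_ISOTOPE_MAX

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "deviation_metric", DeviationMetric(self.deviation_metric)
        )
        if not (0.0 < self.increment <= 0.1):
            raise ValueError("increment must be in (0, 0.1]")
        grid = 1.0 / self.increment
        if abs(grid - round(grid)) > 1e-9:
            raise ValueError("1/increment must be an integer")
        if self.tolerance < 0:
            raise ValueError("tolerance must be non-negative")

    @property
    def grid(self) -> int:
        return round(1.0 / self.increment)


@dataclass(frozen=True)
class ProportionVector:
    """A point on (or near) the 3-simplex: fish, meat, plant proportions."""

    p_fish: float
    p_meat: float
    p_plants: float

    def as_array(self) -> np.ndarray:
        return np.array([self.p_fish, self.p_meat, self.p_plants])

    @property
    def on_simplex(self) -> bool:
        a = self.as_array()
        return bool(np.all(a >= -1e-12) and abs(a.sum() - 1.0) <= 1e-9)


def simplex_grid(grid: int) -> np.ndarray:
    """All integer compositions (a, b, c) with a + b + c = grid.

    Returned as an (n, 3) int array in lexicographic order; n is the
    stars-and-bars count (grid+1)(grid+2)/2.
    """
    reps = np.arange(grid + 1, 0, -1)
    a = np.repeat(np.arange(grid + 1), reps)
    b = np.concatenate([np.arange(grid + 1 - k) for k in range(grid + 1)])
    c = grid - a - b
    return np.column_stack([a, b, c])


@dataclass(frozen=True)
class ContributionSummary:
    mean: float
    minimum: float
    maximum: float
    p01: float
    p99: float


@dataclass(frozen=True)
class FeasibleSet:
    """All grid compositions reproducing the mixture within tolerance.

    Solutions are stored as integer grid counts (rows of ``counts`` sum to
    ``settings.grid`` exactly) so proportions never drift; ``proportions``
    derives the float simplex points.  ``min_deviation`` is the smallest
    deviation achieved over the whole grid — the diagnostic when the set is
    empty (infeasible geometry).
    """

    settings: EnumerationSettings
    geometry: MixingGeometry
    counts: np.ndarray
    min_deviation: float

    @property
    def feasible(self) -> bool:
        return self.counts.shape[0] > 0

    @property
    def n_solutions(self) -> int:
        return int(self.counts.shape[0])

    @property
    def proportions(self) -> np.ndarray:
        return self.counts / self.settings.grid

    def solution_vectors(self) -> list[ProportionVector]:
        return [ProportionVector(*row) for row in self.proportions]

    def summary(self) -> dict[SourceName, ContributionSummary]:
        return summarize_contributions(self)


def _deviations(
    pred: np.ndarray, observed: Sequence[float], metric: DeviationMetric
) -> np.ndarray:
    diff = pred - np.asarray(observed, float)
    if metric is DeviationMetric.PER_ISOTOPE_MAX:
        return np.abs(diff).max(axis=1)
    return np.sqrt((diff**2).sum(axis=1))


def enumerate_feasible(
    geometry: MixingGeometry, settings: EnumerationSettings | None = None
) -> FeasibleSet:
    """Exhaustively test every simplex grid composition against the mixture."""
    settings = settings or EnumerationSettings()
    counts = simplex_grid(settings.grid)
    props = counts / settings.grid
    vertices = np.asarray(geometry.vertices, float)  # (3, 2)
    pred = props @ vertices
    dev = _deviations(pred, geometry.mixture.point, settings.deviation_metric)
    mask = dev <= settings.tolerance + 1e-12
    return FeasibleSet(
        settings=settings,
        geometry=geometry,
        counts=counts[mask],
        min_deviation=float(dev.min()),
    )


@dataclass(frozen=True)
class BarycentricSolution:
    proportions: ProportionVector
    outside_hull: bool


def exact_three_source_solution(geometry: MixingGeometry) -> BarycentricSolution:
    """Exact proportions for the determined 3-source / 2-isotope system.

    Solves the two mass-balance equations plus the closure constraint; for
    mixtures outside the triangle the (negative) barycentric coordinates
    are returned as-is with ``outside_hull`` set.
    """
    bary = barycentric_coordinates(geometry.vertices, geometry.mixture.point)
    return BarycentricSolution(
        proportions=ProportionVector(*(float(x) for x in bary)),
        outside_hull=bool(np.any(bary < -1e-9)),
    )


def summarize_contributions(
    feasible: FeasibleSet,
) -> dict[SourceName, ContributionSummary]:
    """Per-source mean/min/max and 1st/99th percentiles of the feasible set.

    Values are proportions in [0, 1]; report rendering converts to whole
    percentages.  An empty feasible set propagates as an error — callers
    hold the infeasible status instead.
    """
    if not feasible.feasible:
        raise ValueError(
            "cannot summarize an infeasible result "
            f"(min deviation {feasible.min_deviation:.4g} per mil)"
        )
    props = feasible.proportions
    out: dict[SourceName, ContributionSummary] = {}
    for j, name in enumerate(SOURCE_ORDER):
        col = props[:, j]
        out[name] = ContributionSummary(
            mean=float(col.mean()),
            minimum=float(col.min()),
            maximum=float(col.max()),
            p01=float(np.percentile(col, 1)),
            p99=float(np.percentile(col, 99)),
        )
    return out
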