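"""Cross-cohort comparison of mean diet compositions.

Mean source contributions are standardized into integer "resource units"
(equal protein weight per source by default, 100 units total, so units are
rounded percentages) and chronological cohorts are compared pairwise with
Pearson's chi-squared test on the resulting 2 x 3 table.  Significance uses
a Bonferroni-corrected level: alpha / 3 for the three cohort pairs, applied
as the 3-decimal rounded cutoff (0.017 at alpha = 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .mixing import SOURCE_ORDER, ProportionVector
from .sources import SourceName

__all__ = [
    "ResourceUnitTable",
    "ChiSquaredResult",
    "PAIR_LABELS",
    "COHORT_ORDER",
    "standardize_resource_units",
    "chisq_compare",
    "bonferroni_threshold",
    "compare_all_pairs",
]

COHORT_ORDER = ("MOIS3_N", "MOIS3_MH", "MOIS2_MH")
PAIR_LABELS = {
    ("MOIS3_N", "MOIS3_MH"): "N3-MH3",
    ("MOIS3_N", "MOIS2_MH"): "N3-MH2",
    ("MOIS3_MH", "MOIS2_MH"): "MH3-MH2",
}


@dataclass(frozen=True)
class ResourceUnitTable:
    """Integer resource units per source, summing exactly to total_units."""

    cohort: str
    units: Mapping[SourceName, int]
    total_units: int = 100

    def __post_init__(self) -> None:
        if any(u < 0 for u in self.units.values()):
            raise ValueError("resource units must be non-negative")
        if sum(self.units.values()) != self.total_units:
            raise ValueError("resource units must sum to total_units")

    def as_vector(self) -> np.ndarray:
        return np.array([self.units[s] for s in SOURCE_ORDER], dtype=float)


def standardize_resource_units(
    mean_proportions: ProportionVector | Sequence[float],
    total_units: int = 100,
    cohort: str = "",
    protein_weights: Sequence[float] | None = None,
) -> ResourceUnitTable:
    """Convert mean proportions to integer units by largest-remainder rounding.

    Proportions within 1e-6 of summing to one are renormalized; larger
    closure errors are rejected.  ``protein_weights`` optionally reweights
    sources by protein content before allocation (equal weights by
    default).  Rounding ties break in fixed source order (fish, meat,
    plants).
    """
    if isinstance(mean_proportions, ProportionVector):
        props = mean_proportions.as_array()
    else:
        props = np.asarray(mean_proportions, dtype=float)
    if props.shape != (3,):
        raise ValueError("expected three source proportions")
    if np.any(props < 0):
        raise ValueError("proportions must be non-negative")
    total = props.sum()
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"proportions sum to {total}, not 1")
    props = props / total
    if protein_weights is not None:
        w = np.asarray(protein_weights, dtype=float)
        if w.shape != (3,) or np.any(w <= 0):
            raise ValueError("protein_weights must be three positive values")
        props = props * w
        props = props / props.sum()

    shares = props * total_units
    base = np.floor(shares).astype(int)
    remainder = shares - base
    short = total_units - int(base.sum())
    # Largest remainder first; ties resolved by source order (stable sort on
    # the negated remainder preserves index order among equals).
    order = np.argsort(-remainder, kind="stable")
    for idx in order[:short]:
        base[idx] += 1
    units = {name: int(base[j]) for j, name in enumerate(SOURCE_ORDER)}
    return ResourceUnitTable(cohort=cohort, units=units, total_units=total_units)


@dataclass(frozen=True)
class ChiSquaredResult:
    """One pairwise cohort comparison; ``pvalue`` is None for NA cells."""

    pair: str
    statistic: float | None
    df: int | None
    pvalue: float | None
    significant: bool | None
    threshold: float
    dropped_sources: tuple = ()
    note: str = ""

    @property
    def is_na(self) -> bool:
        return self.pvalue is None


def bonferroni_threshold(alpha: float = 0.05, m: int = 3) -> tuple[float, float]:
    """Family-wise corrected level: returns (exact, rounded-to-3-decimals)."""
    if m < 1:
        raise ValueError("number of comparisons must be at least 1")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    exact = alpha / m
    return exact, round(exact, 3)


def chisq_compare(
    units_a: ResourceUnitTable,
    units_b: ResourceUnitTable,
    threshold: float = 0.017,
    pair: str | None = None,
) -> ChiSquaredResult:
    """Pearson chi-squared on the 2 x k resource-unit table (no continuity
    correction).  Sources with zero counts in both cohorts are dropped,
    reducing the degrees of freedom, and noted in the result."""
    if set(units_a.units) != set(units_b.units):
        raise ValueError("cohorts must share the same source set")
    if units_a.total_units != units_b.total_units:
        raise ValueError("cohorts must use the same total_units")
    pair = pair or f"{units_a.cohort}-{units_b.cohort}"
    table = np.vstack([units_a.as_vector(), units_b.as_vector()])
    zero_cols = np.where(table.sum(axis=0) == 0)[0]
    dropped = tuple(SOURCE_ORDER[j] for j in zero_cols)
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    note = (
        f"dropped zero-count source(s): {[s.value for s in dropped]}" if dropped else ""
    )
    if table.shape[1] < 2 or np.array_equal(table[0], table[1]):
        # Identical compositions (or a single shared column): no evidence of
        # difference by construction.
        df = max(table.shape[1] - 1, 0)
        return ChiSquaredResult(
            pair=pair,
            statistic=0.0,
            df=df,
            pvalue=1.0,
            significant=False,
            threshold=threshold,
            dropped_sources=dropped,
            note=note or "identical compositions",
        )
    stat, p, df, _ = stats.chi2_contingency(table, correction=False)
    return ChiSquaredResult(
        pair=pair,
        statistic=float(stat),
        df=int(df),
        pvalue=float(p),
        significant=bool(p < threshold),
        threshold=threshold,
        dropped_sources=dropped,
        note=note,
    )


def compare_all_pairs(
    mean_proportions_by_cohort: Mapping[str, ProportionVector | Sequence[float] | None],
    condition_label: str = "",
    alpha: float = 0.05,
    total_units: int = 100,
    protein_weights: Sequence[float] | None = None,
) -> list[ChiSquaredResult]:
    """All three pairwise cohort comparisons for one simulation condition.

    Cohorts mapped to None (no feasible simulation) yield NA results in
    both of their pairs, mirroring how missing simulations propagate into
    the published-style comparison table.
    """
    _, threshold = bonferroni_threshold(alpha=alpha, m=3)
    units: dict[str, ResourceUnitTable | None] = {}
    for cohort in COHORT_ORDER:
        props = mean_proportions_by_cohort.get(cohort)
        units[cohort] = (
            None
            if props is None
            else standardize_resource_units(
                props,
                total_units=total_units,
                cohort=cohort,
                protein_weights=protein_weights,
            )
        )
    results = []
    for (ca, cb), label in PAIR_LABELS.items():
        ua, ub = units[ca], units[cb]
        if ua is None or ub is None:
            missing = [c for c, u in ((ca, ua), (cb, ub)) if u is None]
            results.append(
                ChiSquaredResult(
                    pair=label,
                    statistic=None,
                    df=None,
                    pvalue=None,
                    significant=None,
                    threshold=threshold,
                    note=f"NA: no feasible result for {', '.join(missing)}"
                    + (f" [{condition_label}]" if condition_label else ""),
                )
            )
        else:
            results.append(chisq_compare(ua, ub, threshold=threshold, pair=label))
    return results
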