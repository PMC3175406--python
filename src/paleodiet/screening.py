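"""Isotopic homogeneity screening across archaeological sites.

Before a faunal type's specimens from several sites are pooled into one
source signature, a Kruskal-Wallis rank test checks that the sites share the
same isotopic distribution.  Screening runs per taxon and per isotope within
a spatial cluster and chronological group; heterogeneous groups (p below the
screening level, 0.01 by default) get divergent sites flagged by an
iterative leave-one-out heuristic, and a config-driven exclusion list
removes (taxon, site) pairs before source construction.
"""

from __future__ import annotations

import enum
import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .records import ChronoGroup, ClusterSpec, IsotopeRecord, Taxon

logger = logging.getLogger(__name__)

__all__ = [
    "KruskalWallisResult",
    "HomogeneityResult",
    "ScreeningStatus",
    "ExclusionEntry",
    "ExclusionList",
    "kruskal_wallis",
    "screen_cohort",
    "apply_exclusions",
]

#: Largest pooled sample for which the two-group exact permutation p-value
#: is enumerated instead of the chi-squared approximation.
EXACT_N_MAX = 10


class KruskalWallisResult(NamedTuple):
    statistic: float
    pvalue: float
    method: str  # "exact" or "asymptotic"


def _midrank_h(values: np.ndarray, sizes: Sequence[int]) -> float:
    """Kruskal-Wallis H on midranks with the standard tie correction.

    ``values`` is the pooled sample laid out group by group with group sizes
    ``sizes``.  All values identical gives H = 0 by convention.
    """
    n = values.size
    ranks = stats.rankdata(values)
    h = 0.0
    start = 0
    for sz in sizes:
        rsum = ranks[start : start + sz].sum()
        h += rsum * rsum / sz
        start += sz
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    denom = 1.0 - tie_term / (n**3 - n)
    if denom <= 0.0:  # every pooled value identical
        return 0.0
    return h / denom


def kruskal_wallis(
    groups: Sequence[Sequence[float]], method: str = "auto"
) -> KruskalWallisResult:
    """Kruskal-Wallis rank test across two or more groups.

    ``method`` is ``"auto"`` (exact permutation enumeration for two groups
    with pooled N <= 10, chi-squared approximation otherwise), ``"exact"``
    or ``"asymptotic"``.  The statistic is always the tie-corrected midrank
    H; the exact p-value is the fraction of all distinct group assignments
    of the pooled values whose H reaches the observed one.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("kruskal_wallis needs at least two groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("kruskal_wallis groups must be nonempty")
    sizes = [a.size for a in arrays]
    n = int(sum(sizes))
    if n < 3:
        raise ValueError("kruskal_wallis needs a pooled sample of at least 3")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return KruskalWallisResult(0.0, 1.0, "degenerate")

    h_obs = _midrank_h(pooled, sizes)

    if method == "auto":
        method = "exact" if (len(arrays) == 2 and n <= EXACT_N_MAX) else "asymptotic"
    if method == "exact":
        if len(arrays) != 2:
            raise ValueError("exact method implemented for two groups only")
        idx = np.arange(n)
        hits = 0
        total = 0
        for combo in itertools.combinations(idx, sizes[0]):
            mask = np.zeros(n, dtype=bool)
            mask[list(combo)] = True
            perm = np.concatenate([pooled[mask], pooled[~mask]])
            if _midrank_h(perm, sizes) >= h_obs - 1e-9:
                hits += 1
            total += 1
        return KruskalWallisResult(float(h_obs), hits / total, "exact")
    if method != "asymptotic":
        raise ValueError(f"unknown method: {method!r}")
    p = float(stats.chi2.sf(h_obs, df=len(arrays) - 1))
    return KruskalWallisResult(float(h_obs), p, "asymptotic")


class ScreeningStatus(str, enum.Enum):
    TESTED = "tested"
    UNTESTABLE = "untestable"


@dataclass(frozen=True)
class HomogeneityResult:
    """Outcome of screening one taxon x isotope across sites."""

    taxon: Taxon
    isotope: str  # "d13C" or "d15N"
    status: ScreeningStatus
    statistic: float | None = None
    pvalue: float | None = None
    group_sizes: Mapping[str, int] = field(default_factory=dict)
    heterogeneous: bool = False
    flagged_sites: tuple = ()
    singleton_sites: tuple = ()
    note: str = ""


def _site_groups(
    records: Iterable[IsotopeRecord], taxon: Taxon, isotope: str
) -> dict[str, list[float]]:
    groups: dict[str, list[float]] = {}
    for r in records:
        if r.taxon is taxon:
            groups.setdefault(r.site, []).append(getattr(r, isotope))
    return groups


def _flag_divergent_sites(
    groups: Mapping[str, Sequence[float]], alpha: float
) -> tuple[str, ...]:
    """Iteratively flag the site farthest from the grand mean in pooled-SD
    units, re-testing until the remainder is homogeneous or only two sites
    are left."""
    working = {s: list(v) for s, v in groups.items()}
    flagged: list[str] = []
    while len(working) > 2:
        res = kruskal_wallis(list(working.values()))
        if res.pvalue >= alpha:
            break
        pooled = np.concatenate([np.asarray(v, float) for v in working.values()])
        grand = pooled.mean()
        sd = pooled.std(ddof=1)
        if sd == 0.0:
            break
        worst = max(working, key=lambda s: abs(np.mean(working[s]) - grand) / sd)
        flagged.append(worst)
        del working[worst]
    return tuple(flagged)


def screen_cohort(
    records: Iterable[IsotopeRecord],
    taxon: Taxon,
    cluster: ClusterSpec,
    chrono: ChronoGroup | Iterable[ChronoGroup],
    alpha_screen: float = 0.01,
) -> dict[str, HomogeneityResult]:
    """Screen one faunal type's site homogeneity, per isotope.

    Returns a result for each of ``d13C`` and ``d15N``.  Cohorts with fewer
    than two sites come back with ``status = untestable`` rather than a
    silent pass.  Single-record sites are retained in the test (the rank
    test tolerates n = 1 groups) but listed in ``singleton_sites``.
    """
    from .records import subset_cohort  # local import avoids cycle at module load

    taxon = Taxon(taxon)
    cohort = subset_cohort(records, cluster, chrono, {taxon})
    out: dict[str, HomogeneityResult] = {}
    for isotope in ("d13C", "d15N"):
        groups = _site_groups(cohort, taxon, isotope)
        sizes = {s: len(v) for s, v in groups.items()}
        singletons = tuple(sorted(s for s, n in sizes.items() if n == 1))
        if len(groups) < 2:
            out[isotope] = HomogeneityResult(
                taxon=taxon,
                isotope=isotope,
                status=ScreeningStatus.UNTESTABLE,
                group_sizes=sizes,
                note=f"{len(groups)} site(s); need at least 2",
            )
            continue
        res = kruskal_wallis(list(groups.values()), method="asymptotic")
        hetero = res.pvalue < alpha_screen
        flagged = _flag_divergent_sites(groups, alpha_screen) if hetero else ()
        out[isotope] = HomogeneityResult(
            taxon=taxon,
            isotope=isotope,
            status=ScreeningStatus.TESTED,
            statistic=res.statistic,
            pvalue=res.pvalue,
            group_sizes=sizes,
            heterogeneous=hetero,
            flagged_sites=flagged,
            singleton_sites=singletons,
        )
    return out


@dataclass(frozen=True)
class ExclusionEntry:
    taxon: Taxon
    site: str
    reason: str = ""


@dataclass(frozen=True)
class ExclusionList:
    """Unique (taxon, site) pairs to drop before source construction."""

    entries: tuple = ()

    def __post_init__(self) -> None:
        entries = tuple(self.entries)
        keys = [(e.taxon, e.site) for e in entries]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate exclusion entries")
        object.__setattr__(self, "entries", entries)

    @classmethod
    def from_config(cls, items: Iterable[Mapping]) -> "ExclusionList":
        return cls(
            tuple(
                ExclusionEntry(
                    taxon=Taxon(item["taxon"]),
                    site=str(item["site"]),
                    reason=str(item.get("reason", "")),
                )
                for item in items
            )
        )

    def to_config(self) -> list[dict]:
        return [
            {"taxon": e.taxon.value, "site": e.site, "reason": e.reason}
            for e in self.entries
        ]


def apply_exclusions(
    records: Iterable[IsotopeRecord], exclusions: ExclusionList
) -> list[IsotopeRecord]:
    """Drop every record matching an exclusion (taxon, site) pair.

    Entries that match nothing produce a warning in the log, not an error.
    """
    records = list(records)
    keys = {(e.taxon, e.site) for e in exclusions.entries}
    kept = [r for r in records if (r.taxon, r.site) not in keys]
    removed = len(records) - len(kept)
    if removed:
        logger.info("apply_exclusions: removed %d record(s)", removed)
    matched = {(r.taxon, r.site) for r in records} & keys
    for e in exclusions.entries:
        if (e.taxon, e.site) not in matched:
            logger.warning(
                "exclusion (%s, %s) matched no records", e.taxon.value, e.site
            )
    return kept
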