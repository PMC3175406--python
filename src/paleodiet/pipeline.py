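"""Orchestration: run a simulation plan end to end and render report tables.

For every enabled plan cell the pipeline subsets the records to the cell's
spatial scope and cohort, applies site exclusions, builds the herbivore /
plant / fish sources, maps the hominid cohort into diet space, constructs
the mixing geometry and enumerates the feasible diet proportions.  Cells
whose cohort lacks a source or a mixture become NA results with an explicit
reason — the published-style comparison table carries NA cells, never a
crash.  Outputs are a per-cell contribution table, a pairwise chi-squared
comparison table, and a machine-readable JSON from which the text reports
can be regenerated verbatim.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .comparison import ChiSquaredResult, compare_all_pairs
from .mixing import (
    SOURCE_ORDER,
    EnumerationSettings,
    FeasibleSet,
    enumerate_feasible,
)
from .plan import FaunaCondition, PlanCell, Scope, SimulationPlan, scope_cluster
from .records import (
    ChronoGroup,
    HERBIVORE_TAXA,
    IsotopeRecord,
    Taxon,
    subset_cohort,
)
from .screening import ExclusionList, apply_exclusions
from .sources import (
    COLLAGEN_DIET_OFFSETS,
    DegenerateGeometryError,
    FractionationOffsets,
    HominidCondition,
    MissingMixtureError,
    MissingSourceError,
    SourceName,
    SourceSignature,
    build_geometry,
    diet_space_mixture,
    estimate_plant_source,
    herbivore_source,
)
from .synthetic import DEFAULT_FISH_SIGNATURE

__all__ = [
    "AnalysisConfig",
    "RunResult",
    "run_plan",
    "compare_cohorts",
    "render_reports",
    "reports_from_json",
]

FAUNA_SETS = {
    FaunaCondition.ALL: (Taxon.REINDEER, Taxon.HORSE, Taxon.BOVID),
    FaunaCondition.NO_REINDEER: (Taxon.HORSE, Taxon.BOVID),
    FaunaCondition.NO_HORSE: (Taxon.REINDEER, Taxon.BOVID),
    FaunaCondition.REINDEER_ONLY: (Taxon.REINDEER,),
}

COHORT_FAUNA_CHRONO = {
    "MOIS3_N": ChronoGroup.FAUNA_MOIS3,
    "MOIS3_MH": ChronoGroup.FAUNA_MOIS3,
    "MOIS2_MH": ChronoGroup.FAUNA_MOIS2,
}
COHORT_HOMINID_TAXON = {
    "MOIS3_N": Taxon.NEANDERTHAL,
    "MOIS3_MH": Taxon.MODERN_HUMAN,
    "MOIS2_MH": Taxon.MODERN_HUMAN,
}


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything beyond records and plan that a run needs."""

    fish: SourceSignature = DEFAULT_FISH_SIGNATURE
    offsets: FractionationOffsets = COLLAGEN_DIET_OFFSETS
    plant_offsets: FractionationOffsets = COLLAGEN_DIET_OFFSETS
    enumeration: EnumerationSettings = field(default_factory=EnumerationSettings)
    exclusions: ExclusionList = field(default_factory=ExclusionList)
    sd_multiplier: float = 1.0
    total_units: int = 100
    alpha: float = 0.05
    # When no grid composition matches at the base tolerance, the tolerance
    # is doubled (up to max_tolerance) until solutions appear — the standard
    # practice with feasible-mixture enumeration tools.  The tolerance used
    # is recorded in the result; set max_tolerance = base tolerance to
    # disable escalation.
    tolerance_factor: float = 2.0
    max_tolerance: float = 0.5

    @classmethod
    def from_config(cls, config: Mapping) -> "AnalysisConfig":
        kwargs: dict = {}
        if "fish" in config:
            f = config["fish"]
            kwargs["fish"] = SourceSignature(
                name=SourceName.FISH,
                mean_d13C=float(f["mean_d13C"]),
                sd_d13C=float(f.get("sd_d13C", 0.0)),
                mean_d15N=float(f["mean_d15N"]),
                sd_d15N=float(f.get("sd_d15N", 0.0)),
            )
        for key, cls_ in (("offsets", FractionationOffsets), ("plant_offsets", FractionationOffsets)):
            if key in config:
                o = config[key]
                kwargs[key] = cls_(
                    dC_range=tuple(o.get("dC_range", (0.8, 1.3))),
                    dN_range=tuple(o.get("dN_range", (3.0, 5.0))),
                    dC_point=float(o.get("dC_point", 1.05)),
                    dN_point=float(o.get("dN_point", 4.0)),
                )
        if "enumeration" in config:
            e = config["enumeration"]
            kwargs["enumeration"] = EnumerationSettings(
                increment=float(e.get("increment", 0.01)),
                tolerance=float(e.get("tolerance", 0.1)),
                deviation_metric=e.get("deviation_metric", "per_isotope_max"),
            )
        if "exclusions" in config:
            kwargs["exclusions"] = ExclusionList.from_config(config["exclusions"])
        for key in ("sd_multiplier", "alpha"):
            if key in config:
                kwargs[key] = float(config[key])
        if "total_units" in config:
            kwargs["total_units"] = int(config["total_units"])
        return cls(**kwargs)


@dataclass(frozen=True)
class RunResult:
    """Outcome of one plan cell.

    ``status`` is ``ok``, ``infeasible`` (geometry valid but no grid
    composition reproduces the mixture within tolerance) or ``na`` (a
    source or the mixture could not be built); ``reason`` explains every
    non-ok cell.
    """

    cell: PlanCell
    status: str
    reason: str = ""
    summary: Mapping[str, Mapping[str, float]] | None = None  # source -> stats, 0..1
    n_solutions: int = 0
    min_deviation: float | None = None
    tolerance_used: float | None = None
    mixture: tuple | None = None
    n_hominids: int = 0
    vertices: tuple | None = None
    mixture_inside: bool | None = None
    roles_ok: bool | None = None

    @property
    def mean_proportions(self) -> tuple | None:
        if self.summary is None:
            return None
        return tuple(self.summary[s.value]["mean"] for s in SOURCE_ORDER)


def _associated_hominids(
    hominids: Sequence[IsotopeRecord], fauna: Sequence[IsotopeRecord]
) -> list[IsotopeRecord]:
    fauna_sites = {r.site for r in fauna}
    return [r for r in hominids if r.site in fauna_sites]


def run_cell(
    records: Sequence[IsotopeRecord], cell: PlanCell, config: AnalysisConfig
) -> RunResult:
    """Run one simulation cell; never raises for missing data."""
    cluster = scope_cluster(cell.scope)
    fauna_chrono = COHORT_FAUNA_CHRONO[cell.cohort]
    kept = apply_exclusions(records, config.exclusions)
    fauna_all = subset_cohort(kept, cluster, fauna_chrono, HERBIVORE_TAXA)
    hominids = subset_cohort(
        kept, cluster, ChronoGroup(cell.cohort), {COHORT_HOMINID_TAXON[cell.cohort]}
    )
    if cell.hominids is HominidCondition.ASSOCIATED:
        hominids = _associated_hominids(hominids, fauna_all)
    try:
        meat = herbivore_source(
            fauna_all, FAUNA_SETS[cell.fauna], dn_shift_sd=cell.dn_shift
        )
        plants = estimate_plant_source(meat, config.plant_offsets)
        mixture = diet_space_mixture(hominids, config.offsets, cell.hominids)
        geometry = build_geometry(
            config.fish,
            meat,
            plants,
            mixture,
            mode=cell.geometry,
            sd_multiplier=config.sd_multiplier,
        )
    except MissingSourceError as exc:
        return RunResult(cell=cell, status="na", reason=f"missing source: {exc}")
    except MissingMixtureError as exc:
        return RunResult(cell=cell, status="na", reason=f"missing mixture: {exc}")
    except DegenerateGeometryError as exc:
        return RunResult(cell=cell, status="na", reason=f"degenerate geometry: {exc}")

    settings = config.enumeration
    feasible = enumerate_feasible(geometry, settings)
    while not feasible.feasible and settings.tolerance < config.max_tolerance:
        settings = EnumerationSettings(
            increment=settings.increment,
            tolerance=min(
                settings.tolerance * config.tolerance_factor, config.max_tolerance
            ),
            deviation_metric=settings.deviation_metric,
        )
        feasible = enumerate_feasible(geometry, settings)
    base = dict(
        cell=cell,
        mixture=geometry.mixture.point,
        n_hominids=geometry.mixture.n_hominids,
        vertices=geometry.vertices,
        mixture_inside=geometry.mixture_inside,
        roles_ok=geometry.roles_ok,
        min_deviation=feasible.min_deviation,
        tolerance_used=settings.tolerance,
    )
    if not feasible.feasible:
        return RunResult(
            status="infeasible",
            reason=(
                f"no grid composition within tolerance <= {settings.tolerance:g} "
                f"(minimum deviation {feasible.min_deviation:.3f} per mil)"
            ),
            **base,
        )
    summary = {
        name.value: {
            "mean": s.mean,
            "min": s.minimum,
            "max": s.maximum,
            "p01": s.p01,
            "p99": s.p99,
        }
        for name, s in feasible.summary().items()
    }
    return RunResult(
        status="ok", summary=summary, n_solutions=feasible.n_solutions, **base
    )


def run_plan(
    records: Sequence[IsotopeRecord],
    plan: SimulationPlan,
    config: AnalysisConfig | None = None,
) -> list[RunResult]:
    """One RunResult per enabled plan cell, in plan order."""
    config = config or AnalysisConfig()
    return [run_cell(records, cell, config) for cell in plan.cells]


def _condition_key(cell: PlanCell) -> tuple:
    return (cell.scope, cell.fauna, cell.hominids, cell.dn_shift, cell.geometry)


def _condition_label(key: tuple) -> str:
    scope, fauna, hominids, shift, geometry = key
    shift_txt = {0.0: "", -1.0: " d15N-1SD", 1.0: " d15N+1SD"}[shift]
    return (
        f"{scope.value} | {geometry.value} | {fauna.value}{shift_txt} | {hominids.value}"
    )


def compare_cohorts(
    results: Sequence[RunResult], config: AnalysisConfig | None = None
) -> list[dict]:
    """Pairwise chi-squared comparisons per condition across cohorts.

    Returns one dict per condition with the three pairwise results; cohorts
    without an ok result in that condition propagate as NA.
    """
    config = config or AnalysisConfig()
    by_condition: dict[tuple, dict[str, RunResult]] = {}
    for res in results:
        by_condition.setdefault(_condition_key(res.cell), {})[res.cell.cohort] = res
    rows = []
    for key in by_condition:
        cohort_props = {
            cohort: (res.mean_proportions if res.status == "ok" else None)
            for cohort, res in by_condition[key].items()
        }
        label = _condition_label(key)
        pair_results = compare_all_pairs(
            cohort_props,
            condition_label=label,
            alpha=config.alpha,
            total_units=config.total_units,
        )
        rows.append({"condition": label, "pairs": pair_results})
    return rows


def _pct(x: float) -> int:
    return int(round(100.0 * x))


def _results_frame(results: Sequence[RunResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        row: dict = {
            "cohort": res.cell.cohort,
            "scope": res.cell.scope.value,
            "fauna": res.cell.fauna.value,
            "hominids": res.cell.hominids.value,
            "dn_shift": res.cell.dn_shift,
            "geometry": res.cell.geometry.value,
            "status": res.status,
            "n_hominids": res.n_hominids,
            "n_solutions": res.n_solutions,
            "tolerance_used": res.tolerance_used,
            "reason": res.reason,
        }
        for name in SOURCE_ORDER:
            if res.summary is None:
                row[f"{name.value}_mean_pct"] = "NA"
                row[f"{name.value}_range_pct"] = "NA"
            else:
                s = res.summary[name.value]
                row[f"{name.value}_mean_pct"] = _pct(s["mean"])
                row[f"{name.value}_range_pct"] = f"{_pct(s['min'])}-{_pct(s['max'])}"
        rows.append(row)
    return pd.DataFrame(rows)


def _comparison_frame(comparisons: Sequence[Mapping]) -> pd.DataFrame:
    rows = []
    for item in comparisons:
        row = {"condition": item["condition"]}
        for pair in item["pairs"]:
            if pair.is_na:
                row[pair.pair] = "NA"
            else:
                star = "*" if pair.significant else ""
                row[pair.pair] = f"{pair.pvalue:.6f}{star}"
        rows.append(row)
    return pd.DataFrame(rows)


def _to_jsonable(results, comparisons) -> dict:
    return {
        "results": [
            {
                "cell": res.cell.to_config(),
                "status": res.status,
                "reason": res.reason,
                "summary": res.summary,
                "n_solutions": res.n_solutions,
                "min_deviation": res.min_deviation,
                "tolerance_used": res.tolerance_used,
                "mixture": list(res.mixture) if res.mixture else None,
                "n_hominids": res.n_hominids,
                "vertices": [list(v) for v in res.vertices] if res.vertices else None,
                "mixture_inside": res.mixture_inside,
                "roles_ok": res.roles_ok,
            }
            for res in results
        ],
        "comparisons": [
            {
                "condition": item["condition"],
                "pairs": [
                    {
                        "pair": p.pair,
                        "statistic": p.statistic,
                        "df": p.df,
                        "pvalue": p.pvalue,
                        "significant": p.significant,
                        "threshold": p.threshold,
                        "note": p.note,
                    }
                    for p in item["pairs"]
                ],
            }
            for item in comparisons
        ],
    }


def render_reports(
    results: Sequence[RunResult],
    comparisons: Sequence[Mapping],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write contributions.tsv, comparisons.tsv and results.json.

    The TSV tables are derived purely from the JSON payload so the text
    reports can be regenerated from stored JSON byte-for-byte.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = _to_jsonable(results, comparisons)
    json_path = out_dir / "results.json"
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    paths = _render_from_payload(payload, out_dir)
    paths["json"] = json_path
    n_na = sum(1 for r in results if r.status != "ok")
    if results and n_na == len(results):
        (out_dir / "WARNINGS.txt").write_text(
            "all plan cells produced NA/infeasible results; "
            "check sources, exclusions and cohort coverage\n"
        )
    return paths


def _render_from_payload(payload: Mapping, out_dir: Path) -> dict[str, Path]:
    results = [_result_from_json(item) for item in payload["results"]]
    contrib = _results_frame(results)
    contrib_path = out_dir / "contributions.tsv"
    contrib.to_csv(contrib_path, sep="\t", index=False)
    comp_rows = []
    for item in payload["comparisons"]:
        row = {"condition": item["condition"]}
        for p in item["pairs"]:
            if p["pvalue"] is None:
                row[p["pair"]] = "NA"
            else:
                star = "*" if p["significant"] else ""
                row[p["pair"]] = f"{p['pvalue']:.6f}{star}"
        comp_rows.append(row)
    comp_path = out_dir / "comparisons.tsv"
    pd.DataFrame(comp_rows).to_csv(comp_path, sep="\t", index=False)
    return {"contributions": contrib_path, "comparisons": comp_path}


def _result_from_json(item: Mapping) -> RunResult:
    return RunResult(
        cell=PlanCell(**item["cell"]),
        status=item["status"],
        reason=item.get("reason", ""),
        summary=item.get("summary"),
        n_solutions=item.get("n_solutions", 0),
        min_deviation=item.get("min_deviation"),
        tolerance_used=item.get("tolerance_used"),
        mixture=tuple(item["mixture"]) if item.get("mixture") else None,
        n_hominids=item.get("n_hominids", 0),
        vertices=tuple(tuple(v) for v in item["vertices"]) if item.get("vertices") else None,
        mixture_inside=item.get("mixture_inside"),
        roles_ok=item.get("roles_ok"),
    )


def reports_from_json(json_path: str | Path, out_dir: str | Path) -> dict[str, Path]:
    """Regenerate the TSV reports from a stored results.json."""
    payload = json.loads(Path(json_path).read_text())
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    return _render_from_payload(payload, out_dir)
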