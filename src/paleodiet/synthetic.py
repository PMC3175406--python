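"""Synthetic trophic-web generator with known true diets.

Emulates the structure the analysis assumes for a late-Pleistocene
terrestrial/aquatic food web: plants at the baseline, herbivores one
trophic step up, carnivores and freshwater fish above them, and hominid
cohorts whose collagen records a known mixture of fish, herbivore meat and
plants plus diet-to-collagen enrichment.  Compartment δ¹³C/δ¹⁵N ranges
follow the Palaeolithic literature values (plants −35..−20 / 0..6 ‰,
herbivores −30..−18 / 3..8 ‰, carnivores −24..−16 / 7..13 ‰, freshwater
fish −23..−19 / 9..15 ‰).  Faunal values are drawn by truncated-normal
rejection sampling inside their compartment range around per-taxon means;
per-site offsets can plant heterogeneity for screening tests.  Every
dataset ships with a truth record (true diets, source signatures, planted
shifts) so downstream stages can be validated end to end.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import truncnorm

from .records import (
    ChronoGroup,
    Environment,
    Geography,
    IsotopeRecord,
    Taxon,
    write_records,
)
from .sources import (
    COLLAGEN_DIET_OFFSETS,
    FractionationOffsets,
    SourceName,
    SourceProvenance,
    SourceSignature,
)

__all__ = [
    "COMPARTMENT_RANGES",
    "SiteSpec",
    "PlantedShift",
    "FoodwebParams",
    "SyntheticTruth",
    "GenerationError",
    "generate_foodweb",
    "plant_site_shift",
    "write_dataset",
]

#: Palaeolithic compartment ranges, per mil: name -> ((C lo, C hi), (N lo, N hi)).
COMPARTMENT_RANGES: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "plants": ((-35.0, -20.0), (0.0, 6.0)),
    "herbivores": ((-30.0, -18.0), (3.0, 8.0)),
    "carnivores": ((-24.0, -16.0), (7.0, 13.0)),
    "freshwater_fish": ((-23.0, -19.0), (9.0, 15.0)),
}

#: Default per-taxon collagen means (δ¹³C, δ¹⁵N).  Glacial European
#: herbivores sit at the ¹³C-enriched end of the herbivore compartment.
DEFAULT_TAXON_MEANS: dict[Taxon, tuple[float, float]] = {
    Taxon.REINDEER: (-18.8, 4.8),
    Taxon.HORSE: (-20.4, 5.6),
    Taxon.BOVID: (-19.6, 6.2),
}

DEFAULT_FISH_SIGNATURE = SourceSignature(
    name=SourceName.FISH,
    mean_d13C=-20.0,
    sd_d13C=0.5,
    mean_d15N=12.0,
    sd_d15N=1.0,
    provenance=SourceProvenance.LITERATURE,
)

#: True diet proportions (fish, meat, plants) per hominid cohort.
DEFAULT_DIET_TRUTH: dict[str, tuple[float, float, float]] = {
    "MOIS3_N": (0.55, 0.10, 0.35),
    "MOIS3_MH": (0.64, 0.08, 0.28),
    "MOIS2_MH": (0.35, 0.45, 0.20),
}

#: Hominid sample sizes per cohort, scaled down (~half) from the published
#: cohort sizes (19 Neanderthals, 61 modern humans split across two stages).
DEFAULT_HOMINID_N: dict[str, int] = {"MOIS3_N": 10, "MOIS3_MH": 8, "MOIS2_MH": 20}

HOMINID_TAXON = {
    "MOIS3_N": Taxon.NEANDERTHAL,
    "MOIS3_MH": Taxon.MODERN_HUMAN,
    "MOIS2_MH": Taxon.MODERN_HUMAN,
}

FAUNA_CHRONO = (ChronoGroup.FAUNA_MOIS3, ChronoGroup.FAUNA_MOIS2)


class GenerationError(ValueError):
    pass


@dataclass(frozen=True)
class SiteSpec:
    name: str
    geography: Geography
    environment: Environment
    has_fauna: bool = True
    hominid_cohorts: tuple = ()


DEFAULT_SITES: tuple[SiteSpec, ...] = (
    SiteSpec("NW-A", Geography.NORTHWEST, Environment.TUNDRA_STEPPE, True,
             ("MOIS3_N", "MOIS3_MH", "MOIS2_MH")),
    SiteSpec("NW-B", Geography.NORTHWEST, Environment.OPEN_BOREAL_WOODLAND, True, ()),
    SiteSpec("SW-A", Geography.SOUTHWEST, Environment.COLD_STEPPE, True,
             ("MOIS3_N", "MOIS3_MH", "MOIS2_MH")),
    SiteSpec("SW-B", Geography.SOUTHWEST, Environment.TUNDRA_STEPPE, True,
             ("MOIS3_N", "MOIS3_MH", "MOIS2_MH")),
    SiteSpec("SW-C", Geography.SOUTHWEST, Environment.WOODED_STEPPE, True, ()),
    SiteSpec("CE-A", Geography.CENTRAL, Environment.TUNDRA_BOREAL_WOODLAND, True, ()),
    # Hominid-only site: makes the whole- vs associated-hominids conditions differ.
    SiteSpec("SW-H", Geography.SOUTHWEST, Environment.OPEN_BOREAL_WOODLAND, False,
             ("MOIS3_N", "MOIS3_MH", "MOIS2_MH")),
)


@dataclass(frozen=True)
class PlantedShift:
    taxon: Taxon
    site: str
    isotope: str  # "d13C" or "d15N"
    delta: float


@dataclass(frozen=True)
class FoodwebParams:
    """Everything the generator needs; identical params + seed reproduce
    byte-identical output."""

    seed: int = 0
    compartments: Mapping[str, tuple] = field(
        default_factory=lambda: dict(COMPARTMENT_RANGES)
    )
    taxon_means: Mapping[Taxon, tuple] = field(
        default_factory=lambda: dict(DEFAULT_TAXON_MEANS)
    )
    fauna_n_per_site: int = 8
    noise_sd: tuple = (0.5, 0.8)  # (δ¹³C, δ¹⁵N) faunal between-individual scatter
    # Hominids within a cohort share one true diet, so their residual scatter
    # is analytical + physiological only, smaller than faunal ecological spread.
    hominid_noise_sd: tuple = (0.3, 0.4)
    sites: tuple = DEFAULT_SITES
    planted_shifts: tuple = ()
    diet_truth: Mapping[str, tuple] = field(
        default_factory=lambda: dict(DEFAULT_DIET_TRUTH)
    )
    hominid_n: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_HOMINID_N))
    fish_signature: SourceSignature = DEFAULT_FISH_SIGNATURE
    offsets: FractionationOffsets = COLLAGEN_DIET_OFFSETS
    plant_offsets: FractionationOffsets = COLLAGEN_DIET_OFFSETS

    def validate(self) -> None:
        for name, (crange, nrange) in self.compartments.items():
            if crange[1] < crange[0] or nrange[1] < nrange[0]:
                raise GenerationError(f"compartment {name} has a reversed range")
        if self.fauna_n_per_site < 0 or any(n < 0 for n in self.hominid_n.values()):
            raise GenerationError("sample sizes must be non-negative")
        crange, nrange = self.compartments["herbivores"]
        widths = {"d13C": crange[1] - crange[0], "d15N": nrange[1] - nrange[0]}
        for shift in self.planted_shifts:
            if abs(shift.delta) > widths[shift.isotope]:
                raise GenerationError(
                    f"planted shift {shift.delta} per mil exceeds the "
                    f"{shift.isotope} compartment width {widths[shift.isotope]}"
                )
        site_names = {s.name for s in self.sites}
        for shift in self.planted_shifts:
            if shift.site not in site_names:
                raise GenerationError(f"unknown site in planted shift: {shift.site}")
        for cohort, p in self.diet_truth.items():
            arr = np.asarray(p, float)
            if arr.shape != (3,) or np.any(arr < 0) or abs(arr.sum() - 1.0) > 1e-9:
                raise GenerationError(f"diet_truth for {cohort} is not on the simplex")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth written alongside every generated dataset."""

    seed: int
    diet_truth: Mapping[str, tuple]
    source_signatures: Mapping[str, Mapping[str, float]]
    planted_shifts: tuple
    per_taxon_n: Mapping[str, int]
    hominid_mixtures: Mapping[str, tuple]  # noise-free diet-space points

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "diet_truth": {k: list(v) for k, v in self.diet_truth.items()},
            "source_signatures": {k: dict(v) for k, v in self.source_signatures.items()},
            "planted_shifts": [
                {
                    "taxon": s.taxon.value,
                    "site": s.site,
                    "isotope": s.isotope,
                    "delta": s.delta,
                }
                for s in self.planted_shifts
            ],
            "per_taxon_n": dict(self.per_taxon_n),
            "hominid_mixtures": {k: list(v) for k, v in self.hominid_mixtures.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _truncated_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    lo: float,
    hi: float,
    n: int,
) -> np.ndarray:
    """n normal draws truncated to [lo, hi] (exact truncated normal)."""
    if sd == 0.0:
        if not (lo <= mean <= hi):
            raise GenerationError(
                f"noise-free mean {mean} outside compartment range [{lo}, {hi}]"
            )
        return np.full(n, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _true_sources(params: FoodwebParams) -> dict[str, SourceSignature]:
    """Noise-free source signatures implied by the parameters.

    Meat is the unweighted average of the per-taxon means — the same rule
    the analysis applies to generated records — and plants subtract the
    herbivore-over-plant point offsets from it.
    """
    means = np.array([params.taxon_means[t] for t in sorted(params.taxon_means, key=lambda t: t.value)])
    meat_c, meat_n = means.mean(axis=0)
    meat = SourceSignature(
        name=SourceName.MEAT,
        mean_d13C=float(meat_c),
        sd_d13C=0.0,
        mean_d15N=float(meat_n),
        sd_d15N=0.0,
        provenance=SourceProvenance.DERIVED_FROM_HERBIVORES,
    )
    plants = SourceSignature(
        name=SourceName.PLANTS,
        mean_d13C=meat.mean_d13C - params.plant_offsets.dC_point,
        sd_d13C=0.0,
        mean_d15N=meat.mean_d15N - params.plant_offsets.dN_point,
        sd_d15N=0.0,
        provenance=SourceProvenance.DERIVED_FROM_HERBIVORES,
    )
    return {"fish": params.fish_signature, "meat": meat, "plants": plants}


def generate_foodweb(
    params: FoodwebParams,
) -> tuple[list[IsotopeRecord], SyntheticTruth]:
    """Generate faunal and hominid records plus the ground-truth record.

    Fauna: for every fauna-bearing site, both stage-level chronological
    groups and every taxon with a mean, ``fauna_n_per_site`` values drawn
    by truncated-normal rejection inside the herbivore compartment around
    the taxon mean plus any per-site planted shift.  Hominids: collagen =
    Σ p_true · source + diet-to-collagen point offsets + noise.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    crange, nrange = params.compartments["herbivores"]
    sd_c, sd_n = params.noise_sd

    shift_map: dict[tuple[Taxon, str], dict[str, float]] = {}
    for s in params.planted_shifts:
        shift_map.setdefault((s.taxon, s.site), {}).setdefault(s.isotope, 0.0)
        shift_map[(s.taxon, s.site)][s.isotope] += s.delta

    records: list[IsotopeRecord] = []
    per_taxon_n: dict[str, int] = {}
    for site in params.sites:
        if not site.has_fauna:
            continue
        for chrono in FAUNA_CHRONO:
            for taxon in sorted(params.taxon_means, key=lambda t: t.value):
                mc, mn = params.taxon_means[taxon]
                shifts = shift_map.get((taxon, site.name), {})
                mc += shifts.get("d13C", 0.0)
                mn += shifts.get("d15N", 0.0)
                n = params.fauna_n_per_site
                vals_c = _truncated_normal(rng, mc, sd_c, *crange, n)
                vals_n = _truncated_normal(rng, mn, sd_n, *nrange, n)
                for i in range(n):
                    records.append(
                        IsotopeRecord(
                            specimen_id=f"{taxon.value}-{site.name}-{chrono.value}-{i:03d}",
                            taxon=taxon,
                            site=site.name,
                            d13C=round(float(vals_c[i]), 4),
                            d15N=round(float(vals_n[i]), 4),
                            chrono_group=chrono,
                            geography=site.geography,
                            environment=site.environment,
                            associated_with_hominids=bool(site.hominid_cohorts),
                        )
                    )
                per_taxon_n[taxon.value] = per_taxon_n.get(taxon.value, 0) + n

    sources = _true_sources(params)
    src_mat = np.array(
        [sources["fish"].mean, sources["meat"].mean, sources["plants"].mean]
    )
    hominid_mixtures: dict[str, tuple] = {}
    for cohort in ("MOIS3_N", "MOIS3_MH", "MOIS2_MH"):
        if cohort not in params.diet_truth:
            continue
        p = np.asarray(params.diet_truth[cohort], float)
        mix = p @ src_mat  # noise-free diet-space point
        hominid_mixtures[cohort] = (float(mix[0]), float(mix[1]))
        collagen = mix + np.array([params.offsets.dC_point, params.offsets.dN_point])
        cohort_sites = [s for s in params.sites if cohort in s.hominid_cohorts]
        if not cohort_sites and params.hominid_n.get(cohort, 0) > 0:
            raise GenerationError(f"no sites host cohort {cohort}")
        taxon = HOMINID_TAXON[cohort]
        n = params.hominid_n.get(cohort, 0)
        hsd_c, hsd_n = params.hominid_noise_sd
        noise_c = rng.normal(0.0, hsd_c, size=n) if hsd_c > 0 else np.zeros(n)
        noise_n = rng.normal(0.0, hsd_n, size=n) if hsd_n > 0 else np.zeros(n)
        for i in range(n):
            site = cohort_sites[i % len(cohort_sites)]
            records.append(
                IsotopeRecord(
                    specimen_id=f"{cohort}-{site.name}-{i:03d}",
                    taxon=taxon,
                    site=site.name,
                    d13C=round(float(collagen[0] + noise_c[i]), 4),
                    d15N=round(float(collagen[1] + noise_n[i]), 4),
                    chrono_group=ChronoGroup(cohort),
                    geography=site.geography,
                    environment=site.environment,
                    associated_with_hominids=False,
                )
            )
        per_taxon_n[taxon.value] = per_taxon_n.get(taxon.value, 0) + n

    truth = SyntheticTruth(
        seed=params.seed,
        diet_truth={k: tuple(v) for k, v in params.diet_truth.items()},
        source_signatures={
            name: {
                "mean_d13C": sig.mean_d13C,
                "sd_d13C": sig.sd_d13C,
                "mean_d15N": sig.mean_d15N,
                "sd_d15N": sig.sd_d15N,
            }
            for name, sig in sources.items()
        },
        planted_shifts=tuple(params.planted_shifts),
        per_taxon_n=per_taxon_n,
        hominid_mixtures=hominid_mixtures,
    )
    return records, truth


def plant_site_shift(
    params: FoodwebParams,
    taxon: Taxon,
    site: str,
    delta: float,
    isotope: str = "d15N",
) -> FoodwebParams:
    """Return params whose generated data shifts one (taxon, site) mean.

    The shift is recorded in the truth so screening tests know which site
    was planted.  Unknown sites are rejected."""
    if site not in {s.name for s in params.sites}:
        raise GenerationError(f"unknown site: {site}")
    if isotope not in ("d13C", "d15N"):
        raise GenerationError(f"unknown isotope: {isotope}")
    shift = PlantedShift(taxon=Taxon(taxon), site=site, isotope=isotope, delta=delta)
    new = replace(params, planted_shifts=params.planted_shifts + (shift,))
    new.validate()
    return new


def write_dataset(
    params: FoodwebParams, out_dir: str | Path
) -> tuple[Path, Path]:
    """Generate and write records.csv + truth.json; returns the two paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records, truth = generate_foodweb(params)
    records_path = out_dir / "records.csv"
    truth_path = out_dir / "truth.json"
    write_records(records, records_path)
    truth.to_json(truth_path)
    return records_path, truth_path
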