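"""Specimen-level collagen isotope records: data model, I/O, cohort subsetting.

Each record is one specimen's bone-collagen δ¹³C (per mil vs VPDB) and δ¹⁵N
(per mil vs AIR) plus the categorical labels the analysis partitions on:
taxon, archaeological site, chronological group, geographic region and
environment class.  Records live in flat CSV/TSV files with a fixed header;
loading validates every row and reports rejects with their row number and
reason rather than failing the whole file.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Taxon",
    "ChronoGroup",
    "Geography",
    "Environment",
    "IsotopeRecord",
    "ClusterSpec",
    "ClusterMode",
    "Inventory",
    "Rejection",
    "SchemaError",
    "REQUIRED_COLUMNS",
    "HERBIVORE_TAXA",
    "HOMINID_TAXA",
    "D13C_WINDOW",
    "D15N_WINDOW",
    "load_records",
    "write_records",
    "write_rejections",
    "subset_cohort",
    "summarize_inventory",
    "records_to_frame",
]


class Taxon(str, enum.Enum):
    REINDEER = "reindeer"
    HORSE = "horse"
    BOVID = "bovid"
    NEANDERTHAL = "neanderthal"
    MODERN_HUMAN = "modern_human"
    OTHER = "other"


HERBIVORE_TAXA = frozenset({Taxon.REINDEER, Taxon.HORSE, Taxon.BOVID})
HOMINID_TAXA = frozenset({Taxon.NEANDERTHAL, Taxon.MODERN_HUMAN})


class ChronoGroup(str, enum.Enum):
    """Chronological cohort labels.

    MOIS3_N / MOIS3_MH / MOIS2_MH tag hominid specimens (Neanderthals and
    modern humans in late Marine Oxygen Isotope Stage 3, modern humans in
    stage 2); fauna carry the stage-level tags.
    """

    MOIS3_N = "MOIS3_N"
    MOIS3_MH = "MOIS3_MH"
    MOIS2_MH = "MOIS2_MH"
    FAUNA_MOIS3 = "fauna_MOIS3"
    FAUNA_MOIS2 = "fauna_MOIS2"
    UNASSIGNED = "unassigned"


class Geography(str, enum.Enum):
    NORTHWEST = "northwest"
    SOUTHWEST = "southwest"
    CENTRAL = "central"
    UNASSIGNED = "unassigned"


class Environment(str, enum.Enum):
    TUNDRA_STEPPE = "tundra_steppe"
    OPEN_BOREAL_WOODLAND = "open_boreal_woodland"
    TUNDRA_BOREAL_WOODLAND = "tundra_boreal_woodland"
    STEPPE = "steppe"
    COLD_STEPPE = "cold_steppe"
    WOODED_STEPPE = "wooded_steppe"
    TEMPERATE_FOREST = "temperate_forest"
    WARM_WOODED_STEPPE = "warm_wooded_steppe"
    UNDEFINED = "undefined"


# Sanity windows around the Palaeolithic compartment ranges; values outside
# are almost certainly unit or sign errors and are rejected at load.
D13C_WINDOW = (-40.0, -5.0)
D15N_WINDOW = (-5.0, 25.0)

REQUIRED_COLUMNS = (
    "specimen_id",
    "taxon",
    "site",
    "d13C",
    "d15N",
    "chrono_group",
    "geography",
    "environment",
)
OPTIONAL_COLUMNS = ("associated_with_hominids",)

_TRUE_STRINGS = {"true", "1", "yes", "t"}
_FALSE_STRINGS = {"false", "0", "no", "f", ""}


class SchemaError(ValueError):
    """The input file does not carry the required column header."""


@dataclass(frozen=True)
class IsotopeRecord:
    """One specimen's collagen isotope measurement with its labels."""

    specimen_id: str
    taxon: Taxon
    site: str
    d13C: float
    d15N: float
    chrono_group: ChronoGroup
    geography: Geography
    environment: Environment
    associated_with_hominids: bool = False


@dataclass(frozen=True)
class Rejection:
    """A row that failed validation, with its 1-based data row number."""

    row: int
    reason: str


class ClusterMode(str, enum.Enum):
    GLOBAL = "global"
    GEOGRAPHIC = "geographic"
    ENVIRONMENTAL = "environmental"


@dataclass(frozen=True)
class ClusterSpec:
    """A spatial restriction of the dataset.

    ``global`` keeps everything; ``geographic`` keeps records whose
    geography label is in ``included_labels``; ``environmental`` filters on
    the environment label instead.
    """

    mode: ClusterMode
    included_labels: frozenset = frozenset()

    def __post_init__(self) -> None:
        mode = ClusterMode(self.mode)
        object.__setattr__(self, "mode", mode)
        labels = frozenset(self.included_labels)
        if mode is ClusterMode.GLOBAL:
            if labels:
                raise ValueError("global cluster must have no included labels")
        else:
            if not labels:
                raise ValueError(f"{mode.value} cluster needs included labels")
            coerced = set()
            for lab in labels:
                if mode is ClusterMode.GEOGRAPHIC:
                    coerced.add(Geography(lab))
                else:
                    coerced.add(Environment(lab))
            labels = frozenset(coerced)
        object.__setattr__(self, "included_labels", labels)

    def matches(self, record: IsotopeRecord) -> bool:
        if self.mode is ClusterMode.GLOBAL:
            return True
        if self.mode is ClusterMode.GEOGRAPHIC:
            return record.geography in self.included_labels
        return record.environment in self.included_labels


@dataclass(frozen=True)
class Inventory:
    """Record counts per taxon and per spatial subcluster."""

    taxon_counts: dict
    geography_counts: dict
    environment_counts: dict
    total: int

    def __post_init__(self) -> None:
        if sum(self.taxon_counts.values()) != self.total:
            raise ValueError("taxon counts do not sum to total")
        for counts in (self.geography_counts, self.environment_counts):
            if counts and sum(counts.values()) != self.total:
                raise ValueError("subcluster counts do not sum to total")

    @classmethod
    def from_taxon_counts(cls, taxon_counts: dict) -> "Inventory":
        """Inventory from per-taxon counts alone (no spatial breakdown)."""
        counts = {Taxon(k): int(v) for k, v in taxon_counts.items()}
        return cls(
            taxon_counts=counts,
            geography_counts={},
            environment_counts={},
            total=sum(counts.values()),
        )


def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def _parse_float(text: str, what: str) -> float:
    # Accept the unicode minus that shows up in copied tables.
    cleaned = text.strip().replace("−", "-")
    try:
        return float(cleaned)
    except ValueError:
        raise ValueError(f"non-numeric {what}: {text!r}") from None


def _parse_bool(text: str) -> bool:
    low = str(text).strip().lower()
    if low in _TRUE_STRINGS:
        return True
    if low in _FALSE_STRINGS or low == "nan":
        return False
    raise ValueError(f"unparseable boolean: {text!r}")


def _parse_row(row: pd.Series, has_assoc: bool) -> IsotopeRecord:
    d13c = _parse_float(str(row["d13C"]), "d13C")
    d15n = _parse_float(str(row["d15N"]), "d15N")
    if not (D13C_WINDOW[0] <= d13c <= D13C_WINDOW[1]):
        raise ValueError(f"d13C {d13c} outside sanity window {D13C_WINDOW}")
    if not (D15N_WINDOW[0] <= d15n <= D15N_WINDOW[1]):
        raise ValueError(f"d15N {d15n} outside sanity window {D15N_WINDOW}")
    try:
        taxon = Taxon(str(row["taxon"]).strip())
    except ValueError:
        raise ValueError(f"unknown taxon: {row['taxon']!r}") from None
    try:
        chrono = ChronoGroup(str(row["chrono_group"]).strip())
    except ValueError:
        raise ValueError(f"unknown chrono_group: {row['chrono_group']!r}") from None
    try:
        geography = Geography(str(row["geography"]).strip())
    except ValueError:
        raise ValueError(f"unknown geography: {row['geography']!r}") from None
    env_text = str(row["environment"]).strip()
    try:
        environment = Environment(env_text)
    except ValueError:
        # The compilation itself carries many 'Undefined' environments, so an
        # unrecognised label degrades to undefined rather than losing the row.
        warnings.warn(
            f"unknown environment {env_text!r} mapped to 'undefined'",
            stacklevel=3,
        )
        environment = Environment.UNDEFINED
    assoc = _parse_bool(row["associated_with_hominids"]) if has_assoc else False
    return IsotopeRecord(
        specimen_id=str(row["specimen_id"]).strip(),
        taxon=taxon,
        site=str(row["site"]).strip(),
        d13C=d13c,
        d15N=d15n,
        chrono_group=chrono,
        geography=geography,
        environment=environment,
        associated_with_hominids=assoc,
    )


def load_records(
    path: str | Path, sep: str | None = None
) -> tuple[list[IsotopeRecord], list[Rejection]]:
    """Load specimen records from a delimited text file.

    Returns ``(records, rejections)``; ``rejections`` carries the 1-based
    data-row number and reason for every row that failed validation.  A
    missing required column raises :class:`SchemaError`.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path, sep), dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    has_assoc = "associated_with_hominids" in frame.columns
    records: list[IsotopeRecord] = []
    rejections: list[Rejection] = []
    for idx, row in frame.iterrows():
        try:
            records.append(_parse_row(row, has_assoc))
        except ValueError as exc:
            rejections.append(Rejection(row=int(idx) + 1, reason=str(exc)))
    if rejections:
        logger.info("load_records: %d row(s) rejected", len(rejections))
    return records, rejections


def records_to_frame(records: Iterable[IsotopeRecord]) -> pd.DataFrame:
    rows = [
        {
            "specimen_id": r.specimen_id,
            "taxon": r.taxon.value,
            "site": r.site,
            "d13C": r.d13C,
            "d15N": r.d15N,
            "chrono_group": r.chrono_group.value,
            "geography": r.geography.value,
            "environment": r.environment.value,
            "associated_with_hominids": r.associated_with_hominids,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS) + list(OPTIONAL_COLUMNS))


def write_records(records: Sequence[IsotopeRecord], path: str | Path, sep: str | None = None) -> None:
    """Write records in the same schema :func:`load_records` reads."""
    path = Path(path)
    frame = records_to_frame(records)
    frame["associated_with_hominids"] = frame["associated_with_hominids"].map(
        {True: "true", False: "false"}
    )
    frame.to_csv(path, sep=_sep_for(path, sep), index=False, float_format="%.6g")


def write_rejections(rejections: Sequence[Rejection], path: str | Path) -> None:
    pd.DataFrame(
        [{"row": r.row, "reason": r.reason} for r in rejections],
        columns=["row", "reason"],
    ).to_csv(path, sep="\t", index=False)


def subset_cohort(
    records: Iterable[IsotopeRecord],
    cluster: ClusterSpec,
    chrono: ChronoGroup | Iterable[ChronoGroup],
    taxa: Iterable[Taxon],
) -> list[IsotopeRecord]:
    """Records matching a spatial cluster, chronological group(s) and taxa.

    ``unassigned`` chronology never matches any cohort.  An empty result is
    legal and returned as an empty list.
    """
    if isinstance(chrono, ChronoGroup):
        chrono_set = {chrono}
    else:
        chrono_set = {ChronoGroup(c) for c in chrono}
    chrono_set.discard(ChronoGroup.UNASSIGNED)
    taxa_set = {Taxon(t) for t in taxa}
    return [
        r
        for r in records
        if r.taxon in taxa_set and r.chrono_group in chrono_set and cluster.matches(r)
    ]


def summarize_inventory(records: Iterable[IsotopeRecord]) -> Inventory:
    """Count records per taxon and per geographic/environmental subcluster."""
    taxon_counts: dict = {}
    geo_counts: dict = {}
    env_counts: dict = {}
    total = 0
    for r in records:
        total += 1
        taxon_counts[r.taxon] = taxon_counts.get(r.taxon, 0) + 1
        geo_counts[r.geography] = geo_counts.get(r.geography, 0) + 1
        env_counts[r.environment] = env_counts.get(r.environment, 0) + 1
    return Inventory(
        taxon_counts=taxon_counts,
        geography_counts=geo_counts,
        environment_counts=env_counts,
        total=total,
    )
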