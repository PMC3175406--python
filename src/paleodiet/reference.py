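"""Published desk-scale reference inputs for the European MOIS3/MOIS2 study.

These are the printed inventory counts and site exclusions from the
compiled literature database (the per-specimen supplement itself is not
redistributed): per-taxon specimen counts of the retained compilation and
the divergent archaeological sites excluded before source construction.
"""

from __future__ import annotations

from .records import Inventory, Taxon
from .screening import ExclusionEntry, ExclusionList

__all__ = [
    "PUBLISHED_TAXON_COUNTS",
    "published_inventory",
    "published_exclusions",
]

#: Retained specimens per taxon in the compiled database.
PUBLISHED_TAXON_COUNTS: dict[Taxon, int] = {
    Taxon.REINDEER: 201,
    Taxon.HORSE: 230,
    Taxon.BOVID: 88,
    Taxon.NEANDERTHAL: 19,
    Taxon.MODERN_HUMAN: 61,
}


def published_inventory() -> Inventory:
    """Inventory built from the published per-taxon counts."""
    return Inventory.from_taxon_counts(PUBLISHED_TAXON_COUNTS)


def published_exclusions() -> ExclusionList:
    """Divergent (taxon, site) pairs excluded in the published analysis."""
    return ExclusionList(
        (
            ExclusionEntry(Taxon.BOVID, "Gough's cave", "divergent site (whole dataset)"),
            ExclusionEntry(Taxon.BOVID, "Kendrick's cave", "divergent site (whole dataset)"),
            ExclusionEntry(Taxon.BOVID, "Pont d'Ambon", "divergent site (south-western area)"),
        )
    )
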