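"""The 13 protein-coding genes of the *Apis* mitogenome.

Two default layouts are provided: one for across-species comparisons and
one for within-*A. mellifera* subspecies comparisons (gene lengths differ
slightly because of lineage-specific indels).  Genes are listed in their
5'->3' coding order on the heavy strand; ND5, ND4, ND4L and ND1 are
encoded on the light strand and must be reverse-complemented into sense
orientation before analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

GENE_ORDER: tuple[str, ...] = (
    "ND2", "CO1", "CO2", "ATP8", "ATP6", "CO3", "ND3",
    "ND5", "ND4", "ND4L", "ND6", "CYTB", "ND1",
)

LIGHT_STRAND: frozenset[str] = frozenset({"ND5", "ND4", "ND4L", "ND1"})

#: common annotation synonyms -> canonical gene name
GENE_SYNONYMS: dict[str, str] = {
    "COX1": "CO1", "COI": "CO1", "COX-1": "CO1", "CO I": "CO1",
    "COX2": "CO2", "COII": "CO2",
    "COX3": "CO3", "COIII": "CO3",
    "COB": "CYTB", "CYT B": "CYTB", "CYTB": "CYTB", "CB": "CYTB",
    "NAD1": "ND1", "NAD2": "ND2", "NAD3": "ND3", "NAD4": "ND4",
    "NAD4L": "ND4L", "NAD5": "ND5", "NAD6": "ND6",
    "NADH1": "ND1", "NADH2": "ND2", "NADH3": "ND3", "NADH4": "ND4",
    "NADH4L": "ND4L", "NADH5": "ND5", "NADH6": "ND6",
    "ATP6": "ATP6", "ATPASE6": "ATP6", "ATP8": "ATP8", "ATPASE8": "ATP8",
}


def normalize_gene_name(raw: str) -> str | None:
    """Map an annotation label to a canonical gene name, or None."""
    key = raw.strip().upper().replace("_", "").replace("-", "")
    if key in GENE_ORDER:
        return key
    return GENE_SYNONYMS.get(key)


@dataclass(frozen=True)
class GeneRow:
    name: str
    bases: int
    triplets: int
    strand: str  # "heavy" | "light"

    def __post_init__(self):
        if self.bases != 3 * self.triplets:
            raise ValueError(f"{self.name}: bases {self.bases} != 3 x {self.triplets}")
        expected = "light" if self.name in LIGHT_STRAND else "heavy"
        if self.strand != expected:
            raise ValueError(f"{self.name}: strand must be {expected!r}")


class GeneTable:
    """Ordered expected gene lengths used for layout and length checks."""

    def __init__(self, rows: list[GeneRow]):
        if [r.name for r in rows] != list(GENE_ORDER):
            raise ValueError("gene table must contain the 13 genes in coding order")
        self.rows = tuple(rows)
        self._by_name = {r.name: r for r in rows}

    def __iter__(self) -> Iterator[GeneRow]:
        return iter(self.rows)

    def __getitem__(self, name: str) -> GeneRow:
        return self._by_name[name]

    @property
    def total_bases(self) -> int:
        return sum(r.bases for r in self.rows)


def _table(lengths: dict[str, int]) -> GeneTable:
    return GeneTable(
        [
            GeneRow(g, lengths[g], lengths[g] // 3,
                    "light" if g in LIGHT_STRAND else "heavy")
            for g in GENE_ORDER
        ]
    )


#: across-species layout (11,070 bases / 3,690 triplets)
SPECIES_TABLE = _table({
    "ND2": 1002, "CO1": 1563, "CO2": 678, "ATP8": 162, "ATP6": 681,
    "CO3": 786, "ND3": 354, "ND5": 1668, "ND4": 1314, "ND4L": 264,
    "ND6": 522, "CYTB": 1152, "ND1": 924,
})

#: within-A. mellifera subspecies layout (11,043 bases / 3,681 triplets)
SUBSPECIES_TABLE = _table({
    "ND2": 1002, "CO1": 1560, "CO2": 678, "ATP8": 138, "ATP6": 681,
    "CO3": 780, "ND3": 354, "ND5": 1665, "ND4": 1347, "ND4L": 264,
    "ND6": 504, "CYTB": 1152, "ND1": 918,
})
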