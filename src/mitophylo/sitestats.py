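"""Alignment column classification and coding-region translation.

A column is *parsimony-informative* when at least two states are each
present in at least two taxa; such columns are the only ones that can
discriminate among tree topologies under equal-weight parsimony.
Columns with variation that does not meet this bar are
*variable singletons*; the rest are *constant*.  Cells holding gaps or
unresolved ambiguity codes do not contribute states.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .genome_io import Supermatrix

_BASES = (b"A", b"C", b"G", b"T")

CONSTANT = "constant"
SINGLETON = "variable_singleton"
INFORMATIVE = "parsimony_informative"


@dataclass(frozen=True)
class PositionFilter:
    """Which codon positions an analysis retains."""

    name: str
    retained: frozenset[int]


P123 = PositionFilter("P123", frozenset({1, 2, 3}))
P12 = PositionFilter("P12", frozenset({1, 2}))


@dataclass
class SiteClassification:
    """Per-column categories over the analyzed (retained) columns."""

    columns: np.ndarray              # alignment column indices classified
    categories: dict[int, str]       # column -> category
    minor_state_taxa: dict[int, dict[str, list[str]]]  # col -> state -> taxa

    @property
    def counts(self) -> dict[str, int]:
        c = Counter(self.categories.values())
        return {k: c.get(k, 0) for k in (CONSTANT, SINGLETON, INFORMATIVE)}

    @property
    def n_variable(self) -> int:
        c = self.counts
        return c[SINGLETON] + c[INFORMATIVE]

    @property
    def n_informative(self) -> int:
        return self.counts[INFORMATIVE]

    def informative_columns(self) -> np.ndarray:
        return np.array(
            [c for c in self.columns if self.categories[c] == INFORMATIVE], dtype=int
        )

    def to_frame(self, matrix: Supermatrix | None = None) -> pd.DataFrame:
        rows = []
        for col in self.columns:
            rows.append({
                "column": int(col),
                "gene": matrix.gene_of_column(int(col)) if matrix else None,
                "codon_position": int(matrix.codon_position[col]) if matrix else None,
                "category": self.categories[col],
                "minor_states": ";".join(
                    f"{s}:{','.join(t)}"
                    for s, t in sorted(self.minor_state_taxa.get(col, {}).items())
                ),
            })
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path, matrix: Supermatrix | None = None) -> None:
        self.to_frame(matrix).to_csv(path, sep="\t", index=False)


def classify_sites(
    matrix: Supermatrix,
    position_filter: PositionFilter = P123,
    columns: Iterable[int] | None = None,
) -> SiteClassification:
    """Classify retained columns as constant / singleton / informative.

    ``columns`` optionally restricts the scan (e.g. to the first 574 ND2
    columns); it is intersected with the mask and position filter.
    """
    if matrix.n_taxa < 3:
        raise ValueError("site classification requires at least 3 taxa")
    retained = matrix.retained_columns(position_filter.retained)
    if columns is not None:
        retained = np.intersect1d(retained, np.asarray(list(columns)))
    accs = matrix.accessions
    categories: dict[int, str] = {}
    minors: dict[int, dict[str, list[str]]] = {}
    for col in retained.tolist():
        cells = matrix.data[:, col]
        counts: Counter[bytes] = Counter()
        holders: dict[bytes, list[str]] = {}
        for i, cell in enumerate(cells):
            b = bytes(cell)
            if b in (b"A", b"C", b"G", b"T"):
                counts[b] += 1
                holders.setdefault(b, []).append(accs[i])
        if len(counts) <= 1:
            categories[col] = CONSTANT
            continue
        major = max(sorted(counts), key=lambda s: counts[s])
        minors[col] = {
            s.decode(): holders[s] for s in sorted(counts) if s != major
        }
        if sum(1 for c in counts.values() if c >= 2) >= 2:
            categories[col] = INFORMATIVE
        else:
            categories[col] = SINGLETON
    return SiteClassification(retained, categories, minors)


def translate_partition(
    matrix: Supermatrix, genes: Iterable[str] | None = None
) -> tuple[np.ndarray, dict[str, tuple[int, int]]]:
    """Translate coding partitions with the invertebrate mitochondrial code.

    Returns an (n_taxa, n_codons) amino-acid byte matrix plus per-gene
    codon intervals.  Codons touching masked columns, gaps, or
    ambiguities translate to ``X``.  A partition whose raw width is not
    divisible by 3 raises, naming the gene.
    """
    gene_list = list(genes) if genes is not None else [
        g for g in matrix.partitions
    ]
    blocks: list[np.ndarray] = []
    aa_partitions: dict[str, tuple[int, int]] = {}
    cursor = 0
    for gene in gene_list:
        s, e = matrix.partitions[gene]
        width = e - s
        if width % 3:
            raise ValueError(f"partition {gene} width {width} not divisible by 3")
        n_codons = width // 3
        mask = matrix.exclusion_mask[s:e].reshape(n_codons, 3).any(axis=1)
        rows = []
        for i in range(matrix.n_taxa):
            nt = matrix.data[i, s:e].tobytes().decode()
            # untranslatable cells become N so biopython yields X
            nt = "".join(
                ch if ch in "ACGT" else "N" for ch in nt
            )
            aa = str(Seq(nt).translate(table=5))
            aa = "".join(
                "X" if mask[j] else aa[j] for j in range(n_codons)
            )
            rows.append(np.frombuffer(aa.encode(), dtype="S1"))
        blocks.append(np.vstack(rows))
        aa_partitions[gene] = (cursor, cursor + n_codons)
        cursor += n_codons
    return np.hstack(blocks), aa_partitions


def variable_aa_columns(aa_matrix: np.ndarray) -> np.ndarray:
    """Indices of amino-acid columns with >= 2 residues (X/gap ignored)."""
    out = []
    for col in range(aa_matrix.shape[1]):
        states = {
            bytes(c) for c in aa_matrix[:, col] if bytes(c) not in (b"X", b"-", b"*")
        }
        if len(states) >= 2:
            out.append(col)
    return np.array(out, dtype=int)
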