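"""Annotated mitogenome records and coding-region supermatrix assembly.

The curation pipeline mirrors standard practice for insect mitogenome
phylogenetics: the 13 protein-coding genes are extracted in sense
orientation (light-strand genes reverse-complemented), concatenated in
coding order against a designated reference genome, kept in frame, and
cleaned deterministically — a configurable 3' ND4 window is masked
(that region aligns poorly across subspecies), autapomorphic
single-triplet insertions are masked, and ambiguous base calls are
resolved toward column invariance.

Internal coordinates are 0-based half-open; GenBank I/O converts from
the 1-based inclusive convention at the file boundary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .gene_table import (
    GENE_ORDER,
    LIGHT_STRAND,
    GeneTable,
    SUBSPECIES_TABLE,
    normalize_gene_name,
)

logger = logging.getLogger(__name__)

AMBIGUITY_CODES = frozenset("RYSWKMBDHVN")
GAP = b"-"


class ParseError(ValueError):
    """A malformed input record, named in the message."""


@dataclass
class GeneFeature:
    """One protein-coding gene annotation (0-based half-open coordinates)."""

    gene_name: str
    start: int
    end: int
    strand: str  # "heavy" | "light"

    def __post_init__(self):
        if self.gene_name not in GENE_ORDER:
            raise ValueError(f"unknown gene {self.gene_name!r}")
        if not 0 <= self.start <= self.end:
            raise ValueError(f"{self.gene_name}: bad interval [{self.start},{self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AnnotatedMitogenome:
    """One mitogenome sequence with gene features and a taxon label."""

    accession: str
    taxon_label: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self):
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        self.sequence = self.sequence.upper()
        for f in self.features:
            if f.end > len(self.sequence):
                raise ValueError(
                    f"{self.accession}: feature {f.gene_name} exceeds sequence bounds"
                )

    def feature(self, gene: str) -> GeneFeature:
        for f in self.features:
            if f.gene_name == gene:
                return f
        raise KeyError(f"{self.accession}: no feature for gene {gene!r}")

    def has_gene(self, gene: str) -> bool:
        return any(f.gene_name == gene for f in self.features)


# --------------------------------------------------------------------- #
# record parsing
# --------------------------------------------------------------------- #

def parse_genbank(source: str | Path | IO[str]) -> list[AnnotatedMitogenome]:
    """Parse GenBank flat-file records into annotated mitogenomes.

    Each CDS with a recognizable mitochondrial gene name becomes one
    :class:`GeneFeature`; synonyms such as COX1 or COB are normalized and
    unrecognized genes are skipped with a warning.  Features are returned
    sorted in canonical coding order.
    """
    genomes: list[AnnotatedMitogenome] = []
    try:
        records = list(SeqIO.parse(source, "genbank"))
    except Exception as exc:  # biopython raises bare ValueError on bad input
        raise ParseError(f"malformed GenBank input: {exc}") from exc
    for rec in records:
        try:
            genomes.append(_convert_record(rec))
        except ParseError:
            raise
        except Exception as exc:
            raise ParseError(f"malformed record {rec.id or '<unnamed>'}: {exc}") from exc
    if not genomes:
        raise ParseError("no GenBank records found in input")
    return genomes


def _convert_record(rec: SeqRecord) -> AnnotatedMitogenome:
    accession = rec.id or rec.name
    taxon = rec.annotations.get("organism", "")
    features: list[GeneFeature] = []
    for feat in rec.features:
        if feat.type == "source" and not taxon:
            taxon = "".join(feat.qualifiers.get("organism", [""]))
        if feat.type != "CDS":
            continue
        raw = (feat.qualifiers.get("gene") or feat.qualifiers.get("product") or [""])[0]
        gene = normalize_gene_name(raw)
        if gene is None:
            logger.warning("%s: unrecognized CDS gene name %r, skipped", accession, raw)
            continue
        strand = "light" if feat.location.strand == -1 else "heavy"
        features.append(
            GeneFeature(gene, int(feat.location.start), int(feat.location.end), strand)
        )
    if not features:
        logger.warning("%s: record has no recognizable CDS features", accession)
    features.sort(key=lambda f: GENE_ORDER.index(f.gene_name))
    return AnnotatedMitogenome(accession, taxon or accession, str(rec.seq), features)


def read_fasta(source: str | Path | IO[str]) -> list[AnnotatedMitogenome]:
    """Read FASTA with ``accession|taxon_label`` headers (no features)."""
    out = []
    for rec in SeqIO.parse(source, "fasta"):
        acc, _, label = rec.id.partition("|")
        out.append(AnnotatedMitogenome(acc, label or acc, str(rec.seq)))
    if not out:
        raise ParseError("no FASTA records found in input")
    return out


def write_genbank(genomes: Iterable[AnnotatedMitogenome], path: str | Path) -> None:
    """Serialize genomes as GenBank flat files (1-based inclusive on disk)."""
    records = []
    for g in genomes:
        rec = SeqRecord(Seq(g.sequence), id=g.accession, name=g.accession[:16],
                        description=g.taxon_label)
        rec.annotations["molecule_type"] = "DNA"
        rec.annotations["organism"] = g.taxon_label
        for f in g.features:
            loc = FeatureLocation(f.start, f.end, strand=-1 if f.strand == "light" else 1)
            rec.features.append(SeqFeature(loc, type="CDS", qualifiers={"gene": [f.gene_name]}))
        records.append(rec)
    SeqIO.write(records, str(path), "genbank")


# --------------------------------------------------------------------- #
# coding-region extraction
# --------------------------------------------------------------------- #

def extract_coding_region(
    genome: AnnotatedMitogenome,
    gene: str,
    table: GeneTable | None = None,
    tolerance: int = 30,
) -> str:
    """Return the gene's sequence in sense-strand 5'->3' orientation.

    Heavy-strand genes are the annotated slice; light-strand genes are
    reverse-complemented.  If ``table`` is given, lengths deviating from
    the expected value by more than ``tolerance`` bases are logged (the
    sequence is still returned).
    """
    feat = genome.feature(gene)
    raw = genome.sequence[feat.start:feat.end]
    seq = str(Seq(raw).reverse_complement()) if feat.strand == "light" else raw
    if table is not None:
        expected = table[gene].bases
        if abs(len(seq) - expected) > tolerance:
            logger.warning(
                "%s %s: length %d deviates from expected %d by more than %d",
                genome.accession, gene, len(seq), expected, tolerance,
            )
    return seq


# --------------------------------------------------------------------- #
# supermatrix
# --------------------------------------------------------------------- #

@dataclass
class Supermatrix:
    """Concatenated in-frame coding-region alignment with bookkeeping.

    ``data`` is an (n_taxa, n_columns) byte matrix over
    {A,C,G,T,-,ambiguity codes}; ``partitions`` maps gene name to a
    0-based half-open column interval; ``exclusion_mask`` marks columns
    that no downstream statistic may count; ``codon_position`` holds
    1/2/3 within coding partitions and 0 elsewhere.
    """

    taxa: list[tuple[str, str]]  # (accession, taxon_label)
    data: np.ndarray
    partitions: dict[str, tuple[int, int]]
    exclusion_mask: np.ndarray
    codon_position: np.ndarray

    def __post_init__(self):
        n, m = self.data.shape
        if len(self.taxa) != n:
            raise ValueError("taxa/data row mismatch")
        if self.exclusion_mask.shape != (m,) or self.codon_position.shape != (m,):
            raise ValueError("mask/codon arrays must match column count")
        accs = [a for a, _ in self.taxa]
        if len(set(accs)) != len(accs):
            raise ValueError("duplicate accessions in supermatrix")

    # -- basic queries -------------------------------------------------- #

    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def n_columns(self) -> int:
        return self.data.shape[1]

    @property
    def accessions(self) -> list[str]:
        return [a for a, _ in self.taxa]

    @property
    def labels(self) -> dict[str, str]:
        return dict(self.taxa)

    def row_index(self, accession: str) -> int:
        try:
            return self.accessions.index(accession)
        except ValueError:
            raise KeyError(f"accession {accession!r} not in supermatrix") from None

    def analyzed_columns(self) -> np.ndarray:
        """Indices of columns not covered by the exclusion mask."""
        return np.flatnonzero(~self.exclusion_mask)

    def retained_columns(self, positions: Iterable[int] | None = None) -> np.ndarray:
        """Analyzed columns, optionally restricted to codon positions."""
        keep = ~self.exclusion_mask
        if positions is not None:
            keep &= np.isin(self.codon_position, list(positions))
        return np.flatnonzero(keep)

    def gene_of_column(self, col: int) -> str | None:
        for gene, (s, e) in self.partitions.items():
            if s <= col < e:
                return gene
        return None

    def subset_columns(self, columns: np.ndarray) -> "Supermatrix":
        """A new matrix over the given columns (single catch-all partition)."""
        cols = np.asarray(columns)
        return Supermatrix(
            taxa=list(self.taxa),
            data=self.data[:, cols].copy(),
            partitions={"ALL": (0, len(cols))},
            exclusion_mask=np.zeros(len(cols), dtype=bool),
            codon_position=self.codon_position[cols].copy(),
        )

    # -- serialization -------------------------------------------------- #

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for (acc, label), row in zip(self.taxa, self.data):
                fh.write(f">{acc}|{label}\n{row.tobytes().decode()}\n")

    def write_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.n_taxa} {self.n_columns}\n")
            for (acc, _), row in zip(self.taxa, self.data):
                fh.write(f"{acc}  {row.tobytes().decode()}\n")

    def write_partitions_tsv(self, path: str | Path) -> None:
        rows = []
        excluded = set(np.flatnonzero(self.exclusion_mask).tolist())
        for gene, (s, e) in self.partitions.items():
            cols = sorted(c for c in excluded if s <= c < e)
            rows.append({
                "gene": gene, "start": s, "end": e,
                "strand": "light" if gene in LIGHT_STRAND else "heavy",
                "excluded_columns": ";".join(map(str, cols)),
            })
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    def to_files(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        self.write_fasta(prefix.with_suffix(".fasta"))
        self.write_partitions_tsv(prefix.with_suffix(".partitions.tsv"))

    @classmethod
    def from_files(cls, prefix: str | Path) -> "Supermatrix":
        prefix = Path(prefix)
        genomes = read_fasta(prefix.with_suffix(".fasta"))
        taxa = [(g.accession, g.taxon_label) for g in genomes]
        data = np.vstack([
            np.frombuffer(g.sequence.encode(), dtype="S1") for g in genomes
        ])
        part_df = pd.read_csv(
            prefix.with_suffix(".partitions.tsv"), sep="\t",
            dtype={"excluded_columns": str}, keep_default_na=False,
        )
        partitions: dict[str, tuple[int, int]] = {}
        mask = np.zeros(data.shape[1], dtype=bool)
        codon = np.zeros(data.shape[1], dtype=np.int8)
        for _, r in part_df.iterrows():
            s, e = int(r["start"]), int(r["end"])
            partitions[r["gene"]] = (s, e)
            codon[s:e] = (np.arange(e - s) % 3) + 1
            if r["excluded_columns"]:
                mask[[int(c) for c in r["excluded_columns"].split(";")]] = True
        return cls(taxa, data, partitions, mask, codon)


@dataclass
class BuildConfig:
    """Curation knobs for :func:`build_supermatrix`."""

    reference_accession: str | None = None  # default: first record
    table: GeneTable = SUBSPECIES_TABLE
    #: (gene, anchor, width): mask `width` columns at the 3' or 5' end
    exclusion_window: tuple[str, str, int] | None = ("ND4", "3prime", 37)
    tolerance: int = 30
    allow_missing_genes: bool = True
    #: externally aligned per-gene FASTA paths, for cases the triplet rule
    #: cannot handle: gene -> path (rows must carry matching accessions)
    gene_alignments: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "reference_accession": self.reference_accession,
            "exclusion_window": list(self.exclusion_window) if self.exclusion_window else None,
            "tolerance": self.tolerance,
            "allow_missing_genes": self.allow_missing_genes,
            "gene_alignments": self.gene_alignments,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _locate_triplet_indel(longer: str, shorter: str) -> int:
    """Position in ``shorter``'s coordinates of the triplet present in
    ``longer`` but absent from ``shorter``, chosen to minimize mismatches
    (SNP differences elsewhere must not confuse the placement).
    """
    assert len(longer) == len(shorter) + 3
    a = np.frombuffer(longer.encode(), dtype="S1")
    b = np.frombuffer(shorter.encode(), dtype="S1")
    n = len(b)
    pre = np.concatenate([[0], np.cumsum(a[:n] != b)])
    tail = (a[3:] != b).astype(int)
    suf = np.concatenate([np.cumsum(tail[::-1])[::-1], [0]])
    cost = pre[: n + 1] + suf[: n + 1]
    return int(np.argmin(cost))


def _align_gene(
    gene: str,
    sequences: dict[str, str],
    reference: str,
    tolerance: int,
) -> tuple[dict[str, str], list[int], set[str]]:
    """Positionally align one gene against the reference sequence.

    Handles single-triplet insertions (new gap-padded columns, masked when
    carried by exactly one taxon) and single-triplet deletions (gap fill).
    Returns (aligned rows, masked local columns, dropped accessions).
    """
    ref = sequences[reference]
    insertions: dict[str, int] = {}
    deletions: dict[str, int] = {}
    dropped: set[str] = set()
    for acc, seq in sequences.items():
        delta = len(seq) - len(ref)
        if delta == 0:
            continue
        if delta == 3:
            insertions[acc] = _locate_triplet_indel(seq, ref)
        elif delta == -3:
            deletions[acc] = _locate_triplet_indel(ref, seq)
        else:
            logger.warning(
                "%s %s: length %d vs reference %d not resolvable by the "
                "single-triplet rule; record excluded",
                acc, gene, len(seq), len(ref),
            )
            dropped.add(acc)
    # normalize each row to (reference-length backbone, own insertion or None)
    norm: dict[str, tuple[str, tuple[int, str] | None]] = {}
    for acc, seq in sequences.items():
        if acc in dropped:
            continue
        if acc in deletions:
            p = deletions[acc]
            norm[acc] = (seq[:p] + "---" + seq[p:], None)
        elif acc in insertions:
            q = insertions[acc]
            norm[acc] = (seq[:q] + seq[q + 3:], (q, seq[q:q + 3]))
        else:
            norm[acc] = (seq, None)
    points = sorted({q for a, q in insertions.items() if a not in dropped})
    carriers = {p: [a for a, q in insertions.items() if q == p and a not in dropped]
                for p in points}
    aligned: dict[str, str] = {}
    for acc, (base, own) in norm.items():
        parts: list[str] = []
        prev = 0
        for p in points:
            parts.append(base[prev:p])
            parts.append(own[1] if own is not None and own[0] == p else "---")
            prev = p
        parts.append(base[prev:])
        aligned[acc] = "".join(parts)
    width = len(ref) + 3 * len(points)
    assert all(len(s) == width for s in aligned.values())
    masked: list[int] = []
    for i, p in enumerate(points):
        if len(carriers[p]) == 1:  # autapomorphic insertion: mask its columns
            col = p + 3 * i
            masked.extend(range(col, col + 3))
    return aligned, masked, dropped


def build_supermatrix(
    genomes: Sequence[AnnotatedMitogenome],
    config: BuildConfig | None = None,
) -> Supermatrix:
    """Concatenate the 13 coding regions into an in-frame supermatrix.

    Per-gene alignment is positional against the reference genome; rows
    whose gene lengths are not resolvable by the single-triplet indel
    rule are excluded with a warning.  Missing genes become all-gap rows
    when ``config.allow_missing_genes``.  The exclusion mask covers the
    configured ND4 3' window and columns carried by exactly one taxon's
    triplet insertion.
    """
    if not genomes:
        raise ValueError("no genomes supplied")
    cfg = config or BuildConfig()
    ref_acc = cfg.reference_accession or genomes[0].accession
    by_acc = {g.accession: g for g in genomes}
    if ref_acc not in by_acc:
        raise ValueError(f"reference accession {ref_acc!r} not among inputs")
    reference = by_acc[ref_acc]

    order = [g.accession for g in genomes]
    keep = set(order)
    gene_blocks: dict[str, dict[str, str]] = {}
    gene_masks: dict[str, list[int]] = {}
    for row in cfg.table:
        gene = row.name
        if gene in cfg.gene_alignments:
            aln = {g.accession: g.sequence
                   for g in read_fasta(cfg.gene_alignments[gene])}
            widths = {len(s) for s in aln.values()}
            if len(widths) != 1:
                raise ParseError(f"external alignment for {gene} has ragged rows")
            gene_blocks[gene], gene_masks[gene] = aln, []
            continue
        if not reference.has_gene(gene):
            raise ValueError(f"reference {ref_acc} is missing gene {gene}")
        seqs: dict[str, str] = {}
        for acc in order:
            g = by_acc[acc]
            if g.has_gene(gene):
                seqs[acc] = extract_coding_region(g, gene, cfg.table, cfg.tolerance)
            elif not cfg.allow_missing_genes:
                raise ValueError(f"{acc} is missing gene {gene}")
        aligned, masked, dropped = _align_gene(gene, seqs, ref_acc, cfg.tolerance)
        keep -= dropped
        gene_blocks[gene] = aligned
        gene_masks[gene] = masked

    taxa = [(acc, by_acc[acc].taxon_label) for acc in order if acc in keep]
    partitions: dict[str, tuple[int, int]] = {}
    columns: list[np.ndarray] = []
    mask_cols: list[int] = []
    cursor = 0
    for row in cfg.table:
        gene = row.name
        block = gene_blocks[gene]
        width = len(next(iter(block.values())))
        rows = []
        for acc, _ in taxa:
            rows.append(block.get(acc, "-" * width))
        arr = np.vstack([np.frombuffer(r.encode(), dtype="S1") for r in rows])
        columns.append(arr)
        partitions[gene] = (cursor, cursor + width)
        mask_cols.extend(cursor + c for c in gene_masks[gene])
        cursor += width
    data = np.hstack(columns)
    m = data.shape[1]
    mask = np.zeros(m, dtype=bool)
    mask[mask_cols] = True
    if cfg.exclusion_window is not None:
        gene, anchor, width = cfg.exclusion_window
        s, e = partitions[gene]
        if anchor == "3prime":
            mask[max(s, e - width):e] = True
        elif anchor == "5prime":
            mask[s:min(e, s + width)] = True
        else:
            raise ValueError(f"unknown exclusion anchor {anchor!r}")
    codon = np.zeros(m, dtype=np.int8)
    for gene, (s, e) in partitions.items():
        codon[s:e] = (np.arange(e - s) % 3) + 1
    return Supermatrix(taxa, data, partitions, mask, codon)


def resolve_ambiguities(matrix: Supermatrix, reference_row: int = 0) -> Supermatrix:
    """Replace ambiguity codes so affected columns become invariant.

    At each column containing IUPAC ambiguity codes, ambiguous cells take
    the column's unanimous unambiguous state when one exists; otherwise
    the column majority state, with ties broken by the reference row's
    state.  Every replacement is logged.
    """
    data = matrix.data.copy()
    bases = {b"A", b"C", b"G", b"T"}
    amb = {c.encode() for c in AMBIGUITY_CODES}
    n, m = data.shape
    for col in range(m):
        cells = data[:, col]
        amb_rows = [i for i in range(n) if cells[i] in amb]
        if not amb_rows:
            continue
        plain = [bytes(cells[i]) for i in range(n) if cells[i] in bases]
        if not plain:
            continue
        states = sorted(set(plain))
        if len(states) == 1:
            target = states[0]
        else:
            counts = {s: plain.count(s) for s in states}
            best = max(counts.values())
            tied = sorted(s for s, c in counts.items() if c == best)
            if len(tied) == 1:
                target = tied[0]
            else:
                ref_state = bytes(cells[reference_row])
                target = ref_state if ref_state in tied else tied[0]
        for i in amb_rows:
            logger.info(
                "ambiguity resolved: taxon %s column %d %s -> %s",
                matrix.taxa[i][0], col, cells[i].decode(), target.decode(),
            )
            data[i, col] = target
    return Supermatrix(
        list(matrix.taxa), data, dict(matrix.partitions),
        matrix.exclusion_mask.copy(), matrix.codon_position.copy(),
    )
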