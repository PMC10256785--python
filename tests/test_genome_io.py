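"""Record parsing, coding-region extraction, and supermatrix curation."""

import io
import logging

import numpy as np
import pytest
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

import mitophylo as mp
from mitophylo.gene_table import LIGHT_STRAND
from mitophylo.genome_io import BuildConfig, ParseError, _align_gene

from util import toy_matrix


def _genbank_text(records) -> io.StringIO:
    buf = io.StringIO()
    SeqIO.write(records, buf, "genbank")
    buf.seek(0)
    return buf


def test_parse_genbank_normalizes_synonyms_and_sorts(caplog):
    seq = Seq("ATG" * 40)
    rec = SeqRecord(seq, id="TEST0001", name="TEST0001")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["organism"] = "Apis testensis"
    for raw, start, end, strand in [
        ("NAD2", 0, 12, 1),        # out of coordinate order on purpose
        ("COB", 60, 72, 1),
        ("COX1", 12, 24, 1),
        ("NAD5", 30, 45, -1),
        ("tRNA-Lys", 45, 51, 1),   # unrecognized -> skipped with warning
    ]:
        rec.features.append(SeqFeature(
            FeatureLocation(start, end, strand=strand), type="CDS",
            qualifiers={"gene": [raw]},
        ))
    with caplog.at_level(logging.WARNING):
        genomes = mp.parse_genbank(_genbank_text([rec]))
    (g,) = genomes
    assert g.taxon_label == "Apis testensis"
    assert [f.gene_name for f in g.features] == ["ND2", "CO1", "ND5", "CYTB"]
    assert g.feature("ND5").strand == "light"  # complement-strand CDS
    assert "unrecognized" in caplog.text


def test_parse_genbank_zero_cds_warns(caplog):
    rec = SeqRecord(Seq("ACGT" * 10), id="EMPTY001", name="EMPTY001")
    rec.annotations["molecule_type"] = "DNA"
    with caplog.at_level(logging.WARNING):
        (g,) = mp.parse_genbank(_genbank_text([rec]))
    assert g.features == []
    assert "no recognizable CDS" in caplog.text


def test_parse_genbank_malformed_input_raises():
    with pytest.raises(ParseError):
        mp.parse_genbank(io.StringIO("this is not a genbank record"))


def test_genbank_round_trip_preserves_simulated_annotations(tmp_path, small):
    _, genomes, _ = small
    path = tmp_path / "rt.gb"
    mp.write_genbank(genomes, path)
    back = mp.parse_genbank(str(path))
    for orig, again in zip(genomes, back):
        assert again.accession == orig.accession
        assert again.sequence == orig.sequence
        assert [(f.gene_name, f.start, f.end, f.strand) for f in again.features] == \
               [(f.gene_name, f.start, f.end, f.strand) for f in orig.features]


def test_extract_light_strand_is_reverse_complement(small):
    _, genomes, _ = small
    g = genomes[0]
    feat = g.feature("ND5")
    raw = g.sequence[feat.start:feat.end]
    sense = mp.extract_coding_region(g, "ND5")
    assert sense == str(Seq(raw).reverse_complement())
    # involution: reverse-complementing the extraction recovers the slice
    assert str(Seq(sense).reverse_complement()) == raw


def test_extract_heavy_strand_is_identity_slice(small):
    _, genomes, _ = small
    g = genomes[0]
    feat = g.feature("CO1")
    assert mp.extract_coding_region(g, "CO1") == g.sequence[feat.start:feat.end]


def test_extract_missing_gene_raises(small):
    _, genomes, _ = small
    bare = mp.AnnotatedMitogenome("X1", "x", genomes[0].sequence, [])
    with pytest.raises(KeyError):
        mp.extract_coding_region(bare, "ND2")


def test_nd2_built_to_table_has_expected_length(small):
    _, genomes, _ = small
    seq = mp.extract_coding_region(genomes[0], "ND2", mp.SUBSPECIES_TABLE)
    assert len(seq) == 1002 == 3 * 334


@pytest.mark.parametrize("table,total", [
    (mp.SPECIES_TABLE, 11070), (mp.SUBSPECIES_TABLE, 11043),
])
def test_gene_tables_totals(table, total):
    assert table.total_bases == total
    for row in table:
        assert row.strand == ("light" if row.name in LIGHT_STRAND else "heavy")


def test_identical_genomes_give_invariant_supermatrix(small):
    _, genomes, _ = small
    twins = [
        mp.AnnotatedMitogenome(f"DUP{i}", "dup", genomes[0].sequence,
                               list(genomes[0].features))
        for i in range(3)
    ]
    m = mp.build_supermatrix(twins)
    assert (m.data == m.data[0]).all()


def test_supermatrix_dimensions_and_mask(small, small_matrix):
    cfg, _, _ = small
    m = small_matrix
    widths = sum(e - s for s, e in m.partitions.values())
    assert widths == m.n_columns == cfg.gene_table.total_bases
    assert len(m.analyzed_columns()) == m.n_columns - 37
    # mask sits at the 3' end of the ND4 partition
    s, e = m.partitions["ND4"]
    assert set(np.flatnonzero(m.exclusion_mask)) == set(range(e - 37, e))
    # codon positions cycle 1,2,3 within each partition
    for s, e in m.partitions.values():
        assert (m.codon_position[s:e] == (np.arange(e - s) % 3) + 1).all()


def _insert_triplet(genome, gene, offset, triplet):
    feat = genome.feature(gene)
    pos = feat.start + offset
    seq = genome.sequence[:pos] + triplet + genome.sequence[pos:]
    feats = []
    for f in genome.features:
        s, e = f.start, f.end
        if s >= pos:
            s, e = s + 3, e + 3
        elif e > pos:
            e = e + 3
        feats.append(mp.GeneFeature(f.gene_name, s, e, f.strand))
    return mp.AnnotatedMitogenome(genome.accession, genome.taxon_label, seq, feats)


def test_autapomorphic_triplet_insertion_is_masked(small):
    _, genomes, _ = small
    offset = 90
    ref_gene = mp.extract_coding_region(genomes[0], "CO2")
    # avoid the neighboring bases so the insertion placement is unambiguous
    ins = next(b * 3 for b in "ACGT"
               if b not in (ref_gene[offset - 1], ref_gene[offset]))
    modified = [_insert_triplet(genomes[3], "CO2", offset, ins)] + \
        [g for i, g in enumerate(genomes) if i != 3]
    m = mp.build_supermatrix(modified, BuildConfig(
        reference_accession=genomes[0].accession))
    s, e = m.partitions["CO2"]
    assert e - s == len(ref_gene) + 3
    expected = {s + offset, s + offset + 1, s + offset + 2}
    masked_in_co2 = set(np.flatnonzero(m.exclusion_mask)) & set(range(s, e))
    assert masked_in_co2 == expected
    # the non-carrier rows are gapped at the masked columns
    row0 = m.data[m.row_index(genomes[0].accession), s + offset:s + offset + 3]
    assert row0.tobytes() == b"---"


def test_shared_insertion_is_not_masked(small):
    _, genomes, _ = small
    offset = 33
    ref_gene = mp.extract_coding_region(genomes[0], "CO2")
    ins = next(b * 3 for b in "ACGT"
               if b not in (ref_gene[offset - 1], ref_gene[offset]))
    modified = [
        _insert_triplet(g, "CO2", offset, ins) if i in (2, 4) else g
        for i, g in enumerate(genomes)
    ]
    m = mp.build_supermatrix(modified, BuildConfig(
        reference_accession=genomes[0].accession))
    s, e = m.partitions["CO2"]
    assert e - s == len(ref_gene) + 3
    assert not (set(np.flatnonzero(m.exclusion_mask)) & set(range(s, e)))


def test_unresolvable_length_drops_record(small, caplog):
    _, genomes, _ = small
    broken = mp.AnnotatedMitogenome(
        genomes[1].accession, genomes[1].taxon_label,
        genomes[1].sequence[:-500], [
            f if f.end <= len(genomes[1].sequence) - 500 else
            mp.GeneFeature(f.gene_name, f.start,
                           min(f.end, len(genomes[1].sequence) - 500), f.strand)
            for f in genomes[1].features
            if f.start < len(genomes[1].sequence) - 500
        ])
    with caplog.at_level(logging.WARNING):
        m = mp.build_supermatrix([genomes[0], broken, genomes[2]])
    assert broken.accession not in m.accessions
    assert "excluded" in caplog.text


def test_missing_reference_gene_raises(small):
    _, genomes, _ = small
    bare = mp.AnnotatedMitogenome("REF0", "r", genomes[0].sequence,
                                  genomes[0].features[1:])  # drop ND2
    with pytest.raises(ValueError, match="ND2"):
        mp.build_supermatrix([bare, genomes[1]],
                             BuildConfig(reference_accession="REF0"))


def test_missing_gene_gap_filled_when_allowed(small):
    _, genomes, _ = small
    partial = mp.AnnotatedMitogenome(
        "PART1", "p", genomes[1].sequence, genomes[1].features[1:])
    m = mp.build_supermatrix([genomes[0], partial, genomes[2]])
    s, e = m.partitions["ND2"]
    assert m.data[m.row_index("PART1"), s:e].tobytes() == b"-" * (e - s)


def test_supermatrix_round_trip(tmp_path, small_matrix):
    prefix = tmp_path / "sm"
    small_matrix.to_files(prefix)
    back = mp.Supermatrix.from_files(prefix)
    assert back.taxa == small_matrix.taxa
    assert (back.data == small_matrix.data).all()
    assert back.partitions == small_matrix.partitions
    assert (back.exclusion_mask == small_matrix.exclusion_mask).all()
    assert (back.codon_position == small_matrix.codon_position).all()


def test_align_gene_handles_deletion():
    seqs = {"r": "AAACCCGGGTTT", "d": "AAAGGGTTT"}
    aligned, masked, dropped = _align_gene("CO2", seqs, "r", 30)
    assert not dropped and not masked
    assert aligned["r"] == "AAACCCGGGTTT"
    assert aligned["d"] == "AAA---GGGTTT"


def test_resolve_ambiguities_unanimous_state():
    m = toy_matrix(["AAT", "AAT", "AWT"])
    out = mp.resolve_ambiguities(m)
    assert out.data[2, 1:2].tobytes() == b"A"
    col = out.data[:, 1]
    assert len(set(col.tolist())) == 1  # column now invariant


def test_resolve_ambiguities_majority_and_reference_tie():
    # majority: two Ts vs one A -> W becomes T
    out = mp.resolve_ambiguities(toy_matrix(["ATA", "TTA", "TWA"]))
    assert out.data[2, 1:2].tobytes() == b"T"
    # tie A/T broken by the reference (row 0) state
    out = mp.resolve_ambiguities(toy_matrix(["AAA", "TAA", "WAA"]))
    assert out.data[2, 0:1].tobytes() == b"A"


def test_resolve_ambiguities_noop_without_codes(small_matrix):
    out = mp.resolve_ambiguities(small_matrix)
    assert (out.data == small_matrix.data).all()
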