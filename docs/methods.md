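# Methods

This note documents the models and procedures implemented in
`mitophylo`, the defaults they ship with, and the decisions taken where
the design was genuinely open. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Coding-region supermatrix

The unit of analysis is the concatenation of the 13 mitochondrial
protein-coding genes in their 5'→3' coding order (ND2, CO1, CO2, ATP8,
ATP6, CO3, ND3, ND5, ND4, ND4L, ND6, CYTB, ND1). Two default gene
tables are provided: an across-species layout (11,070 bases / 3,690
triplets) and a within-*A. mellifera* subspecies layout (11,043 bases /
3,681 triplets); every row satisfies bases = 3 × triplets. ND5, ND4,
ND4L and ND1 are encoded on the light strand and are
reverse-complemented into sense orientation at extraction, so all
downstream code sees 5'→3' coding sequence.

Internal coordinates are 0-based half-open; GenBank I/O converts to and
from the 1-based inclusive convention at the file boundary. Annotation
gene-name synonyms (COX1, NAD5, COB, …) are normalized; unrecognized
CDSs are skipped with a warning.

Per-gene alignment is positional against a designated reference genome
(default: the first record). This replaces manual alignment-by-eye with
a deterministic rule set:

- **Single-triplet indels.** A gene 3 bases longer (shorter) than the
  reference is treated as carrying one triplet insertion (deletion).
  The indel is placed at the position minimizing total mismatches
  against the reference, so point differences elsewhere cannot confuse
  the placement; ties resolve to the smallest coordinate (placements
  that differ only by sliding through a mononucleotide run are
  genuinely equivalent). Insertion columns carried by exactly one
  taxon are added to the exclusion mask — they are autapomorphic and
  uninformative — while insertions shared by two or more taxa remain
  analyzable. Any other length mismatch excludes the record with a
  warning. A config hook accepts externally aligned per-gene FASTA for
  cases the rule cannot handle.
- **ND4 3' window.** 37 columns at the 3' end of the ND4 partition are
  masked by default. The window (gene, anchor, width) is configurable
  because the region's exact coordinates are an alignment judgment;
  only its width is well determined. With the subspecies layout the
  default leaves 11,043 − 37 = 11,006 analyzed columns.
- **Ambiguity resolution.** At any column containing IUPAC ambiguity
  codes, ambiguous cells take the column's unanimous unambiguous state
  when one exists (the column becomes invariant); otherwise the column
  majority state, with ties broken by the reference row's state. Every
  replacement is logged. The rationale: such calls are almost always
  sequencing noise at otherwise conserved positions, and leaving them
  unresolved would deflate distance and likelihood calculations
  unevenly across taxa.

Masked columns are excluded from *every* downstream statistic; tests
verify that masking a constant column changes no output.

## Site statistics and translation

A column is **parsimony-informative** when at least two states are each
held by at least two taxa, **variable-singleton** when variable but not
informative, **constant** otherwise. Cells with gaps or unresolved
ambiguity codes contribute no state: a state present only in such cells
cannot create informativeness. This is the common practice; the
classical definition is silent on gap handling.

Translation uses NCBI genetic code 5 (invertebrate mitochondrial). No
special start-codon recoding is applied — ATT/ATC initiators read as I,
matching the N-terminal residues of the annotated genes. Each
partition is translated on its original reading frame; any codon that
touches a masked column, gap, or ambiguity translates to `X`. (A naive
"drop masked columns, then translate" would break frame whenever a mask
width is not a multiple of 3 — the default 37-column ND4 window is
exactly such a case — so masking is applied at the codon level
instead.)

## Tree inference

All three methods are native implementations operating on the retained
columns (exclusion mask plus an optional codon-position filter, P123 or
P12).

**Neighbor joining** runs on counts of differing columns where both
cells are plain bases (model-free, appropriate at within-species
divergences where multiple hits are rare). Negative branch-length
estimates are clamped to zero with the deficit shifted to the sibling
branch, logged. A trifurcating root stores the unrooted tree.

**Maximum parsimony** uses Fitch's algorithm on 4-bit state sets
(gap/ambiguity = full set, i.e. missing), vectorized over compressed
site patterns; patterns in which all taxa share a state are dropped as
costless. The search takes `n_starts` (default 10) random-addition
stepwise insertion orders followed by SPR hill climbing, keeping every
distinct topology that attains the best length — closely related taxa
routinely admit many equally short trees, and reporting one would
overstate resolution. Branch substitution counts come from the
deterministic Fitch traceback (parent state retained when possible,
otherwise the lowest-indexed member of the state set, with the
traceback rooted on an edge so every change lands on a real branch);
this is the ACCTRAN-style early-change convention.

**Maximum likelihood** uses GTR+I: reversible rate matrix built from
six exchangeabilities and empirical stationary frequencies, normalized
to one expected substitution per site per unit branch length, plus an
invariant-site class of proportion `p_inv`. Branch lengths are in
expected substitutions per site over all sites, so the variable class
evolves at `t / (1 − p_inv)` — the convention used by the standard ML
programs. Transition matrices come from the symmetric eigendecomposition
`D^{1/2} Q D^{-1/2}`; site likelihoods from Felsenstein pruning over
compressed patterns. Optimization alternates coordinate-wise Brent on
branch lengths (bounds 10⁻⁹–10), bounded L-BFGS-B on log
exchangeabilities and logit `p_inv` (frequencies stay empirical, the +F
convention), and NNI sweeps in which each candidate is scored after
re-optimizing only the central branch; the best improving move is
applied and the cycle repeats to a tolerance of 10⁻⁶ log-likelihood
units. The default start tree is NJ with counts rescaled to per-site
lengths. The likelihood trace is returned and is non-decreasing across
accepted steps. Partials are not rescaled between nodes; at the tree
sizes this package targets (tens of taxa) double precision has ample
headroom, but very large trees would need scaling.

**Bootstrap.** Retained columns are resampled with replacement; each
replicate is analyzed under the same method and settings; support for
each bipartition of the point estimate is the percentage of replicates
containing it. The resampling unit is the alignment column after
masking and position filtering, matching the conditions of the main
search.

## Fixed-rate clock

Dating is a two-step procedure with the topology held fixed. First the
rooted ML tree is projected onto a strict clock: each internal node's
height is the mean over leaf pairs spanning it of half their patristic
distance (for an already-ultrametric tree this is exact), with
parent ≥ child nesting enforced. When GTR parameters are available the
heights are then refined by constrained ML — root height and per-node
parent fractions optimized by L-BFGS-B — keeping whichever solution has
the higher likelihood. Relaxed-rate relative-time frameworks are
deliberately **not** reimplemented: with a single fixed calibration
rate, per-lineage rate variation has no observable consequence for the
height-to-age conversion, and the strict clock makes the procedure
closed-form and testable. Ages derived from real data are accordingly
approximate where lineage rates truly vary.

Conversion is pure arithmetic: `age[Kyr] = height / (rate × 10⁻³)` with
`rate` in substitutions/site/Myr, default 0.0115 — a standard insect
mitochondrial coding-region figure. The rate is per lineage;
divergence between two taxa accrues at twice this rate. Reported ages
round to the nearest integer Ka.

## Taxonomic audit

**Patristic reports.** All leaf-pair path lengths (on MP trees these
are substitution counts, so the numbers are directly comparable to
branch labels). Per label: the maximum within-label distance (reported
as missing, never 0, for single-member labels); per label pair: the
min/max between-label distance; plus the per-comparison boolean
"between-pair max < within-label max" that underlies statements of the
form *these nominal subspecies differ less than individuals within that
one*.

**Misassignment flags.** A leaf is a candidate when it is
patristically closer to a foreign multi-member label than to its own
label, where "distance to own label" is measured against the label's
medoid member — the member minimizing total distance to the rest — so
two co-misassigned sequences cannot vouch for each other. A candidate
is flagged only if it *nests*: the smallest unrooted split side
containing the leaf and its nearest foreign member holds no members of
any third label (already-flagged leaves and fellow candidates do not
block). Flags are accepted iteratively, strongest margin first, each
flagged leaf leaving its claimed label's pool, and finally re-validated
against the cleaned pools; this stops an interloper from dragging its
correct neighbors into spurious flags. By default a single-member
label nested inside another label's clade is *not* flagged — in real
datasets that pattern is legitimate nested phylogeography as often as
error — use `strict=True` to flag those too. Known limitation: a
"colony" of several sequences misassigned from one clade to the same
wrong label is formally indistinguishable from a legitimately nested
subgroup; resolving such cases needs external evidence.

**Chimeric-run scans.** At each parsimony-informative column a pair of
sequences is *exclusive* when both carry the same plain base and no
other taxon does. Maximal runs of exclusive sites that are consecutive
in the sequence of informative columns (default; alignment-position
adjacency is available behind a flag, since "unbroken run" is ambiguous
between the two readings) are reported with coordinates, and runs of
≥5 sites (configurable; real faulty-pair diagnostics show runs of about
7) raise a chimeric-run flag for both members. Honest shared ancestry
produces exclusive sites scattered among other informative columns;
only a shared foreign or corrupted block concentrates them into long
runs.

## Synthetic data

The simulator generates what the analysis assumes, nothing more:

- **Tree.** Labeled clades on a ladder backbone with configurable split
  ages (default 780/720/660/540/250 Ka — a late-Pleistocene timeline —
  with six clades and four genomes each) and a common within-clade
  crown age (default 100 Ka) under random nested splitting. Tips are
  contemporaneous.
- **Sequences.** Per-gene root sequences drawn from the stationary
  frequencies; GTR substitution along branches via the matrix
  exponential at 0.0115 subs/site/Myr per lineage. The default GTR is
  AT-rich (π = 0.42/0.10/0.06/0.42 for A/C/G/T, matching insect mtDNA
  composition) with a 6:1 transition bias. Genomes carry correct
  light-strand encoding (stored reverse-complemented with
  `strand="light"` features) and 16-base unevolved AT-rich spacers
  between genes; spacers are identical across taxa and never analyzed.
- **Anomalies.** Mislabels reassign a leaf to a different clade's label
  (one-directional, the way curation errors actually arise in sequence
  databases; source clades keep at least two correctly labeled members
  where possible, the regime in which misassignment is identifiable at
  all). Chimeras overwrite a contiguous block in one or more
  recipients, either from a donor genome or — emulating faulty
  sequence — with a single shared block drawn from the stationary
  frequencies; overlapping blocks on one recipient are rejected. The
  truth record registers every injection with coordinates.

All randomness flows through one explicitly passed seeded generator;
the same seed reproduces the dataset byte for byte.

What the simulator does **not** emulate — and hence what green tests do
not certify about real data: indel evolution beyond single triplets,
recombination, selection, among-site rate variation beyond the
invariant class, base-composition heterogeneity across lineages, and
annotation errors other than label swaps. Real mitogenome sets also
have missing genes and ragged gene boundaries that the curation rules
handle but the default simulation does not generate.

## Problem sizes and checks

The tests and the acceptance script exercise the pipeline at 12–30
taxa and the full 11-kb coding alignment — the scale of the intended
application — with 20 seeded replicates for the end-to-end age-recovery
property, 100 bootstrap replicates for support checks, and exhaustive
or brute-force oracles (all quartet topologies, all internal-state
assignments, graph shortest paths, independent re-translation) wherever
a small instance admits one. Reproducing the published statistics that
depend on the real GenBank mitogenome set requires placing those flat
files under `data/genbank/`; the corresponding checks otherwise report
precisely that.
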