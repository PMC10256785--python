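# mitophylo

Phylogeography from complete mitochondrial genomes, built for the
honey-bee case: many named subspecies, each represented by one or a few
GenBank mitogenomes of uneven curation quality. The package turns
annotated insect mitogenomes into a 13-gene coding-region supermatrix,
infers trees three independent ways, dates divergences with a fixed-rate
molecular clock, and — because names matter — audits whether each
sequence's taxon label is consistent with where it falls on the tree.

It is aimed at systematists and molecular ecologists who work with
mitogenome-scale alignments of closely related taxa (within-species to
within-genus divergences of roughly 0.1–10%) and who need the analysis
chain to be reproducible end to end, including the quality-control
decisions that are usually made by hand.

## What it computes

**Supermatrix.** The 13 protein-coding genes (ND2, CO1, CO2, ATP8,
ATP6, CO3, ND3, ND5, ND4, ND4L, ND6, CYTB, ND1) are extracted from
GenBank CDS annotations, light-strand genes (ND5, ND4, ND4L, ND1)
reverse-complemented into sense orientation, and concatenated in coding
order against a designated reference genome. Curation is deterministic:
a configurable 37-bp window at the 3' end of ND4 (a region that aligns
poorly across subspecies) is masked, autapomorphic single-triplet
insertions are masked, and IUPAC ambiguity codes are resolved toward
column invariance. For the standard *Apis mellifera* subspecies layout
this yields 11,043 columns of which 11,006 are analyzed.

**Trees.** Three native implementations, all honoring the exclusion
mask and an optional codon-position filter (P123 vs P12):

- neighbor joining on counts of pairwise differences,
- equal-weight maximum parsimony: Fitch lengths with bitwise state
  sets, random-addition starts, SPR hill climbing, all minimum-length
  topologies retained, per-branch substitution counts from a
  deterministic traceback,
- maximum likelihood under GTR+I (general time-reversible exchange
  rates `r_AC … r_GT`, stationary frequencies `π`, invariant-site
  proportion `p_inv`) via Felsenstein pruning on compressed site
  patterns, with NNI topology moves alternating with Brent/L-BFGS-B
  numeric optimization,

plus the nonparametric bootstrap (columns resampled with replacement;
support = percentage of replicates containing each bipartition).

**Clock.** A rooted ML tree is linearized to an ultrametric tree
(least-squares heights, optionally refined by constrained ML with the
topology fixed), and node heights *h* in substitutions/site convert to
ages by `age[Kyr] = h / (rate × 10⁻³)` at a fixed per-lineage rate,
default 0.0115 substitutions/site/Myr — so a node at 0.008234
subs/site dates to 716 Ka.

**Audit.** Patristic (path-length) distance reports within and between
labels; misassignment flags for leaves that are closer to, and nest
inside, a foreign label's clade; and scans for unbroken runs of
parsimony-informative sites shared exclusively by one pair of sequences,
the signature of shared faulty sequence blocks.

**Simulator.** A seeded generator produces annotated mitogenomes with
known truth: labeled clades on an ultrametric ladder (default splits at
780/720/660/540/250 Ka, 100 Ka crowns), GTR evolution with AT-rich
composition, correct strand encoding, and optional injected mislabels
and chimeric blocks — so every stage of the pipeline is testable with
no downloads.

## Worked example

```python
import mitophylo as mp

# simulate an annotated mitogenome dataset with known truth
cfg = mp.SimulationConfig()          # 6 clades x 4 genomes, 13 genes
genomes, truth = mp.simulate_dataset(cfg, seed=1)

# concatenated coding-region supermatrix with curation
matrix = mp.build_supermatrix(genomes)
print(f"{matrix.n_taxa} taxa x {matrix.n_columns} columns, "
      f"{len(matrix.analyzed_columns())} analyzed")

cls = mp.classify_sites(matrix)
print(f"{cls.n_variable} variable sites, {cls.n_informative} informative")

# two of the three inference methods
nj = mp.neighbor_joining(mp.pairwise_differences(matrix))
res = mp.ml_search(matrix, seed=1)
print("NJ and ML topologies agree:", nj.same_topology(res.tree))

# strict-clock dating at 0.0115 subs/site/Myr
outgroup = tuple(a for a, l in truth.labels.items() if l == "north_european")
ct = mp.linearize(res.tree, matrix, mp.ClockConfig(outgroup=outgroup),
                  params=res.params)
print(f"basal divergence: {round(ct.root_age)} Ka "
      f"(simulated at {truth.clade_split_ages['north_european']:.0f} Ka)")
```

prints

```
24 taxa x 11043 columns, 11006 analyzed
620 variable sites, 450 informative
NJ and ML topologies agree: True
basal divergence: 839 Ka (simulated at 780 Ka)
```

The 11,006 analyzed columns are the 11,043-column subspecies gene
layout minus the default 37-column ND4 mask. The recovered basal age
differs from the simulated 780 Ka by the stochastic noise expected at
this sequence length; across replicate simulations the mean absolute
relative error of recovered split ages is about 5%.

A `mitophylo` console script exposes the same steps
(`simulate`, `build`, `sites`, `tree`, `clock`, `audit`); run
`mitophylo --help`.

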