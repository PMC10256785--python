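"""Synthetic annotated mitogenomes with known truth.

The generator emulates the statistical structure the analysis assumes:
a set of labeled "subspecies" clades on an ultrametric (clock) tree,
13 protein-coding genes in the canonical heavy/light-strand layout,
GTR substitution with strongly AT-rich composition, and optional
injected anomalies (label swaps between clades and chimeric blocks
copied from a donor genome).

The default scenario places six clades on a ladder backbone with
between-clade split ages of 780, 720, 660, 540 and 250 Ka and a
within-clade crown age of 100 Ka — a timeline shaped like a late
Pleistocene north-to-south phylogeographic expansion — evolving at
0.0115 substitutions/site/Myr per lineage.  All randomness flows
through one explicitly passed seeded generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .gene_table import GeneTable, LIGHT_STRAND, SUBSPECIES_TABLE
from .genome_io import AnnotatedMitogenome, GeneFeature, write_genbank
from .phylo import Node, Phylogeny
from .treeinfer import GTRParams

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

DEFAULT_CLADES = (
    "north_european", "se_european", "asia_minor",
    "levantine", "sub_saharan", "mediterranean",
)


def _default_gtr() -> GTRParams:
    # AT-rich insect mtDNA composition with transition bias
    return GTRParams(
        rates=np.array([1.0, 6.0, 1.0, 1.0, 6.0, 1.0]),
        freqs=np.array([0.42, 0.10, 0.06, 0.42]),
        p_inv=0.0,
    )


@dataclass(frozen=True)
class ChimeraSpec:
    """A contiguous foreign block overwriting one or more recipients.

    ``donor`` is a leaf index whose sequence provides the block; when
    None, a single corrupted block is drawn from the stationary base
    frequencies (emulating faulty/contaminated sequence) and shared by
    all recipients, which is what makes unrelated recipients attract
    each other.
    """

    recipients: tuple[int, ...]
    start: int       # genome coordinate, 0-based
    length: int = 600
    donor: int | None = None


@dataclass
class SimulationConfig:
    clade_names: tuple[str, ...] = DEFAULT_CLADES
    leaves_per_clade: int = 4
    backbone_ages_ka: tuple[float, ...] = (780.0, 720.0, 660.0, 540.0, 250.0)
    crown_age_ka: float = 100.0
    rate: float = 0.0115            # substitutions/site/Myr, per lineage
    gtr: GTRParams = field(default_factory=_default_gtr)
    gene_table: GeneTable = field(default_factory=lambda: SUBSPECIES_TABLE)
    spacer_length: int = 16
    n_mislabels: int = 0
    chimeras: tuple[ChimeraSpec, ...] = ()

    def __post_init__(self):
        if len(self.backbone_ages_ka) != len(self.clade_names) - 1:
            raise ValueError("need one backbone age per clade split")
        ages = list(self.backbone_ages_ka)
        if ages != sorted(ages, reverse=True):
            raise ValueError("backbone ages must decrease root-to-tip")
        if ages and self.crown_age_ka >= ages[-1]:
            raise ValueError("crown age must be below the youngest split")


@dataclass
class TruthRecord:
    """Everything the generator knows that the analysis must recover."""

    tree: Phylogeny                       # ultrametric, branch lengths in Ka
    labels: dict[str, str]                # accession -> true clade label
    clade_split_ages: dict[str, float]    # clade name -> stem divergence age
    crown_age_ka: float
    #: (accession, true label, assigned label) per injected mislabel
    mislabels: list[tuple[str, str, str]] = field(default_factory=list)
    chimeras: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "tree_newick": self.tree.newick(),
            "labels": self.labels,
            "clade_split_ages": self.clade_split_ages,
            "crown_age_ka": self.crown_age_ka,
            "mislabels": self.mislabels,
            "chimeras": self.chimeras,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def labels_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            sorted(self.labels.items()), columns=["accession", "label"]
        ).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------- #
# tree simulation
# --------------------------------------------------------------------- #

def _yule_clade(
    names: list[str], crown: float, rng: np.random.Generator
) -> Node:
    """Random nested ultrametric subtree with the given crown age."""
    if len(names) == 1:
        return Node(names[0])
    if len(names) == 2:
        parts = [[names[0]], [names[1]]]
    else:
        k = int(rng.integers(1, len(names)))
        shuffled = list(names)
        rng.shuffle(shuffled)
        parts = [shuffled[:k], shuffled[k:]]
    node = Node()
    for part in parts:
        child_crown = crown * float(rng.uniform(0.4, 0.9))
        child = _yule_clade(part, child_crown, rng)
        child.length = crown if len(part) == 1 else crown - child_crown
        node.add(child)
    return node


def simulate_clock_tree(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[Phylogeny, dict[str, str]]:
    """Ladder backbone with configured split ages; pure-birth clades.

    Returns an ultrametric rooted tree (branch lengths in Ka, tips at
    age 0) and the accession -> clade-label map.  Leaf accessions are
    ``SYN<clade_index><leaf_index>``.
    """
    labels: dict[str, str] = {}
    clades: list[Node] = []
    for ci, name in enumerate(config.clade_names):
        leaf_names = []
        for li in range(config.leaves_per_clade):
            acc = f"SYN{ci:02d}{li:02d}"
            labels[acc] = name
            leaf_names.append(acc)
        crown = min(config.crown_age_ka, 1.0) if config.leaves_per_clade == 1 \
            else config.crown_age_ka
        clades.append(_yule_clade(leaf_names, crown, rng))
    ages = list(config.backbone_ages_ka)
    if not ages:  # single clade: the clade subtree is the whole tree
        return Phylogeny(clades[0]), labels
    # ladder: root splits clade 0 from the rest, then clade 1, ...
    def stem(node: Node, from_age: float) -> Node:
        crown = 0.0 if node.is_leaf else config.crown_age_ka
        node.length = from_age - crown
        return node

    current = clades[-1]
    current_age = ages[-1]
    current = stem(current, current_age)
    for i in range(len(ages) - 1, -1, -1):
        parent = Node()
        parent.add(stem(clades[i], ages[i]))
        if i == len(ages) - 1:
            parent.add(current)
        else:
            inner = current
            inner.length = ages[i] - ages[i + 1]
            parent.add(inner)
        current = parent
    return Phylogeny(current), labels


def node_ages(tree: Phylogeny) -> dict[Node, float]:
    """Ages implied by an ultrametric tree's branch lengths (tips at 0)."""
    depths = tree.leaf_depths()
    root_age = max(depths.values())
    ages: dict[Node, float] = {tree.root: root_age}
    for node in tree.preorder():
        if node is not tree.root:
            ages[node] = ages[node.parent] - (node.length or 0.0)
    return ages


# --------------------------------------------------------------------- #
# sequence evolution
# --------------------------------------------------------------------- #

def _evolve_block(
    tree: Phylogeny,
    length: int,
    subs_per_site_per_ka: float,
    gtr: GTRParams,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Simulate one gene along the tree; returns leaf-name -> state codes."""
    Q = gtr.rate_matrix()
    root_states = rng.choice(4, size=length, p=gtr.freqs)
    states: dict[Node, np.ndarray] = {tree.root: root_states}
    leaf_seqs: dict[str, np.ndarray] = {}
    for node in tree.preorder():
        if node is tree.root:
            continue
        t = (node.length or 0.0) * subs_per_site_per_ka
        P = expm(Q * t) if t > 0 else np.eye(4)
        P = np.clip(P, 0.0, None)
        P /= P.sum(axis=1, keepdims=True)
        parent = states[node.parent]
        child = np.empty_like(parent)
        for s in range(4):
            idx = np.flatnonzero(parent == s)
            if len(idx):
                child[idx] = rng.choice(4, size=len(idx), p=P[s])
        states[node] = child
        if node.is_leaf:
            leaf_seqs[node.name] = child
    return leaf_seqs


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def _revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def evolve_sequences(
    tree: Phylogeny,
    config: SimulationConfig,
    rng: np.random.Generator,
    labels: dict[str, str] | None = None,
) -> tuple[list[AnnotatedMitogenome], TruthRecord]:
    """Evolve the 13 genes along an ultrametric tree (lengths in Ka) and
    assemble annotated genomes in the canonical layout.

    Light-strand genes are simulated in sense orientation and written
    reverse-complemented into the genome with ``strand="light"``
    features, so coding-region extraction recovers the simulated
    sequences exactly.  Intergenic spacers are unevolved AT-rich filler
    shared by all genomes (spacers are never analyzed).
    """
    per_ka = config.rate * 1e-3  # subs/site/Myr -> per Ka
    gene_seqs: dict[str, dict[str, str]] = {}
    for row in config.gene_table:
        block = _evolve_block(tree, row.bases, per_ka, config.gtr, rng)
        gene_seqs[row.name] = {name: _codes_to_str(c) for name, c in block.items()}
    spacer = _codes_to_str(
        rng.choice(4, size=config.spacer_length, p=config.gtr.freqs)
    )
    genomes: list[AnnotatedMitogenome] = []
    if labels is None:
        labels = {name: name for name in tree.leaf_names()}
    for name in tree.leaf_names():
        parts: list[str] = []
        features: list[GeneFeature] = []
        cursor = 0
        for row in config.gene_table:
            if config.spacer_length:
                parts.append(spacer)
                cursor += config.spacer_length
            sense = gene_seqs[row.name][name]
            stored = _revcomp(sense) if row.name in LIGHT_STRAND else sense
            features.append(
                GeneFeature(row.name, cursor, cursor + len(stored), row.strand)
            )
            parts.append(stored)
            cursor += len(stored)
        genomes.append(
            AnnotatedMitogenome(name, labels[name], "".join(parts), features)
        )
    split_ages = dict(zip(config.clade_names, config.backbone_ages_ka))
    truth = TruthRecord(
        tree=tree.copy(),
        labels=dict(labels),
        clade_split_ages=split_ages,
        crown_age_ka=config.crown_age_ka,
    )
    return genomes, truth


# --------------------------------------------------------------------- #
# anomaly injection
# --------------------------------------------------------------------- #

def inject_anomalies(
    genomes: Sequence[AnnotatedMitogenome],
    truth: TruthRecord,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[list[AnnotatedMitogenome], TruthRecord]:
    """Reassign labels across clades and overwrite chimeric blocks.

    Each mislabel gives one leaf the label of a different clade
    (one-directional misassignment, the way curation errors arise in
    sequence databases).  Returns modified copies; the truth registry
    records every injection.
    """
    genomes = [
        AnnotatedMitogenome(g.accession, g.taxon_label, g.sequence,
                            [replace(f) for f in g.features])
        for g in genomes
    ]
    truth = TruthRecord(
        truth.tree.copy(), dict(truth.labels), dict(truth.clade_split_ages),
        truth.crown_age_ka, list(truth.mislabels), list(truth.chimeras),
    )
    by_acc = {g.accession: g for g in genomes}
    if config.n_mislabels:
        clades: dict[str, list[str]] = {}
        for acc, lab in truth.labels.items():
            clades.setdefault(lab, []).append(acc)
        names = sorted(clades)
        if config.n_mislabels > len(truth.labels):
            raise ValueError("more mislabels requested than leaves available")
        touched: set[str] = set()
        for _ in range(config.n_mislabels):
            # prefer source clades keeping >= 2 correctly labeled members,
            # the regime in which misassignment is identifiable at all
            eligible = [
                l for l in names
                if len([a for a in clades[l] if a not in touched]) >= 3
            ]
            if not eligible:
                eligible = [
                    l for l in names
                    if len([a for a in clades[l] if a not in touched]) >= 2
                ]
            if not eligible:
                raise ValueError("not enough untouched leaves for mislabels")
            la = str(rng.choice(eligible))
            lb = str(rng.choice([l for l in names if l != la]))
            candidates = [a for a in clades[la] if a not in touched]
            a = candidates[int(rng.integers(len(candidates)))]
            by_acc[a].taxon_label = lb
            touched.add(a)
            truth.mislabels.append((a, la, lb))
    blocks: dict[str, list[tuple[int, int]]] = {}
    for spec in config.chimeras:
        start, end = spec.start, spec.start + spec.length
        if spec.donor is not None:
            block = genomes[spec.donor].sequence[start:end]
            donor_name = genomes[spec.donor].accession
        else:
            block = _codes_to_str(
                rng.choice(4, size=spec.length, p=config.gtr.freqs)
            )
            donor_name = "corrupted"
        for idx in spec.recipients:
            recipient = genomes[idx]
            if end > len(recipient.sequence):
                raise ValueError("chimera block exceeds sequence bounds")
            for s, e in blocks.get(recipient.accession, []):
                if start < e and s < end:
                    raise ValueError("overlapping chimera blocks on one recipient")
            blocks.setdefault(recipient.accession, []).append((start, end))
            recipient.sequence = (
                recipient.sequence[:start] + block + recipient.sequence[end:]
            )
            truth.chimeras.append({
                "donor": donor_name, "recipient": recipient.accession,
                "start": start, "end": end,
            })
    return genomes, truth


# --------------------------------------------------------------------- #
# one-call preset
# --------------------------------------------------------------------- #

def simulate_dataset(
    config: SimulationConfig | None = None,
    seed: int | None = None,
) -> tuple[list[AnnotatedMitogenome], TruthRecord]:
    """Simulate tree + sequences + anomalies under one config and seed."""
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    tree, labels = simulate_clock_tree(cfg, rng)
    genomes, truth = evolve_sequences(tree, cfg, rng, labels)
    if cfg.n_mislabels or cfg.chimeras:
        genomes, truth = inject_anomalies(genomes, truth, cfg, rng)
    return genomes, truth


def emit_dataset(
    out_dir: str | Path,
    config: SimulationConfig | None = None,
    seed: int | None = None,
) -> tuple[list[AnnotatedMitogenome], TruthRecord]:
    """Simulate and write GenBank, FASTA, and truth files to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genomes, truth = simulate_dataset(config, seed)
    write_genbank(genomes, out / "genomes.gb")
    with open(out / "genomes.fasta", "w") as fh:
        for g in genomes:
            fh.write(f">{g.accession}|{g.taxon_label}\n{g.sequence}\n")
    truth.to_json(out / "truth.json")
    truth.labels_tsv(out / "labels.tsv")
    return genomes, truth
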