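"""Independent oracles and small builders shared by the test suite.

Everything here deliberately avoids the package's own optimized code
paths: parsimony lengths come from exhaustive internal-state
enumeration, likelihoods from direct matrix exponentials and sums over
ancestral states, so the implementations are checked against first
principles.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.linalg import expm

from mitophylo.genome_io import Supermatrix
from mitophylo.phylo import Node, Phylogeny


def toy_matrix(rows: list[str], labels: list[str] | None = None,
               gene: str = "ND2") -> Supermatrix:
    """Supermatrix from aligned row strings; taxa named t0, t1, ..."""
    m = len(rows[0])
    assert all(len(r) == m for r in rows)
    taxa = [(f"t{i}", labels[i] if labels else f"t{i}") for i in range(len(rows))]
    data = np.vstack([np.frombuffer(r.encode(), dtype="S1") for r in rows])
    codon = ((np.arange(m) % 3) + 1).astype(np.int8)
    return Supermatrix(taxa, data, {gene: (0, m)}, np.zeros(m, dtype=bool), codon)


def leaf_state_sets(column: str, names: list[str]) -> dict[str, frozenset[str]]:
    out = {}
    for name, ch in zip(names, column):
        out[name] = frozenset("ACGT") if ch not in "ACGT" else frozenset(ch)
    return out


def brute_fitch_column(tree: Phylogeny, states: dict[str, frozenset[str]]) -> int:
    """Minimum changes for one column by exhaustive internal labeling."""
    internals = [n for n in tree.postorder() if not n.is_leaf]
    best = np.inf
    for combo in itertools.product("ACGT", repeat=len(internals)):
        assign = dict(zip((id(n) for n in internals), combo))
        cost = 0
        for node in tree.postorder():
            if node.parent is None:
                continue
            parent_state = assign[id(node.parent)]
            if node.is_leaf:
                cost += parent_state not in states[node.name]
            else:
                cost += assign[id(node)] != parent_state
        best = min(best, cost)
    return int(best)


def brute_fitch(tree: Phylogeny, rows: dict[str, str]) -> int:
    names = list(rows)
    total = 0
    for col in range(len(next(iter(rows.values())))):
        column = "".join(rows[n][col] for n in names)
        total += brute_fitch_column(tree, leaf_state_sets(column, names))
    return total


def brute_gtr_log_likelihood(tree, rows: dict[str, str], params) -> float:
    """Direct sum over all ancestral-state assignments, with the +I
    mixture and the same branch-scaling convention as the package
    (variable class evolves at t / (1 - p_inv))."""
    Q = params.rate_matrix()
    scale = 1.0 / (1.0 - params.p_inv) if params.p_inv > 0 else 1.0
    P = {}
    for node in tree.postorder():
        if node.parent is not None:
            P[id(node)] = expm(Q * (node.length or 0.0) * scale)
    internals = [n for n in tree.postorder() if not n.is_leaf]
    idx = {b: i for i, b in enumerate("ACGT")}
    total = 0.0
    n_cols = len(next(iter(rows.values())))
    for col in range(n_cols):
        like_var = 0.0
        for combo in itertools.product(range(4), repeat=len(internals)):
            assign = dict(zip((id(n) for n in internals), combo))
            term = params.freqs[assign[id(tree.root)]]
            for node in tree.postorder():
                if node.parent is None:
                    continue
                ps = assign[id(node.parent)]
                if node.is_leaf:
                    ch = rows[node.name][col]
                    if ch in idx:
                        term *= P[id(node)][ps, idx[ch]]
                    else:  # missing: sum over states = row sum = 1
                        term *= P[id(node)][ps].sum()
                else:
                    term *= P[id(node)][ps, assign[id(node)]]
            like_var += term
        site = (1.0 - params.p_inv) * like_var
        if params.p_inv > 0:
            chars = {rows[n][col] for n in rows if rows[n][col] in idx}
            if len(chars) <= 1:
                for b, i in idx.items():
                    if not chars or b in chars:
                        site += params.p_inv * params.freqs[i]
        total += np.log(site)
    return float(total)


def random_unrooted_tree(names: list[str], rng: np.random.Generator,
                         min_len: float = 0.05, max_len: float = 1.0) -> Phylogeny:
    """Random binary unrooted topology with positive branch lengths."""
    tree = _star(names[:3], rng, min_len, max_len)
    for name in names[3:]:
        edges = [n for n in tree.postorder() if n.parent is not None]
        edge = edges[int(rng.integers(len(edges)))]
        parent = edge.parent
        mid = Node(length=float(rng.uniform(min_len, max_len)))
        parent.children[parent.children.index(edge)] = mid
        mid.parent = parent
        half = edge.length / 2.0
        edge.length = half
        mid.length = half
        mid.add(edge)
        leaf = Node(name, float(rng.uniform(min_len, max_len)))
        mid.add(leaf)
    return tree


def _star(names, rng, lo, hi):
    root = Node()
    for n in names:
        root.add(Node(n, float(rng.uniform(lo, hi))))
    return Phylogeny(root)


def enumerate_unrooted_topologies(names: list[str]):
    """All unrooted binary topologies (1, 3, 15, 105, ... trees)."""

    def grow(tree: Phylogeny, remaining: list[str]):
        if not remaining:
            yield tree.copy()
            return
        name, rest = remaining[0], remaining[1:]
        edges = [n for n in tree.postorder() if n.parent is not None]
        for i in range(len(edges)):
            cand = tree.copy()
            edge = [n for n in cand.postorder() if n.parent is not None][i]
            parent = edge.parent
            mid = Node()
            parent.children[parent.children.index(edge)] = mid
            mid.parent = parent
            mid.add(edge)
            mid.add(Node(name))
            yield from grow(cand, rest)

    root = Node()
    for n in names[:3]:
        root.add(Node(n))
    yield from grow(Phylogeny(root), list(names[3:]))


def four_taxon_trees() -> dict[str, Phylogeny]:
    """The three unrooted quartet topologies on A, B, C, D."""
    return {
        "AB|CD": Phylogeny.from_newick("(A,B,(C,D));"),
        "AC|BD": Phylogeny.from_newick("(A,C,(B,D));"),
        "AD|BC": Phylogeny.from_newick("(A,D,(B,C));"),
    }


def genome_to_matrix_column(genome, matrix, genome_pos: int) -> int | None:
    """Map a genome coordinate to its supermatrix column (None in spacers)."""
    from mitophylo.gene_table import LIGHT_STRAND

    for f in genome.features:
        if f.start <= genome_pos < f.end:
            s, _ = matrix.partitions[f.gene_name]
            if f.gene_name in LIGHT_STRAND:
                return s + (f.end - 1 - genome_pos)
            return s + (genome_pos - f.start)
    return None
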