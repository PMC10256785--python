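"""Native tree inference: NJ on difference counts, equal-weight Fitch
parsimony with SPR search, and GTR+I likelihood with NNI search, plus
the nonparametric bootstrap.

These are the package's own implementations (the scientific core), not
wrappers.  All methods honor the supermatrix exclusion mask and an
optional codon-position filter; gap and ambiguity cells are treated as
missing data throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .genome_io import Supermatrix
from .phylo import Node, Phylogeny, star_tree
from .sitestats import P123, PositionFilter

logger = logging.getLogger(__name__)

# 4-bit state masks: A=1 C=2 G=4 T=8; missing/gap = all four
_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}
_IUPAC = {
    "R": 5, "Y": 10, "S": 6, "W": 9, "K": 12, "M": 3,
    "B": 14, "D": 13, "H": 11, "V": 7, "N": 15, "-": 15, "?": 15,
}
_MASK_LUT = np.full(256, 15, dtype=np.uint8)
for _ch, _v in {**_BITS, **_IUPAC}.items():
    _MASK_LUT[ord(_ch)] = _v

_LOWBIT_LUT = np.zeros(16, dtype=np.uint8)
for _m in range(1, 16):
    _LOWBIT_LUT[_m] = _m & (-_m)


# --------------------------------------------------------------------- #
# distances and neighbor joining
# --------------------------------------------------------------------- #

@dataclass
class DistanceMatrix:
    taxa: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        self.values = v

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.taxa.index(pair[0]), self.taxa.index(pair[1])
        return float(self.values[i, j])


def pairwise_differences(
    matrix: Supermatrix, position_filter: PositionFilter | None = P123
) -> DistanceMatrix:
    """Counts of differing retained columns where both cells are plain bases."""
    if matrix.n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    positions = position_filter.retained if position_filter else None
    cols = matrix.retained_columns(positions)
    codes = _MASK_LUT[matrix.data[:, cols].view(np.uint8)]
    plain = np.isin(codes, (1, 2, 4, 8))
    n = matrix.n_taxa
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            usable = plain[i] & plain[j]
            d = np.count_nonzero(usable & (codes[i] != codes[j]))
            D[i, j] = D[j, i] = d
    return DistanceMatrix(matrix.accessions, D)


def neighbor_joining(D: DistanceMatrix) -> Phylogeny:
    """Saitou-Nei neighbor joining; returns an unrooted tree (trifurcating
    root).  Negative branch-length estimates are clamped to zero with the
    deficit shifted to the sibling branch (logged)."""
    n = len(D.taxa)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    d = D.values.astype(float).copy()
    nodes: list[Node] = [Node(name) for name in D.taxa]
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        ai, aj = divmod(int(np.argmin(q)), m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        vi = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        vj = dij - vi
        if vi < 0 or vj < 0:
            logger.info("NJ: clamped negative branch length at join %s/%s",
                        nodes[i].name, nodes[j].name)
            if vi < 0:
                vj, vi = vj + vi, 0.0
            else:
                vi, vj = vi + vj, 0.0
        parent = Node()
        nodes[i].length = max(vi, 0.0)
        nodes[j].length = max(vj, 0.0)
        parent.add(nodes[i])
        parent.add(nodes[j])
        # distances from the new node to the others
        old_n = d.shape[0]
        new = np.zeros(old_n)
        for k in active:
            if k in (i, j):
                continue
            new[k] = 0.5 * (d[i, k] + d[j, k] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new
        d[:-1, -1] = new
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]
    # join the last three around a trifurcating root
    i, j, k = active
    dij, dik, djk = d[i, j], d[i, k], d[j, k]
    root = Node()
    for idx, length in (
        (i, 0.5 * (dij + dik - djk)),
        (j, 0.5 * (dij + djk - dik)),
        (k, 0.5 * (dik + djk - dij)),
    ):
        nodes[idx].length = max(length, 0.0)
        root.add(nodes[idx])
    return Phylogeny(root)


# --------------------------------------------------------------------- #
# Fitch parsimony
# --------------------------------------------------------------------- #

class FitchEngine:
    """Pattern-compressed Fitch length evaluator for one dataset."""

    def __init__(
        self,
        matrix: Supermatrix,
        position_filter: PositionFilter | None = P123,
        columns: np.ndarray | None = None,
    ):
        positions = position_filter.retained if position_filter else None
        cols = matrix.retained_columns(positions) if columns is None else np.asarray(columns)
        codes = _MASK_LUT[matrix.data[:, cols].view(np.uint8)]
        patterns, weights = np.unique(codes, axis=1, return_counts=True)
        if patterns.shape[1]:
            # patterns where every taxon shares a state never cost changes
            keep = np.bitwise_and.reduce(patterns, axis=0) == 0
            patterns, weights = patterns[:, keep], weights[keep]
        self.patterns = patterns
        self.weights = weights
        self.leaf_rows = {acc: i for i, acc in enumerate(matrix.accessions)}

    def _leaf_masks(self, name: str) -> np.ndarray:
        try:
            return self.patterns[self.leaf_rows[name]]
        except KeyError:
            raise ValueError(f"tree leaf {name!r} is not a matrix taxon") from None

    def length(self, tree: Phylogeny) -> int:
        """Equal-weight parsimony length of the tree on this dataset."""
        total = 0
        sets: dict[Node, np.ndarray] = {}
        for node in tree.postorder():
            if node.is_leaf:
                sets[node] = self._leaf_masks(node.name)
                continue
            acc = sets[node.children[0]]
            for child in node.children[1:]:
                inter = acc & sets[child]
                disjoint = inter == 0
                total += int(self.weights[disjoint].sum())
                acc = np.where(disjoint, acc | sets[child], inter)
            sets[node] = acc
        return total

    def branch_lengths(self, tree: Phylogeny) -> int:
        """Assign per-branch substitution counts in place (ACCTRAN-style
        deterministic traceback); returns the total length."""
        work = tree
        sets: dict[Node, np.ndarray] = {}
        for node in work.postorder():
            if node.is_leaf:
                sets[node] = self._leaf_masks(node.name)
        counts: dict[Node, int] = {}
        # down-pass (children already available via postorder)
        for node in work.postorder():
            if node.is_leaf:
                continue
            acc = sets[node.children[0]]
            for child in node.children[1:]:
                inter = acc & sets[child]
                acc = np.where(inter == 0, acc | sets[child], inter)
            sets[node] = acc

        def assign(node: Node, state: np.ndarray) -> None:
            for child in node.children:
                s = sets[child]
                keep = (state & s) != 0
                child_state = np.where(keep, state, _LOWBIT_LUT[s])
                counts[child] = counts.get(child, 0) + int(
                    self.weights[child_state != state].sum()
                )
                assign(child, child_state)

        root = work.root
        if len(root.children) <= 2:
            state = _LOWBIT_LUT[sets[root]]
            assign(root, state)
        else:
            # root the traceback on the edge above the last child so that
            # virtual-node changes land on a real edge
            *rest, last = root.children
            acc = sets[rest[0]]
            for child in rest[1:]:
                inter = acc & sets[child]
                acc = np.where(inter == 0, acc | sets[child], inter)
            v_set = acc
            inter = v_set & sets[last]
            final = np.where(inter == 0, v_set | sets[last], inter)
            state = _LOWBIT_LUT[final]
            keep_v = (state & v_set) != 0
            v_state = np.where(keep_v, state, _LOWBIT_LUT[v_set])
            keep_l = (state & sets[last]) != 0
            l_state = np.where(keep_l, state, _LOWBIT_LUT[sets[last]])
            counts[last] = int(
                self.weights[(l_state != state) | (v_state != state)].sum()
            )
            assign(last, l_state)
            for child in rest:
                s = sets[child]
                keep = (v_state & s) != 0
                child_state = np.where(keep, v_state, _LOWBIT_LUT[s])
                counts[child] = int(self.weights[child_state != v_state].sum())
                assign(child, child_state)
        total = 0
        for node in work.postorder():
            if node is work.root:
                node.length = None
                continue
            node.length = float(counts.get(node, 0))
            total += counts.get(node, 0)
        return total


def fitch_length(
    tree: Phylogeny,
    matrix: Supermatrix,
    position_filter: PositionFilter | None = P123,
) -> int:
    """Minimum number of state changes (equal weights, missing = union)."""
    engine = FitchEngine(matrix, position_filter)
    names = set(tree.leaf_names())
    taxa = set(matrix.accessions)
    if names != taxa:
        raise ValueError(
            f"tree leaves and matrix taxa differ: {sorted(names ^ taxa)}"
        )
    return engine.length(tree)


# --------------------------------------------------------------------- #
# parsimony search
# --------------------------------------------------------------------- #

def _split_edge_and_attach(tree: Phylogeny, edge_child: Node, subtree: Node) -> None:
    """Insert a new internal node on the edge above ``edge_child`` and hang
    ``subtree`` from it (in place)."""
    parent = edge_child.parent
    mid = Node()
    parent.children[parent.children.index(edge_child)] = mid
    mid.parent = parent
    mid.add(edge_child)
    mid.add(subtree)


def _detach_subtree(tree: Phylogeny, node: Node) -> None:
    """Remove ``node`` (with its subtree) and splice out its parent."""
    parent = node.parent
    parent.children.remove(node)
    node.parent = None
    if parent is tree.root:
        if len(parent.children) == 1:
            tree.root = parent.children[0]
            tree.root.parent = None
    elif len(parent.children) == 1:
        only = parent.children[0]
        grand = parent.parent
        grand.children[grand.children.index(parent)] = only
        only.parent = grand


def _edges(tree: Phylogeny) -> list[Node]:
    return [n for n in tree.postorder() if n.parent is not None]


def _stepwise_addition(engine: FitchEngine, order: list[str]) -> Phylogeny:
    tree = star_tree(order[:3])
    for name in order[3:]:
        best: tuple[int, int] | None = None
        for idx in range(len(_edges(tree))):
            cand = tree.copy()
            _split_edge_and_attach(cand, _edges(cand)[idx], Node(name))
            score = engine.length(cand)
            if best is None or score < best[0]:
                best = (score, idx)
        _split_edge_and_attach(tree, _edges(tree)[best[1]], Node(name))
    return tree


def _spr_neighbors(tree: Phylogeny) -> Iterable[Phylogeny]:
    """All subtree-prune-regraft neighbors of an unrooted tree."""
    n_edges = len(_edges(tree))
    for prune_idx in range(n_edges):
        base = tree.copy()
        edges = _edges(base)
        sub = edges[prune_idx]
        if sub.parent is base.root and len(base.root.children) <= 2:
            continue
        _detach_subtree(base, sub)
        if len(base.leaves()) < 2 or base.root.is_leaf:
            continue
        for target_idx, target in enumerate(_edges(base)):
            cand = base.copy()
            cand_target = _edges(cand)[target_idx]
            sub_copy = Phylogeny(sub).copy().root
            _split_edge_and_attach(cand, cand_target, sub_copy)
            yield cand


def mp_search(
    matrix: Supermatrix,
    n_starts: int = 10,
    seed: int | None = None,
    position_filter: PositionFilter | None = P123,
) -> list[Phylogeny]:
    """Equal-weight parsimony search: random-addition starts followed by
    SPR hill climbing.  Returns every distinct topology attaining the best
    length found, in canonical order, with per-branch substitution counts
    assigned by the deterministic Fitch traceback."""
    if matrix.n_taxa < 4:
        raise ValueError("parsimony search requires at least 4 taxa")
    rng = np.random.default_rng(seed)
    engine = FitchEngine(matrix, position_filter)
    names = matrix.accessions
    best_len: int | None = None
    best_trees: dict[frozenset, Phylogeny] = {}

    def consider(tree: Phylogeny, score: int) -> None:
        nonlocal best_len
        if best_len is None or score < best_len:
            best_len = score
            best_trees.clear()
        if score == best_len:
            best_trees.setdefault(tree.splits(), tree)

    for _ in range(n_starts):
        order = list(names)
        rng.shuffle(order)
        tree = _stepwise_addition(engine, order)
        score = engine.length(tree)
        consider(tree, score)
        improved = True
        while improved:
            improved = False
            for cand in _spr_neighbors(tree):
                s = engine.length(cand)
                if s < score:
                    tree, score = cand, s
                    improved = True
                    break
                consider(cand, s)
            consider(tree, score)
    out = []
    for key in sorted(best_trees, key=lambda k: sorted(map(sorted, k))):
        t = best_trees[key]
        engine.branch_lengths(t)
        out.append(t)
    return out


# --------------------------------------------------------------------- #
# GTR + I likelihood
# --------------------------------------------------------------------- #

_RATE_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))  # AC AG AT CG CT GT


@dataclass
class GTRParams:
    """General time-reversible model with a proportion of invariant sites.

    ``rates`` are the six exchangeabilities in the order AC, AG, AT, CG,
    CT, GT; ``freqs`` are the stationary frequencies of A, C, G, T.
    """

    rates: np.ndarray = field(default_factory=lambda: np.ones(6))
    freqs: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    p_inv: float = 0.0

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.rates.shape != (6,) or np.any(self.rates <= 0):
            raise ValueError("need 6 positive exchangeabilities")
        if self.freqs.shape != (4,) or not np.isclose(self.freqs.sum(), 1.0):
            raise ValueError("frequencies must sum to 1")
        if np.any(self.freqs <= 0):
            raise ValueError("frequencies must be positive")
        if not 0.0 <= self.p_inv < 1.0:
            raise ValueError("p_inv must lie in [0, 1)")

    @classmethod
    def jc(cls) -> "GTRParams":
        return cls()

    def rate_matrix(self) -> np.ndarray:
        """Q normalized to one expected substitution per site per unit time."""
        Q = np.zeros((4, 4))
        for r, (i, j) in zip(self.rates, _RATE_PAIRS):
            Q[i, j] = r * self.freqs[j]
            Q[j, i] = r * self.freqs[i]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -float(np.dot(self.freqs, np.diag(Q)))
        return Q / mu


class GTREngine:
    """Felsenstein pruning over compressed site patterns with a +I mixture.

    Branch lengths are expected substitutions per site over all sites;
    the variable class therefore evolves at length t / (1 - p_inv).
    """

    def __init__(
        self,
        matrix: Supermatrix,
        position_filter: PositionFilter | None = P123,
        columns: np.ndarray | None = None,
    ):
        positions = position_filter.retained if position_filter else None
        cols = matrix.retained_columns(positions) if columns is None else np.asarray(columns)
        if len(cols) == 0:
            raise ValueError("no retained columns")
        codes = _MASK_LUT[matrix.data[:, cols].view(np.uint8)]
        patterns, weights = np.unique(codes, axis=1, return_counts=True)
        self.weights = weights.astype(float)
        npat = patterns.shape[1]
        n = matrix.n_taxa
        tips = np.zeros((n, npat, 4))
        for b in range(4):
            tips[:, :, b] = (patterns & (1 << b)) != 0
        self.tips = tips
        self.leaf_rows = {acc: i for i, acc in enumerate(matrix.accessions)}
        # per-pattern indicator that all taxa are compatible with base b
        self.invariant_support = tips.prod(axis=0)  # (npat, 4)
        self.n_sites = int(weights.sum())
        self._eig: tuple | None = None
        self._eig_key: bytes | None = None

    def empirical_freqs(self) -> np.ndarray:
        plain = (self.tips.sum(axis=2) == 1)  # unambiguous cells
        tally = np.zeros(4)
        for b in range(4):
            tally[b] = (self.tips[:, :, b] * plain * self.weights[None, :]).sum()
        tally = np.maximum(tally, 1.0)
        return tally / tally.sum()

    def constant_fraction(self) -> float:
        const = (self.invariant_support.sum(axis=1) > 0)
        return float(self.weights[const].sum() / self.n_sites)

    def _eigen(self, params: GTRParams):
        key = params.rates.tobytes() + params.freqs.tobytes()
        if self._eig_key != key:
            Q = params.rate_matrix()
            sq = np.sqrt(params.freqs)
            # detailed balance makes D^1/2 Q D^-1/2 symmetric
            B = Q * sq[:, None] / sq[None, :]
            B = 0.5 * (B + B.T)
            lam, U = np.linalg.eigh(B)
            left = U.T * sq[None, :]
            right = U / sq[:, None]
            self._eig = (lam, right, left)
            self._eig_key = key
        return self._eig

    def transition(self, params: GTRParams, t: float) -> np.ndarray:
        lam, right, left = self._eigen(params)
        with np.errstate(over="ignore", invalid="ignore"):
            P = (right * np.exp(np.minimum(lam * t, 700.0))[None, :]) @ left
        return np.clip(np.nan_to_num(P, nan=0.0, posinf=0.0), 0.0, None)

    def log_likelihood(self, tree: Phylogeny, params: GTRParams) -> float:
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            return self._log_likelihood(tree, params)

    def _log_likelihood(self, tree: Phylogeny, params: GTRParams) -> float:
        scale = 1.0 / (1.0 - params.p_inv) if params.p_inv > 0 else 1.0
        partial: dict[Node, np.ndarray] = {}
        for node in tree.postorder():
            if node.is_leaf:
                try:
                    partial[node] = self.tips[self.leaf_rows[node.name]]
                except KeyError:
                    raise ValueError(f"tree leaf {node.name!r} not in matrix") from None
                continue
            acc = None
            for child in node.children:
                t = child.length if child.length is not None else 0.0
                if t < 0 or not np.isfinite(t):
                    raise ValueError(f"invalid branch length {t}")
                P = self.transition(params, t * scale)
                term = partial[child] @ P.T
                acc = term if acc is None else acc * term
            partial[node] = acc
        site_var = partial[tree.root] @ params.freqs
        site = (1.0 - params.p_inv) * site_var
        if params.p_inv > 0:
            site = site + params.p_inv * (self.invariant_support @ params.freqs)
        if np.any(site <= 0):
            return -np.inf
        return float(np.dot(self.weights, np.log(site)))


def gtr_log_likelihood(
    tree: Phylogeny,
    matrix: Supermatrix,
    params: GTRParams,
    position_filter: PositionFilter | None = P123,
) -> float:
    """Log-likelihood of the supermatrix on the tree under GTR+I."""
    engine = GTREngine(matrix, position_filter)
    ll = engine.log_likelihood(tree, params)
    if not np.isfinite(ll):
        raise ValueError("non-finite log-likelihood (zero site likelihood)")
    return ll


# --------------------------------------------------------------------- #
# ML search
# --------------------------------------------------------------------- #

_BL_BOUNDS = (1e-9, 10.0)


def _optimize_branches(
    tree: Phylogeny, params: GTRParams, engine: GTREngine, rounds: int = 2
) -> float:
    ll = engine.log_likelihood(tree, params)
    for _ in range(rounds):
        for node in tree.postorder():
            if node is tree.root:
                continue
            saved = node.length if node.length is not None else 0.0

            def score(t: float) -> float:
                node.length = t
                return -engine.log_likelihood(tree, params)

            res = minimize_scalar(
                score, bounds=_BL_BOUNDS, method="bounded",
                options={"xatol": 1e-8},
            )
            if -res.fun >= ll:
                node.length = float(res.x)
                ll = -res.fun
            else:
                node.length = saved
    return ll


def _optimize_params(
    tree: Phylogeny, params: GTRParams, engine: GTREngine
) -> tuple[GTRParams, float]:
    freqs = params.freqs

    def unpack(x: np.ndarray) -> GTRParams:
        rates = np.append(np.exp(np.clip(x[:5], -8.0, 8.0)), 1.0)
        p_inv = 1.0 / (1.0 + np.exp(-np.clip(x[5], -12.0, 12.0)))
        p_inv = min(max(p_inv, 0.0), 0.99)
        return GTRParams(rates=rates, freqs=freqs, p_inv=p_inv)

    def objective(x: np.ndarray) -> float:
        try:
            ll = engine.log_likelihood(tree, unpack(x))
        except (ValueError, FloatingPointError, np.linalg.LinAlgError):
            return 1e12
        return -ll if np.isfinite(ll) else 1e12

    x0 = np.concatenate([
        np.log(np.maximum(params.rates[:5] / params.rates[5], 1e-6)),
        [np.log(max(params.p_inv, 1e-3) / max(1 - params.p_inv, 1e-3))],
    ])
    bounds = [(-8.0, 8.0)] * 5 + [(-12.0, 12.0)]
    res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 200, "ftol": 1e-10})
    best = unpack(res.x)
    try:
        ll = engine.log_likelihood(tree, best)
    except np.linalg.LinAlgError:
        ll = -np.inf
    ll0 = engine.log_likelihood(tree, params)
    if ll0 > ll:
        return params, ll0
    return best, ll


def _swap_subtrees(a: Node, b: Node) -> None:
    pa, pb = a.parent, b.parent
    pa.children[pa.children.index(a)] = b
    pb.children[pb.children.index(b)] = a
    a.parent, b.parent = pb, pa


def _nni_candidates(tree: Phylogeny) -> list[tuple[Node, Node, Node]]:
    """(edge_child, subtree_below, subtree_across) triples describing the
    two alternative arrangements around each internal edge."""
    out = []
    for v in tree.postorder():
        u = v.parent
        if v.is_leaf or u is None:
            continue
        if u is tree.root and len(u.children) >= 3:
            others = [c for c in u.children if c is not v]
            out.append((v, v.children[0], others[0]))
            out.append((v, v.children[0], others[1]))
        elif u is not tree.root:
            w = next(c for c in u.children if c is not v)
            out.append((v, v.children[0], w))
            out.append((v, v.children[1], w))
    return out


@dataclass
class MLResult:
    tree: Phylogeny
    params: GTRParams
    log_likelihood: float
    trace: list[float]

    def __iter__(self):  # allows `tree, params = ml_search(...)`
        return iter((self.tree, self.params))


def ml_search(
    matrix: Supermatrix,
    start: Phylogeny | None = None,
    seed: int | None = None,
    position_filter: PositionFilter | None = P123,
    tol: float = 1e-6,
    max_rounds: int = 20,
) -> MLResult:
    """GTR+I maximum likelihood: NNI topology moves alternating with
    numeric optimization of branch lengths and model parameters.

    The default start tree is neighbor joining on difference counts with
    branch lengths rescaled to substitutions per site.
    """
    engine = GTREngine(matrix, position_filter)
    if start is None:
        tree = neighbor_joining(pairwise_differences(matrix, position_filter))
        for node in tree.postorder():
            if node.length is not None:
                node.length = max(node.length / engine.n_sites, _BL_BOUNDS[0])
    else:
        tree = start.copy()
        for node in tree.postorder():
            if node is not tree.root and (node.length is None or node.length <= 0):
                node.length = _BL_BOUNDS[0]
    params = GTRParams(
        rates=np.array([1.0, 4.0, 1.0, 1.0, 4.0, 1.0]),
        freqs=engine.empirical_freqs(),
        p_inv=0.5 * engine.constant_fraction(),
    )
    trace: list[float] = []
    ll = engine.log_likelihood(tree, params)
    trace.append(ll)
    for _ in range(max_rounds):
        ll = _optimize_branches(tree, params, engine)
        params, ll = _optimize_params(tree, params, engine)
        trace.append(ll)
        # NNI sweep: try both arrangements at every internal edge
        best_gain = 0.0
        best_move = None
        for v, below, across in _nni_candidates(tree):
            saved_len = v.length
            _swap_subtrees(below, across)

            def score(t: float) -> float:
                v.length = t
                return -engine.log_likelihood(tree, params)

            res = minimize_scalar(score, bounds=_BL_BOUNDS, method="bounded",
                                  options={"xatol": 1e-8})
            gain = (-res.fun) - ll
            _swap_subtrees(below, across)
            v.length = saved_len
            if gain > best_gain + tol:
                best_gain = gain
                best_move = (v, below, across, float(res.x))
        if best_move is None:
            break
        v, below, across, new_len = best_move
        _swap_subtrees(below, across)
        v.length = new_len
        ll = engine.log_likelihood(tree, params)
        trace.append(ll)
    ll = _optimize_branches(tree, params, engine)
    params, ll = _optimize_params(tree, params, engine)
    trace.append(ll)
    if not np.isfinite(ll):
        raise ValueError("ML search ended with non-finite likelihood")
    return MLResult(tree, params, ll, trace)


# --------------------------------------------------------------------- #
# bootstrap
# --------------------------------------------------------------------- #

def _node_splits(tree: Phylogeny) -> dict[Node, frozenset[str]]:
    all_names = frozenset(tree.leaf_names())
    ref = min(all_names)
    below: dict[Node, frozenset[str]] = {}
    out: dict[Node, frozenset[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[node] = frozenset([node.name])
        else:
            below[node] = frozenset().union(*(below[c] for c in node.children))
        if node.parent is None:
            continue
        side = below[node]
        if ref in side:
            side = all_names - side
        if 1 < len(side) < len(all_names) - 1:
            out[node] = side
    return out


def bootstrap(
    matrix: Supermatrix,
    method: str = "nj",
    B: int = 100,
    seed: int | None = None,
    position_filter: PositionFilter | None = P123,
    point_tree: Phylogeny | None = None,
    mp_starts: int = 1,
) -> Phylogeny:
    """Nonparametric bootstrap over retained columns.

    Columns are resampled with replacement; each replicate is analyzed
    with the same method, and support for every bipartition of the point
    estimate is the percentage of replicates containing it.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if method not in ("nj", "mp", "ml"):
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    positions = position_filter.retained if position_filter else None
    cols = matrix.retained_columns(positions)

    def infer(sub: Supermatrix, rep_seed: int) -> Phylogeny:
        if method == "nj":
            return neighbor_joining(pairwise_differences(sub, None))
        if method == "mp":
            return mp_search(sub, n_starts=mp_starts, seed=rep_seed,
                             position_filter=None)[0]
        return ml_search(sub, seed=rep_seed, position_filter=None).tree

    if point_tree is None:
        point_tree = infer(matrix.subset_columns(cols), int(rng.integers(2**31)))
    tree = point_tree.copy()
    tally: dict[frozenset[str], int] = {}
    for b in range(B):
        resampled = rng.choice(cols, size=len(cols), replace=True)
        rep = infer(matrix.subset_columns(resampled), int(rng.integers(2**31)))
        for split in rep.splits():
            tally[split] = tally.get(split, 0) + 1
    for node, split in _node_splits(tree).items():
        node.support = 100.0 * tally.get(split, 0) / B
    return tree
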