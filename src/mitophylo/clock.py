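"""Strict-clock linearization and fixed-rate divergence dating.

A rooted tree with branch lengths in substitutions/site is projected
onto an ultrametric (clock-like) tree: each internal node's height is
the mean over leaf pairs spanning that node of half their patristic
distance (the least-squares projection for balanced designs), with
nesting enforced.  When GTR parameters and the alignment are supplied,
heights are then refined by constrained maximum likelihood with the
topology fixed.  Node heights convert to ages through a single fixed
substitution rate applied per lineage: age[Kyr] = height / (rate/1000).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .genome_io import Supermatrix
from .phylo import Node, Phylogeny, patristic_distances
from .sitestats import P123, PositionFilter
from .treeinfer import GTREngine, GTRParams


@dataclass(frozen=True)
class ClockConfig:
    """Fixed clock rate in substitutions/site/Myr and the outgroup label(s)."""

    rate: float = 0.0115
    outgroup: tuple[str, ...] = ()

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("clock rate must be positive")


def node_age(height: float, config: ClockConfig) -> float:
    """Convert a node height (substitutions/site) to an age in Kyr.

    The rate is per lineage, so a height of 0.0115 subs/site at
    0.0115 subs/site/Myr dates a node to exactly 1000 Ka.
    """
    if height < 0:
        raise ValueError("node height must be non-negative")
    return height / (config.rate * 1e-3)


@dataclass
class ClockTree:
    """Ultrametric rooted tree with node heights and ages.

    ``heights`` maps each node to its height in substitutions/site
    (leaves at 0); branch lengths on ``tree`` are height differences.
    """

    tree: Phylogeny
    heights: dict[Node, float]
    config: ClockConfig

    def age(self, node: Node) -> float:
        return node_age(self.heights[node], self.config)

    @property
    def root_age(self) -> float:
        return self.age(self.tree.root)

    def table(self) -> pd.DataFrame:
        below: dict[Node, list[str]] = {}
        rows = []
        for i, node in enumerate(self.tree.postorder()):
            if node.is_leaf:
                below[node] = [node.name]
                continue
            below[node] = sorted(
                itertools.chain.from_iterable(below[c] for c in node.children)
            )
            rows.append({
                "node_id": i,
                "clade_leaves": ",".join(below[node]),
                "height_subs_per_site": self.heights[node],
                "age_ka": round(self.age(node)),
            })
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        self.table().to_csv(path, sep="\t", index=False)

    def newick_with_ages(self) -> str:
        """Newick with rounded node ages (Ka) as internal labels."""
        t = self.tree.copy()
        # map by traversal order: copies preserve traversal order
        for orig, cp in zip(self.tree.postorder(), t.postorder()):
            if not cp.is_leaf:
                cp.name = str(round(self.age(orig)))
                cp.support = None
        return t.newick()


def _mean_spanning_heights(tree: Phylogeny) -> dict[Node, float]:
    """h(v) = mean over leaf pairs whose path crosses v of d(i,j)/2."""
    dist = patristic_distances(tree)
    below: dict[Node, list[str]] = {}
    heights: dict[Node, float] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[node] = [node.name]
            heights[node] = 0.0
            continue
        below[node] = list(
            itertools.chain.from_iterable(below[c] for c in node.children)
        )
        total, count = 0.0, 0
        for c1, c2 in itertools.combinations(node.children, 2):
            for a in below[c1]:
                for b in below[c2]:
                    total += dist[(a, b)]
                    count += 2
        heights[node] = total / count if count else 0.0
    return heights


def _enforce_nesting(tree: Phylogeny, heights: dict[Node, float]) -> None:
    for node in tree.postorder():
        if not node.is_leaf:
            floor = max(heights[c] for c in node.children)
            heights[node] = max(heights[node], floor)


def _apply_heights(tree: Phylogeny, heights: dict[Node, float]) -> None:
    for node in tree.postorder():
        if node.parent is not None:
            node.length = max(heights[node.parent] - heights[node], 0.0)


def _ml_refine(
    tree: Phylogeny,
    heights: dict[Node, float],
    engine: GTREngine,
    params: GTRParams,
) -> dict[Node, float]:
    """Constrained-ML node heights: optimize root height and per-node
    parent fractions with the topology fixed."""
    internals = [n for n in tree.preorder() if not n.is_leaf and n is not tree.root]
    root = tree.root
    h_root0 = max(heights[root], 1e-8)

    def build(x: np.ndarray) -> dict[Node, float]:
        h = {root: float(np.exp(np.clip(x[0], -30.0, 3.0)))}
        fracs = 1.0 / (1.0 + np.exp(-np.clip(x[1:], -12.0, 12.0)))
        for node, f in zip(internals, fracs):
            h[node] = h[node.parent] * float(f)
        for node in tree.postorder():
            if node.is_leaf:
                h[node] = 0.0
        return h

    def objective(x: np.ndarray) -> float:
        h = build(x)
        _apply_heights(tree, h)
        ll = engine.log_likelihood(tree, params)
        return -ll if np.isfinite(ll) else 1e12

    x0 = [np.log(h_root0)]
    for node in internals:
        f = heights[node] / max(heights[node.parent], 1e-12)
        f = min(max(f, 1e-3), 1.0 - 1e-3)
        x0.append(np.log(f / (1.0 - f)))
    bounds = [(-30.0, 3.0)] + [(-12.0, 12.0)] * len(internals)
    res = minimize(objective, np.array(x0), method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 300, "ftol": 1e-10})
    best = build(res.x)
    # keep the better of LS and ML solutions (optimizer can stall)
    _apply_heights(tree, best)
    ll_ml = engine.log_likelihood(tree, params)
    _apply_heights(tree, heights)
    ll_ls = engine.log_likelihood(tree, params)
    return best if ll_ml >= ll_ls else dict(heights)


def linearize(
    tree: Phylogeny,
    matrix: Supermatrix | None = None,
    config: ClockConfig = ClockConfig(),
    params: GTRParams | None = None,
    position_filter: PositionFilter = P123,
) -> ClockTree:
    """Project a tree onto a strict clock and return a dated ClockTree.

    The tree is rooted with ``config.outgroup`` if it is not already
    rooted (bifurcating root).  Heights come from the least-squares
    (mean spanning pair) projection; when ``matrix`` and ``params`` are
    both given, heights are refined by constrained ML.
    """
    if len(tree.root.children) == 2:
        rooted = tree.copy()
    else:
        if not config.outgroup:
            raise ValueError("tree is unrooted and no outgroup is configured")
        missing = set(config.outgroup) - set(tree.leaf_names())
        if missing:
            raise ValueError(f"outgroup leaves absent from tree: {sorted(missing)}")
        rooted = tree.root_with_outgroup(config.outgroup)
    heights = _mean_spanning_heights(rooted)
    _enforce_nesting(rooted, heights)
    if matrix is not None and params is not None:
        engine = GTREngine(matrix, position_filter)
        heights = _ml_refine(rooted, heights, engine, params)
        _enforce_nesting(rooted, heights)
    _apply_heights(rooted, heights)
    return ClockTree(rooted, heights, config)
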