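"""Taxonomic quality control on trees and alignments.

Three related diagnostics, all driven by the observation that a
sequence's nearest relatives on the tree should share its label:

* patristic within-label vs between-label distance comparisons,
* misassignment flagging (a leaf closer to, and nested inside, a
  foreign label's clade),
* detection of faulty or chimeric sequences through unbroken runs of
  parsimony-informative sites shared exclusively by one pair of taxa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .genome_io import Supermatrix
from .phylo import Phylogeny, patristic_distances
from .sitestats import P123, PositionFilter, classify_sites
from .treeinfer import DistanceMatrix

logger = logging.getLogger(__name__)


def patristic_matrix(tree: Phylogeny) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix (invariant under re-rooting)."""
    dist = patristic_distances(tree)
    names = sorted(tree.leaf_names())
    n = len(names)
    values = np.zeros((n, n))
    for i, a in enumerate(names):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = dist[(a, names[j])]
    return DistanceMatrix(names, values)


@dataclass
class PatristicReport:
    """Within/between-label patristic summaries.

    ``within_max`` is None for single-member labels (undefined, never 0).
    """

    within_max: dict[str, float | None]
    between: dict[tuple[str, str], tuple[float, float]]  # (min, max)
    pairs: pd.DataFrame

    def between_lt_within(self, pair: tuple[str, str], label: str) -> bool | None:
        """Is the between-pair maximum smaller than the within-label max?"""
        key = tuple(sorted(pair))
        w = self.within_max.get(label)
        if w is None or key not in self.between:
            return None
        return self.between[key][1] < w

    def comparisons(self) -> pd.DataFrame:
        rows = []
        for pair, (_, bmax) in sorted(self.between.items()):
            for label, w in sorted(self.within_max.items()):
                if w is None:
                    continue
                rows.append({
                    "label_a": pair[0], "label_b": pair[1],
                    "between_max": bmax, "within_label": label,
                    "within_max": w, "between_lt_within": bmax < w,
                })
        return pd.DataFrame(rows)


def within_between_report(
    tree: Phylogeny, labels: Mapping[str, str]
) -> PatristicReport:
    """Patristic distance summary per label and per label pair."""
    if len(set(labels.values())) < 2:
        raise ValueError("need at least 2 labels")
    D = patristic_matrix(tree)
    rows = []
    for i, a in enumerate(D.taxa):
        for j in range(i + 1, len(D.taxa)):
            b = D.taxa[j]
            rows.append({
                "a": a, "b": b,
                "label_a": labels[a], "label_b": labels[b],
                "distance": D.values[i, j],
            })
    pairs = pd.DataFrame(rows)
    within_max: dict[str, float | None] = {}
    for label in sorted(set(labels.values())):
        sub = pairs[(pairs.label_a == label) & (pairs.label_b == label)]
        within_max[label] = float(sub.distance.max()) if len(sub) else None
    between: dict[tuple[str, str], tuple[float, float]] = {}
    mixed = pairs[pairs.label_a != pairs.label_b]
    for _, r in mixed.iterrows():
        key = tuple(sorted((r.label_a, r.label_b)))
        lo, hi = between.get(key, (np.inf, -np.inf))
        between[key] = (min(lo, r.distance), max(hi, r.distance))
    return PatristicReport(within_max, between, pairs)


@dataclass
class AuditFlag:
    accession: str
    flag_kind: str  # misassigned | chimeric_run | attraction_outlier
    evidence: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        return {"accession": self.accession, "flag": self.flag_kind,
                **{f"evidence_{k}": v for k, v in self.evidence.items()}}


def flag_misassigned(
    tree: Phylogeny, labels: Mapping[str, str], strict: bool = False
) -> list[AuditFlag]:
    """Flag leaves that are patristically closer to a foreign multi-member
    label than to their own label AND nest inside that label's clade.

    A single-member label placed inside another label's clade is treated
    as legitimate nested phylogeographic structure unless ``strict``.

    The distance to the leaf's own label is measured against the label's
    medoid member, so a pair of co-misassigned sequences cannot vouch
    for each other.  Flags are accepted iteratively, strongest first,
    with flagged leaves removed from their claimed label's pool, then
    re-validated against the cleaned pools; this keeps an interloper
    from dragging its correctly labeled neighbors into spurious flags.
    """
    pools: dict[str, set[str]] = {}
    for acc, label in labels.items():
        pools.setdefault(label, set()).add(acc)
    dist = patristic_distances(tree)
    sides = _split_sides(tree)

    def smallest_side(a: str, b: str) -> frozenset[str]:
        best = None
        for side in sides:
            if a in side and b in side and (best is None or len(side) < len(best)):
                best = side
        return best if best is not None else frozenset(labels)

    def medoid_distance(acc: str, pool: set[str]) -> float:
        """Distance from acc to the most central other member of pool."""
        others = [a for a in pool if a != acc]
        if not others:
            return np.inf
        if len(others) == 1:
            return dist[(acc, others[0])]
        medoid = min(
            sorted(others),
            key=lambda a: sum(dist[(a, b)] for b in others if b != a),
        )
        return dist[(acc, medoid)]

    def evaluate(acc: str, current: dict[str, set[str]], flagged: set[str]):
        """Distance condition for one leaf; None when it looks at home."""
        label = labels[acc]
        own_others = current.get(label, set()) - {acc}
        if not own_others and not strict:
            return None
        d_same = medoid_distance(acc, current[label])
        multi = {l for l, m in current.items() if len(m - {acc}) >= 2}
        near_label, near_member, d_foreign = None, None, np.inf
        for other in sorted(multi - {label}):
            for a in sorted(current[other] - {acc}):
                if dist[(acc, a)] < d_foreign:
                    near_label, near_member = other, a
                    d_foreign = dist[(acc, a)]
        if near_label is None or d_foreign >= d_same:
            return None
        return near_label, near_member, d_foreign, d_same

    flags: dict[str, AuditFlag] = {}
    flagged: set[str] = set()
    while True:
        candidates = {}
        for acc in sorted(labels):
            if acc in flagged:
                continue
            hit = evaluate(acc, pools, flagged)
            if hit is not None:
                candidates[acc] = hit
        best = None
        for acc, (near_label, near_member, d_foreign, d_same) in candidates.items():
            # nesting: the smallest split side joining the leaf to its
            # nearest foreign member must hold only that foreign label;
            # flagged leaves and fellow candidates do not block
            side = smallest_side(acc, near_member)
            blockers = [
                l for l in side
                if l != acc and l not in flagged and l not in candidates
                and labels[l] != near_label
            ]
            if blockers:
                continue
            strength = (d_same - d_foreign) if np.isfinite(d_same) else np.inf
            flag = AuditFlag(acc, "misassigned", {
                "nearest_label": near_label,
                "distance_to_nearest_foreign": float(d_foreign),
                "distance_to_own_label": (
                    float(d_same) if np.isfinite(d_same) else None
                ),
            })
            if best is None or strength > best[0]:
                best = (strength, acc, flag)
        if best is None:
            break
        _, acc, flag = best
        flags[acc] = flag
        flagged.add(acc)
        pools[labels[acc]].discard(acc)
    # validation: drop flags that are no longer supported once every
    # confirmed interloper is out of its claimed pool
    changed = True
    while changed:
        changed = False
        for acc in sorted(flags):
            if evaluate(acc, pools, flagged) is None:
                pools[labels[acc]].add(acc)
                flagged.discard(acc)
                del flags[acc]
                changed = True
    return [flags[a] for a in sorted(flags)]


def _split_sides(tree: Phylogeny) -> list[frozenset[str]]:
    """Both sides of every non-trivial edge split of the (unrooted) tree."""
    all_names = frozenset(tree.leaf_names())
    below: dict = {}
    sides: set[frozenset[str]] = set()
    for node in tree.postorder():
        if node.is_leaf:
            below[node] = frozenset([node.name])
        else:
            below[node] = frozenset().union(*(below[c] for c in node.children))
        if node.parent is None:
            continue
        side = below[node]
        if 1 < len(side) < len(all_names) - 1:
            sides.add(side)
            sides.add(all_names - side)
        elif len(side) == len(all_names) - 1:
            sides.add(side)
    return sorted(sides, key=lambda s: (len(s), sorted(s)))


def informative_run_scan(
    matrix: Supermatrix,
    pair: tuple[str, str],
    position_filter: PositionFilter = P123,
    adjacency: str = "informative",
) -> list[tuple[int, int, int]]:
    """Runs of informative sites shared exclusively by one pair of taxa.

    At each parsimony-informative column, the pair is *exclusive* when
    both carry the same plain base and no other taxon does.  Runs are
    maximal stretches of exclusive sites that are consecutive in the
    sequence of informative columns (``adjacency="informative"``, the
    default) or at adjacent alignment positions (``adjacency="alignment"``).
    Returns (start_column, end_column, run_length) tuples, 0-based
    inclusive alignment coordinates.
    """
    if adjacency not in ("informative", "alignment"):
        raise ValueError(f"unknown adjacency mode {adjacency!r}")
    ia = matrix.row_index(pair[0])
    ib = matrix.row_index(pair[1])
    cls = classify_sites(matrix, position_filter)
    info_cols = cls.informative_columns()
    exclusive: list[int] = []
    for col in info_cols.tolist():
        a, b = bytes(matrix.data[ia, col]), bytes(matrix.data[ib, col])
        if a != b or a not in (b"A", b"C", b"G", b"T"):
            continue
        others = [
            bytes(matrix.data[i, col])
            for i in range(matrix.n_taxa)
            if i not in (ia, ib)
        ]
        if a not in others:
            exclusive.append(col)
    if not exclusive:
        return []
    info_index = {c: k for k, c in enumerate(info_cols.tolist())}
    runs: list[tuple[int, int, int]] = []
    start = prev = exclusive[0]
    length = 1
    for col in exclusive[1:]:
        if adjacency == "informative":
            contiguous = info_index[col] == info_index[prev] + 1
        else:
            contiguous = col == prev + 1
        if contiguous:
            length += 1
        else:
            runs.append((start, prev, length))
            start, length = col, 1
        prev = col
    runs.append((start, prev, length))
    return runs


def flag_chimeric_runs(
    matrix: Supermatrix,
    pairs: Iterable[tuple[str, str]] | None = None,
    min_run: int = 5,
    position_filter: PositionFilter = P123,
    adjacency: str = "informative",
) -> list[AuditFlag]:
    """Flag accession pairs joined by exclusive informative-site runs of
    at least ``min_run`` sites (the signature of shared faulty blocks)."""
    if pairs is None:
        accs = matrix.accessions
        pairs = [(a, b) for i, a in enumerate(accs) for b in accs[i + 1:]]
    flags = []
    for a, b in pairs:
        runs = [r for r in informative_run_scan(matrix, (a, b), position_filter,
                                                adjacency)
                if r[2] >= min_run]
        for start, end, length in runs:
            ev = {"partner": None, "run_start": start, "run_end": end,
                  "run_length": length}
            flags.append(AuditFlag(a, "chimeric_run", {**ev, "partner": b}))
            flags.append(AuditFlag(b, "chimeric_run", {**ev, "partner": a}))
    return flags


def audit_report(flags: Iterable[AuditFlag], path: str | Path | None = None) -> pd.DataFrame:
    df = pd.DataFrame([f.to_row() for f in flags])
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
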