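"""Lightweight rooted/unrooted phylogeny container.

Every inference module in this package operates on :class:`Phylogeny`,
a plain parent/child node structure.  Unrooted trees are stored rooted at
an arbitrary internal node with three (or more) children; rooted trees
have a bifurcating root.  Newick parsing is delegated to dendropy;
writing is direct string assembly.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Iterator

import dendropy


class Node:
    """Tree node. ``length`` is the length of the edge to the parent."""

    __slots__ = ("children", "parent", "length", "name", "support")

    def __init__(self, name: str | None = None, length: float | None = None):
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.length = length
        self.name = name
        self.support: float | None = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.name!r}, len={self.length})"


class Phylogeny:
    """A tree with named leaves, optional branch lengths and supports."""

    def __init__(self, root: Node):
        self.root = root

    # ------------------------------------------------------------------ #
    # traversal and basic queries
    # ------------------------------------------------------------------ #

    def postorder(self) -> Iterator[Node]:
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or node.is_leaf:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def internal_nodes(self, include_root: bool = True) -> list[Node]:
        out = [n for n in self.postorder() if not n.is_leaf]
        if not include_root:
            out = [n for n in out if n is not self.root]
        return out

    def find_leaf(self, name: str) -> Node:
        for leaf in self.leaves():
            if leaf.name == name:
                return leaf
        raise KeyError(f"leaf {name!r} not in tree")

    def mrca(self, names: Iterable[str]) -> Node:
        """Most recent common ancestor of the named leaves (given rooting)."""
        names = set(names)
        targets = [lf for lf in self.leaves() if lf.name in names]
        if len(targets) != len(names):
            missing = names - {lf.name for lf in targets}
            raise KeyError(f"leaves not in tree: {sorted(missing)}")
        paths = []
        for leaf in targets:
            path = []
            node: Node | None = leaf
            while node is not None:
                path.append(node)
                node = node.parent
            paths.append(path[::-1])
        anc = None
        for level in zip(*paths):
            if all(n is level[0] for n in level):
                anc = level[0]
            else:
                break
        assert anc is not None
        return anc

    def copy(self) -> "Phylogeny":
        def clone(node: Node) -> Node:
            new = Node(node.name, node.length)
            new.support = node.support
            for child in node.children:
                new.add(clone(child))
            return new

        return Phylogeny(clone(self.root))

    # ------------------------------------------------------------------ #
    # topology identity
    # ------------------------------------------------------------------ #

    def splits(self) -> frozenset[frozenset[str]]:
        """Non-trivial unrooted bipartitions, each given as the side not
        containing the lexicographically smallest leaf."""
        all_names = frozenset(self.leaf_names())
        ref = min(all_names)
        below: dict[Node, frozenset[str]] = {}
        out: set[frozenset[str]] = set()
        for node in self.postorder():
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
                out.add(side)
        return frozenset(out)

    def same_topology(self, other: "Phylogeny") -> bool:
        return (
            set(self.leaf_names()) == set(other.leaf_names())
            and self.splits() == other.splits()
        )

    # ------------------------------------------------------------------ #
    # rooting
    # ------------------------------------------------------------------ #

    def _make_root(self, node: Node) -> None:
        """Reverse parent pointers so ``node`` becomes the root (in place)."""
        path = []
        n: Node | None = node
        while n is not None:
            path.append(n)
            n = n.parent
        original = [(n.length, n.support) for n in path]
        for (child, parent), (length, support) in zip(
            zip(path[:-1], path[1:]), original[:-1]
        ):
            parent.children.remove(child)
            child.children.append(parent)
            parent.parent = child
            parent.length, parent.support = length, support
        node.parent = None
        node.length = None
        node.support = None
        old_root = path[-1]
        if len(old_root.children) == 1 and old_root is not node:
            # the old bifurcating root becomes a degree-2 node: splice it out
            only = old_root.children[0]
            grand = old_root.parent
            assert grand is not None
            grand.children[grand.children.index(old_root)] = only
            only.parent = grand
            if only.length is not None or old_root.length is not None:
                only.length = (only.length or 0.0) + (old_root.length or 0.0)
        self.root = node

    def root_with_outgroup(
        self, outgroup: str | Iterable[str], fraction: float = 0.5
    ) -> "Phylogeny":
        """Return a copy rooted on the edge above the outgroup clade.

        The edge subtended by the MRCA of the outgroup leaves is split
        ``fraction`` of its length on the outgroup side.
        """
        names = [outgroup] if isinstance(outgroup, str) else list(outgroup)
        tree = self.copy()
        try:
            anchor = next(lf for lf in tree.leaves() if lf.name not in names)
        except StopIteration:
            raise ValueError("outgroup cannot contain every leaf")
        if anchor.parent is not None:
            tree._make_root(anchor.parent)
        og = tree.mrca(names) if len(names) > 1 else tree.find_leaf(names[0])
        if og is tree.root:
            raise ValueError(f"outgroup {names} is not monophyletic in this tree")
        parent = og.parent
        assert parent is not None
        length = og.length
        parent.children.remove(og)
        og.parent = None
        tree._make_root(parent)
        new_root = Node()
        new_root.add(og)
        new_root.add(parent)
        if length is not None:
            og.length = length * fraction
            parent.length = length * (1.0 - fraction)
        tree.root = new_root
        return tree

    def is_ultrametric(self, tol: float = 1e-8) -> bool:
        depths = self.leaf_depths()
        vals = list(depths.values())
        return max(vals) - min(vals) <= tol * max(1.0, max(vals))

    def leaf_depths(self) -> dict[str, float]:
        """Root-to-leaf path lengths keyed by leaf name."""
        depth: dict[Node, float] = {self.root: 0.0}
        out: dict[str, float] = {}
        for node in self.preorder():
            if node is self.root:
                continue
            depth[node] = depth[node.parent] + (node.length or 0.0)
            if node.is_leaf:
                out[node.name] = depth[node]
        return out

    # ------------------------------------------------------------------ #
    # serialization
    # ------------------------------------------------------------------ #

    def newick(self, lengths: bool = True, supports: bool = False) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                core = node.name or ""
            else:
                core = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if supports and node.support is not None:
                    core += format(node.support, "g")
                elif node.name:
                    core += node.name
            if lengths and node.length is not None:
                core += f":{node.length:.10g}"
            return core

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        dtree = dendropy.Tree.get(data=text, schema="newick")

        def convert(dnode) -> Node:
            name = dnode.taxon.label if dnode.taxon is not None else dnode.label
            node = Node(name, dnode.edge.length)
            if not dnode.is_leaf() and name is not None:
                try:
                    node.support = float(name)
                    node.name = None
                except ValueError:
                    pass
            for dchild in dnode.child_nodes():
                node.add(convert(dchild))
            return node

        return cls(convert(dtree.seed_node))

    def __repr__(self) -> str:  # pragma: no cover
        return f"Phylogeny({len(self.leaves())} leaves)"


def star_tree(names: Iterable[str]) -> Phylogeny:
    root = Node()
    for name in names:
        root.add(Node(name))
    return Phylogeny(root)


def patristic_distances(tree: Phylogeny) -> dict[tuple[str, str], float]:
    """All leaf-pair path lengths; requires branch lengths on non-root nodes."""
    for node in tree.postorder():
        if node is not tree.root and node.length is None:
            raise ValueError("tree has missing branch lengths")
    depth: dict[Node, float] = {tree.root: 0.0}
    order: dict[Node, int] = {tree.root: 0}
    for i, node in enumerate(tree.preorder()):
        order[node] = i
        if node is not tree.root:
            depth[node] = depth[node.parent] + node.length
    out: dict[tuple[str, str], float] = {}
    leaves = tree.leaves()
    for a, b in itertools.combinations(leaves, 2):
        x, y = a, b
        while x is not y:
            if order[x] < order[y]:
                y = y.parent
            else:
                x = x.parent
        d = depth[a] + depth[b] - 2.0 * depth[x]
        out[(a.name, b.name)] = d
        out[(b.name, a.name)] = d
    for leaf in leaves:
        out[(leaf.name, leaf.name)] = 0.0
    return out
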