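"""Unrooted gene trees: newick I/O, bipartitions and sister-subtree pairs.

Trees are stored as an undirected adjacency structure over integer node ids.
Rooted newick inputs are unrooted by suppressing the degree-2 root, so the
topology queries never depend on how the inference software happened to write
the tree. Branch lengths and internal labels are carried but never interpreted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import dendropy

__all__ = [
    "NewickError",
    "GeneTreeError",
    "SubtreePair",
    "GeneTree",
    "parse_newick",
    "read_tree_file",
    "read_trees",
]


class NewickError(ValueError):
    """Unparseable newick input."""


class GeneTreeError(ValueError):
    """Invalid topology query."""


@dataclass(frozen=True)
class SubtreePair:
    """Two adjacent subtrees meeting at an internal node.

    ``side_a`` and ``side_b`` are the leaf sets of two subtrees hanging off the
    same internal node (``anchor``); ``away`` is one of the remaining
    neighbours, guaranteeing the pair does not cover the whole leaf set. Each
    side is a clade of the unrooted tree.
    """

    side_a: frozenset
    side_b: frozenset
    anchor: int
    away: int


class GeneTree:
    """Leaf-labelled unrooted tree with internal nodes of degree >= 3."""

    def __init__(
        self,
        adjacency: dict[int, list[int]],
        labels: dict[int, str],
        tree_id: str = "tree",
        lengths: Optional[dict[tuple[int, int], float]] = None,
    ):
        self.tree_id = tree_id
        self._adj = {u: list(vs) for u, vs in adjacency.items()}
        self._labels = dict(labels)
        self._lengths = dict(lengths or {})
        self._side_cache: dict[tuple[int, int], frozenset] = {}
        seen: set[str] = set()
        for lbl in self._labels.values():
            if lbl in seen:
                raise NewickError(f"duplicate leaf label {lbl!r}")
            seen.add(lbl)

    # -- basic structure ---------------------------------------------------

    @property
    def leaves(self) -> frozenset:
        return frozenset(self._labels.values())

    @property
    def n_leaves(self) -> int:
        return len(self._labels)

    def is_leaf(self, node: int) -> bool:
        return node in self._labels

    def label(self, node: int) -> Optional[str]:
        return self._labels.get(node)

    def neighbors(self, node: int) -> list[int]:
        return list(self._adj[node])

    def internal_nodes(self) -> list[int]:
        return sorted(n for n in self._adj if n not in self._labels)

    def nodes(self) -> list[int]:
        return sorted(self._adj)

    def branch_length(self, u: int, v: int) -> Optional[float]:
        return self._lengths.get((u, v)) or self._lengths.get((v, u))

    # -- subtree machinery -------------------------------------------------

    def side(self, u: int, v: int) -> frozenset:
        """Leaf set of the subtree on ``v``'s side of the edge ``(u, v)``."""
        key = (u, v)
        cached = self._side_cache.get(key)
        if cached is not None:
            return cached
        # iterative DFS away from u
        out: set[str] = set()
        stack = [(u, v)]
        order: list[tuple[int, int]] = []
        while stack:
            parent, node = stack.pop()
            order.append((parent, node))
            lbl = self._labels.get(node)
            if lbl is not None:
                out.add(lbl)
            for nb in self._adj[node]:
                if nb != parent:
                    stack.append((node, nb))
        result = frozenset(out)
        self._side_cache[key] = result
        return result

    def bipartition_sides(self) -> set[frozenset]:
        """All clades: one frozenset per directed edge (both sides of each
        bipartition, including trivial single-leaf sides)."""
        sides: set[frozenset] = set()
        for u, vs in self._adj.items():
            for v in vs:
                sides.add(self.side(u, v))
        return sides

    def is_clade(self, leafset: Iterable[str]) -> bool:
        """True iff ``leafset`` is one side of some bipartition (singletons
        count as clades)."""
        ls = frozenset(leafset)
        if not ls:
            raise GeneTreeError("empty leaf set")
        unknown = ls - self.leaves
        if unknown:
            raise GeneTreeError(f"unknown leaves: {sorted(unknown)}")
        if len(ls) == 1:
            return True
        return ls in self.bipartition_sides()

    def sister_pairs(self) -> list[SubtreePair]:
        """Enumerate all adjacent-subtree pairs.

        For every internal node, every unordered pair of its adjacent subtrees
        is emitted (with one remaining neighbour recorded as ``away``); this is
        exactly the set of sister pairs observable under any rooting of the
        tree. For a binary tree on L leaves there are 3*(L-2) pairs.
        """
        if self.n_leaves < 4:
            raise GeneTreeError(
                f"tree {self.tree_id!r} has {self.n_leaves} leaves; need >= 4"
            )
        pairs: list[SubtreePair] = []
        for node in self.internal_nodes():
            nbrs = self._adj[node]
            for i in range(len(nbrs)):
                for j in range(i + 1, len(nbrs)):
                    away = next(
                        nbrs[k] for k in range(len(nbrs)) if k != i and k != j
                    )
                    pairs.append(
                        SubtreePair(
                            side_a=self.side(node, nbrs[i]),
                            side_b=self.side(node, nbrs[j]),
                            anchor=node,
                            away=away,
                        )
                    )
        return pairs

    # -- serialisation -----------------------------------------------------

    def to_newick(self) -> str:
        """Serialise rooted at the first internal node (or first node)."""
        internals = self.internal_nodes()
        root = internals[0] if internals else min(self._adj)

        def render(parent: int, node: int) -> str:
            lbl = self._labels.get(node)
            if lbl is not None:
                body = lbl
            else:
                kids = [nb for nb in self._adj[node] if nb != parent]
                body = "(" + ",".join(render(node, k) for k in kids) + ")"
            bl = self.branch_length(parent, node) if parent != node else None
            return body if bl is None else f"{body}:{bl:g}"

        kids = self._adj[root]
        return "(" + ",".join(render(root, k) for k in kids) + ");"


def _from_dendropy(dt: dendropy.Tree, tree_id: str) -> GeneTree:
    ids: dict[int, int] = {}
    adjacency: dict[int, list[int]] = {}
    labels: dict[int, str] = {}
    lengths: dict[tuple[int, int], float] = {}
    for i, nd in enumerate(dt.preorder_node_iter()):
        ids[id(nd)] = i
        adjacency[i] = []
        if nd.is_leaf():
            lbl = nd.taxon.label if nd.taxon else (nd.label or "")
            labels[i] = lbl
    for nd in dt.preorder_node_iter():
        u = ids[id(nd)]
        for ch in nd.child_nodes():
            v = ids[id(ch)]
            adjacency[u].append(v)
            adjacency[v].append(u)
            if ch.edge.length is not None:
                lengths[(u, v)] = float(ch.edge.length)

    # suppress any degree-2 internal nodes (typically the newick root)
    def degree2(a: dict[int, list[int]]) -> Optional[int]:
        for n, vs in a.items():
            if n not in labels and len(vs) == 2:
                return n
        return None

    while (n := degree2(adjacency)) is not None:
        a, b = adjacency[n]
        la = lengths.pop((n, a), lengths.pop((a, n), None))
        lb = lengths.pop((n, b), lengths.pop((b, n), None))
        adjacency[a] = [x for x in adjacency[a] if x != n]
        adjacency[b] = [x for x in adjacency[b] if x != n]
        adjacency[a].append(b)
        adjacency[b].append(a)
        if la is not None or lb is not None:
            lengths[(a, b)] = (la or 0.0) + (lb or 0.0)
        del adjacency[n]

    return GeneTree(adjacency, labels, tree_id=tree_id, lengths=lengths)


def parse_newick(text: str, tree_id: str = "tree") -> GeneTree:
    """Parse one newick string into an unrooted :class:`GeneTree`.

    Branch lengths and support labels are accepted; a rooted (degree-2 root)
    input is unrooted by suppressing the root node. Unbalanced parentheses and
    duplicate leaf labels raise :class:`NewickError` with position information
    from the underlying reader.
    """
    try:
        dt = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises reader-specific subclasses
        raise NewickError(f"tree {tree_id!r}: {exc}") from None
    return _from_dendropy(dt, tree_id)


_TREE_SUFFIXES = (".nwk", ".newick", ".tree", ".treefile", ".tre")


def read_tree_file(path: str | Path) -> list[GeneTree]:
    """Read one or more trees (one newick per line) from a single file."""
    path = Path(path)
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise NewickError(f"cannot read tree file {path}: {exc}") from None
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise NewickError(f"no trees in {path}")
    if len(lines) == 1:
        return [parse_newick(lines[0], tree_id=path.stem)]
    return [
        parse_newick(ln, tree_id=f"{path.stem}_{i}")
        for i, ln in enumerate(lines, start=1)
    ]


def read_trees(path: str | Path) -> list[GeneTree]:
    """Read all trees below ``path`` (a directory of newick files, sorted by
    name) or from a single (possibly multi-tree) file."""
    path = Path(path)
    if path.is_dir():
        trees: list[GeneTree] = []
        for fp in sorted(path.iterdir()):
            if fp.suffix.lower() in _TREE_SUFFIXES:
                trees.extend(read_tree_file(fp))
        if not trees:
            raise NewickError(f"no tree files found under {path}")
        return trees
    return read_tree_file(path)
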