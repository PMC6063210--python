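"""Unrooted binary trees: structure, enumeration, paths, patristic distances.

The tree is the parameter object of the least-squares machinery: every
branch carries a length ``x_b`` (in the same units as the input distances,
typically substitutions per site) and the expected distance between two
leaves is the sum of branch lengths on the path joining them (the
*patristic* distance).  Everything downstream — branch-length fitting,
imputation, NNI search, Robinson–Foulds comparison — works through the
canonical branch ordering and bipartition machinery defined here.
"""

from __future__ import annotations

import itertools
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "UnrootedTree",
    "Bipartition",
    "enumerate_topologies",
    "path_incidence",
    "patristic_matrix",
    "tree_length",
    "bipartitions",
    "rf_distance",
    "num_unrooted_topologies",
]

Edge = FrozenSet[int]


class TreeError(ValueError):
    """Structural problem with a tree (degree violation, unset lengths...)."""


class Bipartition:
    """A leaf-set split induced by cutting one branch of an unrooted tree.

    Stored canonically as the side that does NOT contain the
    lexicographically first leaf label, so equal splits compare and hash
    equal regardless of which tree produced them.  Trivial splits (one leaf
    against the rest) are excluded from comparison sets.
    """

    __slots__ = ("side", "origin_branch")

    def __init__(self, side: Iterable[str], origin_branch: Optional[int] = None):
        self.side: FrozenSet[str] = frozenset(side)
        self.origin_branch = origin_branch

    def __eq__(self, other) -> bool:
        return isinstance(other, Bipartition) and self.side == other.side

    def __hash__(self) -> int:
        return hash(self.side)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Bipartition({sorted(self.side)})"

    def is_trivial(self) -> bool:
        return len(self.side) <= 1

    def restrict(self, labels: Iterable[str]) -> "Bipartition":
        """Split induced on a subset of the leaves (may become trivial)."""
        keep = set(labels)
        return Bipartition(self.side & keep)


class UnrootedTree:
    """Unrooted tree with labelled degree-1 leaves and degree-3 internal nodes.

    Parameters
    ----------
    adjacency:
        ``{node: {neighbour: length_or_None}}``; symmetric.
    leaf_labels:
        ``{node: label}`` for every degree-1 node.  Labels must be unique.
    """

    def __init__(self, adjacency: Dict[int, Dict[int, Optional[float]]],
                 leaf_labels: Dict[int, str]):
        self._adj = {u: dict(nb) for u, nb in adjacency.items()}
        self._leaf_labels = dict(leaf_labels)
        labels = list(self._leaf_labels.values())
        if len(set(labels)) != len(labels):
            raise TreeError("duplicate leaf labels")
        self._label_to_node = {v: k for k, v in self._leaf_labels.items()}
        self._validate()
        self._branches: Optional[List[Edge]] = None

    # -- construction -------------------------------------------------
    @classmethod
    def star(cls, labels: Sequence[str]) -> "UnrootedTree":
        """The unique (star) topology on three leaves."""
        if len(labels) != 3:
            raise TreeError("star() builds the 3-leaf tree only")
        adj: Dict[int, Dict[int, Optional[float]]] = {3: {}}
        leaf_labels = {}
        for i, lab in enumerate(labels):
            adj[i] = {3: None}
            adj[3][i] = None
            leaf_labels[i] = lab
        return cls(adj, leaf_labels)

    @classmethod
    def quartet(cls, pair1: Tuple[str, str], pair2: Tuple[str, str]) -> "UnrootedTree":
        """Four-leaf tree with ``pair1`` sisters and ``pair2`` sisters."""
        a, b = pair1
        c, d = pair2
        adj: Dict[int, Dict[int, Optional[float]]] = {
            0: {4: None}, 1: {4: None}, 2: {5: None}, 3: {5: None},
            4: {0: None, 1: None, 5: None}, 5: {2: None, 3: None, 4: None},
        }
        return cls(adj, {0: a, 1: b, 2: c, 3: d})

    def copy(self) -> "UnrootedTree":
        return UnrootedTree(self._adj, self._leaf_labels)

    def _validate(self) -> None:
        for u, nb in self._adj.items():
            for v, ln in nb.items():
                if u not in self._adj.get(v, {}):
                    raise TreeError("adjacency not symmetric")
            deg = len(nb)
            if u in self._leaf_labels:
                if deg != 1:
                    raise TreeError(f"leaf {u} has degree {deg}")
            elif deg < 3:
                raise TreeError(f"internal node {u} has degree {deg} < 3")
        n = len(self._leaf_labels)
        if n < 3:
            raise TreeError("need at least 3 leaves")

    @property
    def is_binary(self) -> bool:
        """True when every internal node has degree exactly 3.  Least-squares
        fitting and NNI require binary trees; Robinson–Foulds comparison
        accepts polytomies (they simply induce fewer bipartitions)."""
        return all(len(nb) == 3 for u, nb in self._adj.items()
                   if u not in self._leaf_labels)

    def require_binary(self) -> "UnrootedTree":
        if not self.is_binary:
            raise TreeError("operation requires a binary (fully resolved) tree")
        return self

    # -- basic queries -------------------------------------------------
    @property
    def labels(self) -> List[str]:
        """Leaf labels in sorted order."""
        return sorted(self._label_to_node)

    @property
    def n_leaves(self) -> int:
        return len(self._leaf_labels)

    def leaf_node(self, label: str) -> int:
        return self._label_to_node[label]

    def neighbors(self, u: int) -> Dict[int, Optional[float]]:
        return self._adj[u]

    def is_leaf(self, u: int) -> bool:
        return u in self._leaf_labels

    def edges(self) -> List[Edge]:
        return [frozenset((u, v)) for u in self._adj for v in self._adj[u] if u < v]

    # -- canonical branch order ----------------------------------------
    def _min_label_beyond(self) -> Dict[Tuple[int, int], str]:
        """For each directed edge (u, v): smallest leaf label on v's side."""
        out: Dict[Tuple[int, int], str] = {}

        def rec(u: int, v: int) -> str:
            if (u, v) in out:
                return out[(u, v)]
            if self.is_leaf(v):
                res = self._leaf_labels[v]
            else:
                res = min(rec(v, w) for w in self._adj[v] if w != u)
            out[(u, v)] = res
            return res

        for u in self._adj:
            for v in self._adj[u]:
                rec(u, v)
        return out

    def branches(self) -> List[Edge]:
        """Branches in canonical order: depth-first from the node bearing the
        lexicographically smallest leaf label, neighbours visited in order of
        the smallest label reachable through them.  Construction-independent.
        """
        if self._branches is not None:
            return self._branches
        key = self._min_label_beyond()
        start = self._label_to_node[min(self._label_to_node)]
        order: List[Edge] = []
        seen = set()

        def dfs(u: int, parent: Optional[int]) -> None:
            nxt = sorted((w for w in self._adj[u] if w != parent),
                         key=lambda w: key[(u, w)])
            for w in nxt:
                e = frozenset((u, w))
                if e not in seen:
                    seen.add(e)
                    order.append(e)
                    dfs(w, u)

        dfs(start, None)
        self._branches = order
        return order

    def branch_index(self) -> Dict[Edge, int]:
        return {e: i for i, e in enumerate(self.branches())}

    def internal_branches(self) -> List[Edge]:
        return [e for e in self.branches()
                if not any(self.is_leaf(u) for u in e)]

    # -- branch lengths --------------------------------------------------
    def branch_lengths(self) -> np.ndarray:
        """Vector of lengths in canonical branch order (NaN where unset)."""
        out = np.empty(len(self.branches()))
        for i, e in enumerate(self.branches()):
            u, v = tuple(e)
            ln = self._adj[u][v]
            out[i] = np.nan if ln is None else ln
        return out

    def set_branch_lengths(self, x: Sequence[float]) -> "UnrootedTree":
        br = self.branches()
        if len(x) != len(br):
            raise TreeError(f"expected {len(br)} lengths, got {len(x)}")
        for e, ln in zip(br, x):
            u, v = tuple(e)
            self._adj[u][v] = float(ln)
            self._adj[v][u] = float(ln)
        return self

    def has_lengths(self) -> bool:
        return not np.isnan(self.branch_lengths()).any()

    # -- paths / splits ---------------------------------------------------
    def leaf_pairs(self) -> List[Tuple[str, str]]:
        """Unordered leaf pairs in lexicographic order."""
        return list(itertools.combinations(self.labels, 2))

    def path_edges(self, label_a: str, label_b: str) -> List[Edge]:
        a, b = self._label_to_node[label_a], self._label_to_node[label_b]
        parent = {a: None}
        stack = [a]
        while stack:
            u = stack.pop()
            if u == b:
                break
            for v in self._adj[u]:
                if v not in parent:
                    parent[v] = u
                    stack.append(v)
        path = []
        u = b
        while parent[u] is not None:
            path.append(frozenset((u, parent[u])))
            u = parent[u]
        return path

    def split_for_branch(self, e: Edge) -> Bipartition:
        u, v = tuple(e)
        side = set()
        stack, seen = [v], {u, v}
        while stack:
            w = stack.pop()
            if self.is_leaf(w):
                side.add(self._leaf_labels[w])
            for z in self._adj[w]:
                if z not in seen:
                    seen.add(z)
                    stack.append(z)
        first = min(self._label_to_node)
        if first in side:
            side = set(self._label_to_node) - side
        return Bipartition(side, origin_branch=self.branch_index()[e])

    # -- rearrangement -----------------------------------------------------
    def nni_neighbors(self, e: Edge) -> List["UnrootedTree"]:
        """The two nearest-neighbour-interchange rearrangements around an
        internal branch.  Branch lengths are carried over unchanged (they are
        refitted by the caller)."""
        u, v = tuple(e)
        if self.is_leaf(u) or self.is_leaf(v):
            raise TreeError("NNI requires an internal branch")
        a, b = sorted(w for w in self._adj[u] if w != v)
        c, d = sorted(w for w in self._adj[v] if w != u)
        out = []
        for swap_u, swap_v in ((b, c), (b, d)):
            adj = {n: dict(nb) for n, nb in self._adj.items()}
            lu = adj[u].pop(swap_u); adj[swap_u].pop(u)
            lv = adj[v].pop(swap_v); adj[swap_v].pop(v)
            adj[u][swap_v] = lv; adj[swap_v][u] = lv
            adj[v][swap_u] = lu; adj[swap_u][v] = lu
            out.append(UnrootedTree(adj, self._leaf_labels))
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return f"UnrootedTree(n={self.n_leaves})"


# ---------------------------------------------------------------------------
# module-level operations
# ---------------------------------------------------------------------------

def num_unrooted_topologies(n: int) -> int:
    """(2n-5)!! distinct binary unrooted topologies on n labelled leaves."""
    out = 1
    for k in range(3, n):
        out *= 2 * k - 3
    return out


def enumerate_topologies(labels: Sequence[str], max_n: int = 8) -> List[UnrootedTree]:
    """All binary unrooted topologies on the given labels (lengths unset).

    Generated by stepwise addition: the k-th taxon is attached to every
    branch of every (k-1)-taxon topology, which yields each of the
    (2n-5)!! topologies exactly once.
    """
    labels = sorted(labels)
    n = len(labels)
    if n < 4:
        raise TreeError("topology enumeration needs at least 4 leaves")
    if n > max_n:
        raise TreeError(
            f"refusing to enumerate {num_unrooted_topologies(n)} topologies "
            f"for n={n} > cap {max_n}")
    trees = [UnrootedTree.star(labels[:3])]
    next_id = 4
    for k in range(3, n):
        lab = labels[k]
        new_trees = []
        for t in trees:
            for e in t.edges():
                u, v = tuple(e)
                adj = {n_: dict(nb) for n_, nb in t._adj.items()}
                mid = max(adj) + 1
                leaf = mid + 1
                adj[u].pop(v); adj[v].pop(u)
                adj[mid] = {u: None, v: None, leaf: None}
                adj[u][mid] = None; adj[v][mid] = None
                adj[leaf] = {mid: None}
                ll = dict(t._leaf_labels); ll[leaf] = lab
                new_trees.append(UnrootedTree(adj, ll))
        trees = new_trees
        next_id += 2
    return trees


def path_incidence(tree: UnrootedTree) -> np.ndarray:
    """Binary K x (2N-3) matrix A: row per leaf pair (lexicographic order),
    column per branch (canonical order); A[p, b] = 1 iff branch b lies on the
    path joining pair p.  Expected distances are then ``A @ x``."""
    idx = tree.branch_index()
    pairs = tree.leaf_pairs()
    A = np.zeros((len(pairs), len(idx)), dtype=float)
    for r, (a, b) in enumerate(pairs):
        for e in tree.path_edges(a, b):
            A[r, idx[e]] = 1.0
    return A


def patristic_matrix(tree: UnrootedTree):
    """Patristic (path-length) distances between all leaf pairs, as a
    complete :class:`~distimpute.matrix_io.LabeledDistanceMatrix`."""
    from .matrix_io import LabeledDistanceMatrix

    if not tree.has_lengths():
        raise TreeError("branch lengths unset")
    labels = tree.labels
    n = len(labels)
    D = np.zeros((n, n))
    A = path_incidence(tree)
    x = tree.branch_lengths()
    vals = A @ x
    for (r, (a, b)) in enumerate(tree.leaf_pairs()):
        i, j = labels.index(a), labels.index(b)
        D[i, j] = D[j, i] = vals[r]
    return LabeledDistanceMatrix(labels, D)


def tree_length(tree: UnrootedTree) -> float:
    """TL = sum of all branch lengths (the minimum-evolution statistic)."""
    x = tree.branch_lengths()
    if np.isnan(x).any():
        raise TreeError("branch lengths unset")
    return float(x.sum())


def bipartitions(tree: UnrootedTree) -> FrozenSet[Bipartition]:
    """Non-trivial splits, one per internal branch (N-3 for a binary tree)."""
    out = set()
    for e in tree.internal_branches():
        bp = tree.split_for_branch(e)
        if not bp.is_trivial() and len(bp.side) < tree.n_leaves - 1:
            out.add(bp)
    return frozenset(out)


def rf_distance(t1: UnrootedTree, t2: UnrootedTree) -> int:
    """Robinson–Foulds distance: size of the symmetric difference of the
    two trees' non-trivial bipartition sets."""
    if set(t1.labels) != set(t2.labels):
        raise TreeError("trees have different leaf sets")
    b1, b2 = bipartitions(t1), bipartitions(t2)
    return len(b1 ^ b2)
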