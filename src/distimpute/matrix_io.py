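"""Distance-matrix container and file formats.

Reads and writes PHYLIP-style distance matrices in which missing distances
are marked with ``'.'`` (aliases ``NA`` and ``?`` are also accepted), plus
aligned FASTA (via Biopython) and Newick trees (via DendroPy).  The
:class:`LabeledDistanceMatrix` is the package's central container: a
symmetric matrix of pairwise distances together with a boolean mask of the
entries that are missing and must be imputed.
"""

from __future__ import annotations

import io
import itertools
from typing import Dict, List, Optional, Sequence, Tuple, Union

import dendropy
import numpy as np
from Bio import AlignIO

from .trees import TreeError, UnrootedTree

__all__ = [
    "LabeledDistanceMatrix",
    "read_phylip_distances",
    "write_phylip_distances",
    "read_fasta_alignment",
    "read_newick",
    "write_newick",
]

MISSING_TOKENS = {".", "NA", "?"}

Pair = Tuple[str, str]


class MatrixFormatError(ValueError):
    """Malformed distance-matrix input."""


class LabeledDistanceMatrix:
    """Symmetric pairwise distance matrix with taxon labels and missing mask.

    With N taxa there are K = N(N-1)/2 unordered pairs; M of them may be
    missing (masked).  Entries are non-negative reals in whatever units the
    distances were estimated in (typically substitutions per site); the
    diagonal is zero and never missing.
    """

    def __init__(self, labels: Sequence[str], entries: np.ndarray,
                 missing_mask: Optional[np.ndarray] = None):
        labels = list(labels)
        if len(set(labels)) != len(labels):
            raise MatrixFormatError("duplicate taxon labels")
        n = len(labels)
        entries = np.asarray(entries, dtype=float)
        if entries.shape != (n, n):
            raise MatrixFormatError(f"matrix shape {entries.shape} != ({n},{n})")
        if missing_mask is None:
            missing_mask = np.zeros((n, n), dtype=bool)
        missing_mask = np.asarray(missing_mask, dtype=bool)
        # symmetrise the mask, then require value symmetry on observed cells;
        # values stored under the mask are carried along untouched (they act
        # as working fill values; only observed cells enter any objective)
        missing_mask = missing_mask | missing_mask.T
        np.fill_diagonal(missing_mask, False)
        obs = ~missing_mask
        chk = np.where(obs, entries, 0.0)
        if not np.allclose(chk, chk.T, atol=1e-9, rtol=0.0):
            raise MatrixFormatError("matrix is asymmetric beyond 1e-9")
        vals = (entries + entries.T) / 2.0
        if np.any(np.diag(vals) != 0.0):
            raise MatrixFormatError("diagonal must be zero")
        if np.any(vals[obs] < 0):
            raise MatrixFormatError("negative distances are not allowed")
        self.labels = labels
        self.entries = vals
        self.missing_mask = missing_mask
        self._index = {lab: i for i, lab in enumerate(labels)}

    # -- counting ------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def n_pairs(self) -> int:
        """K = N(N-1)/2."""
        return self.n * (self.n - 1) // 2

    @property
    def n_missing(self) -> int:
        """M = number of missing unordered pairs."""
        return int(self.missing_mask.sum()) // 2

    # -- access --------------------------------------------------------
    def index(self, label: str) -> int:
        return self._index[label]

    def get(self, a: str, b: str) -> Optional[float]:
        i, j = self._index[a], self._index[b]
        if self.missing_mask[i, j]:
            return None
        return float(self.entries[i, j])

    def set(self, a: str, b: str, value: float) -> None:
        i, j = self._index[a], self._index[b]
        self.entries[i, j] = self.entries[j, i] = float(value)
        self.missing_mask[i, j] = self.missing_mask[j, i] = False

    def pairs(self) -> List[Pair]:
        """Unordered label pairs in lexicographic order (the row order of the
        path-incidence matrix)."""
        return list(itertools.combinations(sorted(self.labels), 2))

    def missing_pairs(self) -> List[Pair]:
        return [(a, b) for a, b in self.pairs()
                if self.missing_mask[self._index[a], self._index[b]]]

    def observed_pairs(self) -> List[Pair]:
        return [(a, b) for a, b in self.pairs()
                if not self.missing_mask[self._index[a], self._index[b]]]

    def condensed(self) -> Tuple[np.ndarray, np.ndarray]:
        """(values, observed_flags) over pairs() order; missing values are NaN."""
        pairs = self.pairs()
        vals = np.empty(len(pairs))
        obs = np.empty(len(pairs), dtype=bool)
        for r, (a, b) in enumerate(pairs):
            i, j = self._index[a], self._index[b]
            obs[r] = not self.missing_mask[i, j]
            vals[r] = self.entries[i, j] if obs[r] else np.nan
        return vals, obs

    def copy(self) -> "LabeledDistanceMatrix":
        return LabeledDistanceMatrix(self.labels, self.entries.copy(),
                                     self.missing_mask.copy())

    def subset(self, labels: Sequence[str]) -> "LabeledDistanceMatrix":
        idx = [self._index[l] for l in labels]
        return LabeledDistanceMatrix(list(labels),
                                     self.entries[np.ix_(idx, idx)],
                                     self.missing_mask[np.ix_(idx, idx)])

    def __repr__(self) -> str:  # pragma: no cover
        return (f"LabeledDistanceMatrix(n={self.n}, "
                f"missing={self.n_missing}/{self.n_pairs})")


# ---------------------------------------------------------------------------
# PHYLIP distance matrices with '.' for missing
# ---------------------------------------------------------------------------

def _parse_cell(tok: str) -> Tuple[float, bool]:
    if tok in MISSING_TOKENS:
        return np.nan, True
    try:
        return float(tok), False
    except ValueError:
        raise MatrixFormatError(f"non-numeric matrix entry {tok!r}")


def read_phylip_distances(source: Union[str, io.TextIOBase],
                          dialect: str = "auto") -> LabeledDistanceMatrix:
    """Parse a PHYLIP-style distance matrix; ``'.'`` marks a missing distance.

    Both the square and the lower-left triangular dialect are accepted
    (auto-detected from row lengths by default).  Labels are read up to
    whitespace rather than as fixed 10-column fields.
    """
    text = source.read() if hasattr(source, "read") else source
    tokens_by_line = [ln.split() for ln in text.splitlines() if ln.strip()]
    if not tokens_by_line:
        raise MatrixFormatError("empty input")
    header = tokens_by_line[0]
    try:
        n = int(header[0])
    except ValueError:
        raise MatrixFormatError(f"first token must be the taxon count, got "
                                f"{header[0]!r}")
    if n < 2:
        raise MatrixFormatError("need at least 2 taxa")
    # flatten remaining tokens, then re-chunk into rows: each row starts with
    # a label followed by its numeric/'.' cells (possibly wrapped over lines)
    flat = [t for line in tokens_by_line[1:] for t in line]
    rows: List[Tuple[str, List[str]]] = []
    if dialect not in ("auto", "square", "lower"):
        raise MatrixFormatError(f"unknown dialect {dialect!r}")

    def chunk(cells_for_row):
        pos = 0
        out = []
        for r in range(n):
            if pos >= len(flat):
                raise MatrixFormatError(f"taxon count mismatch: expected {n} "
                                        f"rows, found {r}")
            label = flat[pos]
            pos += 1
            k = cells_for_row(r)
            cells = flat[pos:pos + k]
            if len(cells) < k:
                raise MatrixFormatError(f"row {label!r}: expected {k} cells, "
                                        f"found {len(cells)}")
            pos += k
            out.append((label, cells))
        if pos != len(flat):
            raise MatrixFormatError("trailing tokens after matrix")
        return out

    if dialect == "auto":
        total = len(flat)
        if total == n * (n + 1):
            dialect = "square"
        elif total == n + n * (n - 1) // 2:
            dialect = "lower"
        else:
            raise MatrixFormatError(
                f"token count {total} fits neither square ({n * (n + 1)}) "
                f"nor lower-triangular ({n + n * (n - 1) // 2}) layout for "
                f"{n} taxa")
    rows = chunk((lambda r: n) if dialect == "square" else (lambda r: r))

    labels = [lab for lab, _ in rows]
    if len(set(labels)) != len(labels):
        raise MatrixFormatError("duplicate taxon labels")
    D = np.zeros((n, n))
    mask = np.zeros((n, n), dtype=bool)
    if dialect == "square":
        for i, (_, cells) in enumerate(rows):
            for j, tok in enumerate(cells):
                val, miss = _parse_cell(tok)
                if i == j:
                    if miss:
                        raise MatrixFormatError("diagonal entries may not be "
                                                "missing")
                    if abs(val) > 1e-9:
                        raise MatrixFormatError("diagonal entries must be 0")
                    continue
                if miss:
                    mask[i, j] = True
                else:
                    D[i, j] = val
        obs = ~(mask | mask.T)
        if not np.allclose(np.where(obs, D, 0.0),
                           np.where(obs, D, 0.0).T, atol=1e-9, rtol=0.0):
            raise MatrixFormatError("square matrix asymmetric beyond 1e-9")
        if (mask != mask.T).any():
            raise MatrixFormatError("missing markers must appear at both "
                                    "(i,j) and (j,i) in square input")
    else:
        for i, (_, cells) in enumerate(rows):
            for j, tok in enumerate(cells):
                val, miss = _parse_cell(tok)
                if miss:
                    mask[i, j] = mask[j, i] = True
                else:
                    D[i, j] = D[j, i] = val
    return LabeledDistanceMatrix(labels, D, mask)


def write_phylip_distances(d: LabeledDistanceMatrix, dialect: str = "square",
                           precision: int = 10) -> str:
    """Render a matrix in PHYLIP layout, missing entries as ``'.'``."""
    if dialect not in ("square", "lower"):
        raise MatrixFormatError(f"unknown dialect {dialect!r}")
    width = max(len(l) for l in d.labels) + 2
    lines = [f"{d.n}"]
    for i, lab in enumerate(d.labels):
        cols = range(d.n) if dialect == "square" else range(i)
        cells = []
        for j in cols:
            if d.missing_mask[i, j]:
                cells.append(".")
            else:
                cells.append(f"{d.entries[i, j]:.{precision}g}")
        lines.append(lab.ljust(width) + "  ".join(cells))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# FASTA alignments
# ---------------------------------------------------------------------------

def read_fasta_alignment(source: Union[str, io.TextIOBase]) -> Dict[str, str]:
    """Aligned FASTA -> ordered {label: sequence}; gaps ('-') preserved.

    All records must have equal length; a ragged file is rejected.
    """
    handle = io.StringIO(source) if isinstance(source, str) else source
    try:
        aln = AlignIO.read(handle, "fasta")
    except ValueError as exc:
        raise MatrixFormatError(f"bad alignment: {exc}") from exc
    out: Dict[str, str] = {}
    for rec in aln:
        if rec.id in out:
            raise MatrixFormatError(f"duplicate sequence id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta_alignment(seqs: Dict[str, str]) -> str:
    lines = []
    for lab, seq in seqs.items():
        lines.append(f">{lab}")
        for i in range(0, len(seq), 70):
            lines.append(seq[i:i + 70])
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Newick trees (DendroPy behind the scenes)
# ---------------------------------------------------------------------------

def _from_dendropy(dtree: "dendropy.Tree") -> UnrootedTree:
    dtree = dtree.clone(depth=1)
    # collapse a degree-2 root so the tree is genuinely unrooted
    dtree.collapse_basal_bifurcation() if len(dtree.seed_node.child_nodes()) == 2 else None
    adj: Dict[int, Dict[int, Optional[float]]] = {}
    leaf_labels: Dict[int, str] = {}
    ids: Dict[object, int] = {}

    def nid(nd) -> int:
        if nd not in ids:
            ids[nd] = len(ids)
            adj[ids[nd]] = {}
        return ids[nd]

    for edge in dtree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        u, v = nid(edge.tail_node), nid(edge.head_node)
        ln = edge.length
        adj[u][v] = ln
        adj[v][u] = ln
    for leaf in dtree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise TreeError("unlabelled leaf in Newick input")
        leaf_labels[nid(leaf)] = leaf.taxon.label
    if len(leaf_labels) < 3:
        raise TreeError("Newick tree must have at least 3 leaves")
    return UnrootedTree(adj, leaf_labels)


def _to_dendropy(tree: UnrootedTree) -> "dendropy.Tree":
    taxa = dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=taxa)
    # root arbitrarily at an internal node adjacent to the first leaf
    first = tree.leaf_node(tree.labels[0])
    root = next(iter(tree.neighbors(first)))
    node_of = {root: dtree.seed_node}

    def build(u, parent):
        for v, ln in sorted(tree.neighbors(u).items()):
            if v == parent:
                continue
            child = node_of[u].new_child()
            child.edge.length = ln
            node_of[v] = child
            if tree.is_leaf(v):
                child.taxon = taxa.new_taxon(tree._leaf_labels[v])
            else:
                build(v, u)

    build(root, None)
    return dtree


def read_newick(source: Union[str, io.TextIOBase]) -> UnrootedTree:
    """Parse one Newick tree into an :class:`UnrootedTree`."""
    text = source.read() if hasattr(source, "read") else source
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  preserve_underscores=True)
    except Exception as exc:
        raise TreeError(f"bad Newick: {exc}") from exc
    return _from_dendropy(dtree)


def write_newick(tree: UnrootedTree, precision: int = 10) -> str:
    """Serialise to Newick with branch lengths (omitted where unset)."""
    dtree = _to_dendropy(tree)
    s = dtree.as_string(schema="newick", suppress_rooting=True,
                        unquoted_underscores=True,
                        real_value_format_specifier=f".{precision}g")
    return s.strip() + "\n"
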