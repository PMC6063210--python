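"""Tree construction from complete distance matrices.

Neighbor joining gives the starting topology; an OLS-guided
nearest-neighbour-interchange (NNI) hill climb then searches for the
topology minimising the masked least-squares objective.  The combination
stands in for balanced minimum-evolution programs such as FastME: on the
kind of data handled here the two approaches return the same trees, and
NJ+NNI keeps the whole pipeline on the single least-squares criterion that
also drives the imputation.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .lsfit import FitResult, fit_branch_lengths
from .matrix_io import LabeledDistanceMatrix
from .trees import TreeError, UnrootedTree

__all__ = ["neighbor_joining", "ols_nni_refine", "build_tree"]


def neighbor_joining(d: LabeledDistanceMatrix) -> UnrootedTree:
    """Standard neighbor-joining agglomeration (Saitou & Nei / Studier &
    Keppler Q-criterion).

    The matrix must be complete (impute first if it has missing entries).
    Ties in the Q matrix break deterministically on the lowest index pair.
    Negative branch-length estimates at a join are clamped to zero with the
    deficit transferred to the sister branch, a common post-hoc repair.
    """
    if d.n_missing:
        raise ValueError(
            f"{d.n_missing} missing distance(s): impute before tree building")
    n = d.n
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = d.entries.copy()
    # each active cluster maps to a node id in the growing tree
    adj: dict[int, dict[int, Optional[float]]] = {i: {} for i in range(n)}
    leaf_labels = {i: lab for i, lab in enumerate(d.labels)}
    active = list(range(n))
    node_of = {i: i for i in range(n)}
    next_node = n

    def clamp(la: float, lb: float) -> tuple[float, float]:
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        return la, max(lb, 0.0)

    while len(active) > 3:
        k = len(active)
        idx = np.array(active)
        sub = D[np.ix_(idx, idx)]
        r = sub.sum(axis=1)
        Q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest-index tie-break: argmin scans row-major
        fi, fj = np.unravel_index(np.argmin(Q), Q.shape)
        if fi > fj:
            fi, fj = fj, fi
        a, b = idx[fi], idx[fj]
        dab = D[a, b]
        la = 0.5 * dab + (r[fi] - r[fj]) / (2 * (k - 2))
        lb = dab - la
        la, lb = clamp(la, lb)
        u = next_node
        next_node += 1
        adj[u] = {}
        na, nb = node_of[a], node_of[b]
        adj[u][na] = la; adj[na][u] = la
        adj[u][nb] = lb; adj[nb][u] = lb
        # distances from the new cluster
        new_row = np.zeros(D.shape[0] + 1)
        D = np.pad(D, ((0, 1), (0, 1)))
        c = D.shape[0] - 1
        for other in active:
            if other in (a, b):
                continue
            D[c, other] = D[other, c] = 0.5 * (D[a, other] + D[b, other] - dab)
        active = [x for x in active if x not in (a, b)] + [c]
        node_of[c] = u
    # final join of the last three clusters on a single internal node
    a, b, c = active
    da, db, dc = D[b, c], D[a, c], D[a, b]
    la = (db + dc - da) / 2
    lb = (da + dc - db) / 2
    lc = (da + db - dc) / 2
    u = next_node
    adj[u] = {}
    for cl, ln in ((a, la), (b, lb), (c, lc)):
        nd = node_of[cl]
        ln = max(ln, 0.0)
        adj[u][nd] = ln
        adj[nd][u] = ln
    return UnrootedTree(adj, leaf_labels)


def ols_nni_refine(tree: UnrootedTree, d: LabeledDistanceMatrix, m: int = 0,
                   max_sweeps: int = 50) -> FitResult:
    """Greedy NNI hill climb on the masked least-squares objective.

    Every internal branch contributes two alternative topologies; each sweep
    fits all of them and accepts the best strict RSS decrease.  The search
    stops at a local optimum (no alternative improves) and the RSS never
    increases, so termination is guaranteed.  Works with masked matrices:
    only observed pairs enter the objective.
    """
    tree.require_binary()
    best = fit_branch_lengths(tree, d, m=m)
    for _ in range(max_sweeps):
        candidate = None
        for e in best.tree.internal_branches():
            for alt in best.tree.nni_neighbors(e):
                fit = fit_branch_lengths(alt, d, m=m)
                if fit.rss < best.rss - 1e-12 and (
                        candidate is None or fit.rss < candidate.rss):
                    candidate = fit
        if candidate is None:
            break
        best = candidate
    return best


def build_tree(d: LabeledDistanceMatrix, m: int = 0, refine: bool = True
               ) -> FitResult:
    """NJ starting tree, optional OLS-NNI refinement, OLS branch lengths.

    Accepts masked matrices as long as some complete working copy can seed
    NJ — callers normally pass an already-filled matrix; if the matrix has
    missing entries NJ runs on the entries as stored (the mask only shapes
    the least-squares objective).
    """
    if d.n == 3:
        tree = neighbor_joining(d)
        from .trees import patristic_matrix, tree_length
        return FitResult(tree=tree, x=tree.branch_lengths(),
                         rss=0.0, tl=tree_length(tree),
                         patristic=patristic_matrix(tree), imputed={},
                         unique=True, m=m)
    seed = d if not d.n_missing else LabeledDistanceMatrix(
        d.labels, d.entries.copy())
    tree = neighbor_joining(seed)
    if refine:
        return ols_nni_refine(tree, d, m=m)
    return fit_branch_lengths(tree, d, m=m)
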