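"""Least-squares branch-length estimation on a fixed topology.

The objective is the (possibly weighted) residual sum of squares

    RSS = sum over observed pairs (i,j) of [D_ij - E(D_ij)]^2 / D_ij^m

where E(D_ij) = (A x)_ij is the patristic distance implied by branch
lengths x through the path-incidence matrix A, and m is 0 (ordinary least
squares, the default), 1 or 2.  Missing pairs are simply excluded from the
sum, which is what makes the criterion usable for imputation: the fitted
tree's patristic distance at a masked pair is the imputed value.  Branch
lengths are constrained to be non-negative (active-set NNLS); OLS is the
default because it shows less topological bias than the m=1 or m=2
weightings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.optimize import linprog, nnls

from .matrix_io import LabeledDistanceMatrix, Pair
from .trees import UnrootedTree, path_incidence, tree_length

__all__ = ["FitResult", "fit_branch_lengths", "rss", "quartet_closed_form",
           "IdentifiabilityError"]

RANK_TOL = 1e-8


class IdentifiabilityError(ValueError):
    """The requested exact solve is singular (e.g. the missing distance
    joins two sister taxa, so the path equations have determinant 0)."""


@dataclass
class FitResult:
    """Outcome of a least-squares branch-length fit on one topology."""

    tree: UnrootedTree                      # topology with fitted lengths
    x: np.ndarray                           # lengths, canonical branch order
    rss: float                              # attained minimum of the objective
    tl: float                               # tree length, sum(x)
    patristic: LabeledDistanceMatrix        # E(D) at the fit (complete)
    imputed: Dict[Pair, float]              # masked pair -> fitted patristic
    unique: bool                            # False when multiple optima exist
    m: int                                  # weighting power used
    imputed_interval: Dict[Pair, Tuple[float, float]] = field(default_factory=dict)
    # when unique is False: per masked pair, the [lo, hi] range of values the
    # equal-RSS optima assign to it (the "narrow range of optimal values")


def _design(tree: UnrootedTree, d: LabeledDistanceMatrix, m: int
            ) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(A_obs, b_obs, weights, A_all) restricted to observed pairs.

    Requires the tree and matrix to carry the same label set; pair order is
    the shared lexicographic order.
    """
    if set(tree.labels) != set(d.labels):
        raise ValueError("tree and matrix label sets differ")
    A = path_incidence(tree)
    vals, obs = d.condensed()
    if not obs.any():
        raise ValueError("no observed distances")
    b = vals[obs]
    w = np.ones_like(b)
    if m:
        zero = b <= 0.0
        if zero.any():
            warnings.warn(
                f"{int(zero.sum())} observed zero distance(s) with m={m}: "
                "using unit weight (m=0) for those pairs", RuntimeWarning)
        w[~zero] = b[~zero] ** (-float(m))
    return A[obs], b, w, A


def _solution_set_lp(Aw: np.ndarray, yhat_w: np.ndarray, c: np.ndarray,
                     maximize: bool = False) -> Optional[np.ndarray]:
    """Optimize c@x over {x >= 0 : Aw x = yhat_w} (the LS optimal set)."""
    res = linprog((-c if maximize else c), A_eq=Aw, b_eq=yhat_w,
                  bounds=(0, None), method="highs")
    return res.x if res.status == 0 else None


def fit_branch_lengths(tree: UnrootedTree, d: LabeledDistanceMatrix,
                       m: int = 0, nonneg: bool = True,
                       compute_intervals: bool = False) -> FitResult:
    """Fit branch lengths minimising the masked, weighted RSS.

    Parameters
    ----------
    tree:
        Topology (lengths ignored); must be binary and share the matrix's
        label set.
    d:
        Distance matrix; masked (missing) pairs are excluded from the
        objective and reported back as imputed patristic values.
    m:
        Weighting power in the denominator D_ij^m; 0 = OLS (default).
    nonneg:
        Constrain x >= 0 (active-set NNLS).  With ``False`` the plain
        weighted least-squares solution is returned; negative lengths are
        then possible and flagged only through the values themselves.

    Notes
    -----
    When the observed design matrix is rank-deficient the optimum is not
    unique (classically: the masked pair joins sister taxa).  ``unique`` is
    then False and the returned representative is the minimum-tree-length
    point of the optimal set; with ``compute_intervals=True`` the attainable
    range of each imputed value over the equal-RSS optima is additionally
    reported in ``imputed_interval``.
    """
    tree = tree.copy().require_binary()
    A_obs, b, w, A_all = _design(tree, d, m)
    sw = np.sqrt(w)
    Aw = A_obs * sw[:, None]
    bw = b * sw
    rank = np.linalg.matrix_rank(Aw, tol=RANK_TOL)
    unique = rank == Aw.shape[1]
    if nonneg:
        x, _ = nnls(Aw, bw)
    else:
        x, *_ = np.linalg.lstsq(Aw, bw, rcond=None)
    if nonneg and not unique:
        # deterministic representative: minimum TL over the optimal set
        yhat_w = Aw @ x
        x_lp = _solution_set_lp(Aw, yhat_w, np.ones(Aw.shape[1]))
        if x_lp is not None:
            x = x_lp
    resid = bw - Aw @ x
    rss_val = float(resid @ resid)
    x = np.where(np.abs(x) < 1e-12, 0.0, x)
    tree.set_branch_lengths(x)
    # patristic distances come straight from the incidence matrix
    pat_vals = A_all @ x
    labels = sorted(d.labels)
    n = len(labels)
    P = np.zeros((n, n))
    rows, cols = np.triu_indices(n, k=1)
    P[rows, cols] = pat_vals
    P[cols, rows] = pat_vals
    pat = LabeledDistanceMatrix(labels, P)
    imputed = {p: pat.get(*p) for p in d.missing_pairs()}
    intervals: Dict[Pair, Tuple[float, float]] = {}
    if compute_intervals and nonneg and not unique:
        yhat_w = Aw @ x
        pair_rows = {p: r for r, p in enumerate(d.pairs())}
        for p in d.missing_pairs():
            row = A_all[pair_rows[p]]
            lo = _solution_set_lp(Aw, yhat_w, row)
            hi = _solution_set_lp(Aw, yhat_w, row, maximize=True)
            if lo is not None and hi is not None:
                intervals[p] = (float(row @ lo), float(row @ hi))
    return FitResult(tree=tree, x=x, rss=rss_val, tl=tree_length(tree),
                     patristic=pat, imputed=imputed, unique=bool(unique),
                     m=m, imputed_interval=intervals)


def rss(tree: UnrootedTree, d: LabeledDistanceMatrix, m: int = 0) -> float:
    """Evaluate the objective at the tree's current branch lengths,
    over observed pairs only."""
    A_obs, b, w, _ = _design(tree, d, m)
    x = tree.branch_lengths()
    if np.isnan(x).any():
        raise ValueError("branch lengths unset")
    r = b - A_obs @ x
    return float(np.sum(w * r * r))


def quartet_closed_form(d: LabeledDistanceMatrix, tree: UnrootedTree
                        ) -> Tuple[np.ndarray, Optional[float]]:
    """Exact algebraic solve of the five path equations on a quartet.

    With four taxa, five branches and five observed distances (one pair
    missing) the path equations form a square linear system; its solution
    gives the branch lengths directly (negatives allowed) and, through them,
    the implied value of the missing distance.  When the missing pair are
    sisters on the given topology the system is singular and an
    :class:`IdentifiabilityError` is raised.

    Returns ``(x, implied_missing)`` in canonical branch order;
    ``implied_missing`` is None when no pair is masked (exact interpolation
    of a full matrix is then over-determined and not attempted — use
    :func:`fit_branch_lengths`).
    """
    if d.n != 4 or tree.n_leaves != 4:
        raise ValueError("quartet solve requires exactly 4 taxa")
    if d.n_missing > 1:
        raise ValueError("at most one distance may be missing")
    A = path_incidence(tree)
    vals, obs = d.condensed()
    A_obs = A[obs]
    if A_obs.shape[0] != 5:
        raise ValueError("need exactly five observed distances")
    if abs(np.linalg.det(A_obs)) < RANK_TOL:
        raise IdentifiabilityError(
            "singular path equations: the missing distance joins sister "
            "taxa on this topology")
    x = np.linalg.solve(A_obs, vals[obs])
    missing = d.missing_pairs()
    implied = None
    if missing:
        r = d.pairs().index(missing[0])
        implied = float(A[r] @ x)
    return x, implied
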