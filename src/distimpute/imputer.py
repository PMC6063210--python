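"""Joint estimation of missing distances and the best least-squares tree.

The search problem: find values for the M missing distances and a topology
such that the masked least-squares objective (observed pairs only) is
minimised; the imputed value of each missing pair is the patristic distance
on the optimal tree.  Four strategies are provided, mirroring how the
problem is attacked at different scales:

* exhaustive enumeration of all (2N-5)!! topologies with a constrained fit
  on each (small N only);
* an EM-like alternation — build a tree from the filled matrix, replace the
  missing entries by that tree's patristic distances, repeat while the RSS
  decreases — fast but prone to local optima;
* Brent line search over a single missing value;
* Nelder–Mead downhill simplex over several missing values, restarted from
  jittered initial points, with the tree builder nested inside the
  objective.

Initialisation uses the triangle-inequality fill: a missing D_ij starts at
the smallest D_ik + D_jk over taxa k observed against both i and j (an
upper bound on D_ij when the triangle inequality holds).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from .lsfit import FitResult, fit_branch_lengths
from .matrix_io import LabeledDistanceMatrix
from .trees import UnrootedTree, enumerate_topologies

__all__ = [
    "ImputationResult", "check_connectivity", "initial_fill", "em_refine",
    "impute_exhaustive", "impute_optimize", "impute", "DisconnectedError",
]


class DisconnectedError(ValueError):
    """The graph of observed distances is disconnected: some taxa share no
    measured distance with the rest and no imputation method can place
    them.  Add linking taxa or drop an isolated block."""


@dataclass
class ImputationResult:
    """Best tree plus the distance matrix with its missing entries filled."""

    best_tree: UnrootedTree
    filled_matrix: LabeledDistanceMatrix   # mask cleared, imputed values in
    rss: float                             # masked LS objective at best_tree
    fit: FitResult                         # full fit at the best tree
    method: str                            # exhaustive | brent | simplex | em-only | none
    n_restarts: int = 0
    trajectory: List[float] = field(default_factory=list)  # per-iteration RSS
    seed: Optional[int] = None


def _observed_graph(d: LabeledDistanceMatrix) -> csr_matrix:
    w = np.where(d.missing_mask, 0.0, d.entries)
    conn = (~d.missing_mask).astype(float)
    np.fill_diagonal(conn, 0.0)
    # keep zero-distance edges representable: store connectivity weights of
    # max(value, tiny) so csgraph does not drop structural zeros
    w = np.where(conn > 0, np.maximum(w, 1e-300), 0.0)
    return csr_matrix(w)


def check_connectivity(d: LabeledDistanceMatrix) -> bool:
    """True iff the graph on taxa whose edges are the observed pairs is
    connected (a necessary condition for imputation to be possible)."""
    ncomp, _ = connected_components(_observed_graph(d), directed=False)
    return ncomp == 1


def connected_components_labels(d: LabeledDistanceMatrix) -> List[List[str]]:
    """Taxon labels grouped by connected component of the observed graph,
    largest first (ties broken lexicographically)."""
    _, comp = connected_components(_observed_graph(d), directed=False)
    groups: dict[int, List[str]] = {}
    for lab, c in zip(d.labels, comp):
        groups.setdefault(int(c), []).append(lab)
    return sorted(groups.values(), key=lambda g: (-len(g), sorted(g)))


def initial_fill(d: LabeledDistanceMatrix) -> LabeledDistanceMatrix:
    """Triangle-inequality starting values for every missing distance.

    Missing D_ij <- min over k of (D_ik + D_jk) with both legs observed;
    when i and j have no common observed neighbour, the shortest-path
    distance through the observed graph is used instead.
    """
    if not check_connectivity(d):
        raise DisconnectedError(
            "observed-distance graph is disconnected; components: "
            + "; ".join(",".join(g) for g in connected_components_labels(d)))
    out = d.copy()
    if not d.n_missing:
        return out
    obs = ~d.missing_mask
    np.fill_diagonal(obs, False)
    E = d.entries
    sp = None
    for a, b in d.missing_pairs():
        i, j = d.index(a), d.index(b)
        common = obs[i] & obs[j]
        if common.any():
            val = float(np.min(E[i, common] + E[j, common]))
        else:
            if sp is None:
                sp = shortest_path(_observed_graph(d), directed=False)
            val = float(sp[i, j])
        out.set(a, b, val)
    return out


def _filled(d: LabeledDistanceMatrix, values: np.ndarray) -> LabeledDistanceMatrix:
    """Complete copy of d with candidate values at the masked pairs."""
    out = LabeledDistanceMatrix(d.labels, d.entries.copy())
    for (a, b), v in zip(d.missing_pairs(), values):
        out.set(a, b, max(float(v), 0.0))
    return out


def _finalize(d: LabeledDistanceMatrix, fit: FitResult, method: str,
              restarts: int = 0, trajectory: Optional[List[float]] = None,
              seed: Optional[int] = None) -> ImputationResult:
    """Install the fitted patristic values at masked pairs (their residuals
    are zero by construction, so imputed = patristic at the optimum)."""
    filled = LabeledDistanceMatrix(d.labels, d.entries.copy())
    for p, v in fit.imputed.items():
        filled.set(*p, v)
    return ImputationResult(best_tree=fit.tree, filled_matrix=filled,
                            rss=fit.rss, fit=fit, method=method,
                            n_restarts=restarts,
                            trajectory=list(trajectory or []), seed=seed)


# ---------------------------------------------------------------------------
# EM-like alternation
# ---------------------------------------------------------------------------

def em_refine(d: LabeledDistanceMatrix,
              tree_builder: Optional[Callable[[LabeledDistanceMatrix], FitResult]] = None,
              m: int = 0, tol: float = 1e-10, max_iter: int = 50
              ) -> ImputationResult:
    """Alternate tree building and patristic replacement until the RSS
    stops decreasing.

    Each iteration builds a tree from the current filled matrix, fits
    branch lengths on the observed pairs only, and overwrites the missing
    entries with the fitted patristic distances.  The recorded trajectory is
    non-increasing: an iteration that fails to improve the best RSS by more
    than ``tol`` terminates the loop (oscillation is thereby cut off at the
    best point seen).
    """
    if tree_builder is None:
        from .treebuild import build_tree
        tree_builder = lambda mat: build_tree(mat, m=m, refine=False)
    if not d.n_missing:
        fit = tree_builder(d)
        return _finalize(d, fit, "em-only", trajectory=[fit.rss])
    start = initial_fill(d)
    work = LabeledDistanceMatrix(d.labels, start.entries.copy(), None)
    masked = d.missing_mask
    best: Optional[FitResult] = None
    trajectory: List[float] = []
    for _ in range(max_iter):
        candidate = LabeledDistanceMatrix(d.labels, work.entries.copy(), masked)
        fit = tree_builder(candidate)
        if best is not None and fit.rss > best.rss - tol:
            break
        best = fit
        trajectory.append(fit.rss)
        for p, v in fit.imputed.items():
            work.set(*p, v)
    assert best is not None
    return _finalize(d, best, "em-only", trajectory=trajectory)


# ---------------------------------------------------------------------------
# exhaustive search (small N)
# ---------------------------------------------------------------------------

def impute_exhaustive(d: LabeledDistanceMatrix, m: int = 0, max_n: int = 8
                      ) -> ImputationResult:
    """Constrained fit on every topology; return the global optimum.

    Ties on RSS break toward the smaller tree length, then the earlier
    topology in the stepwise-addition enumeration order (deterministic).
    """
    if not check_connectivity(d):
        raise DisconnectedError("observed-distance graph is disconnected")
    best: Optional[FitResult] = None
    for topo in enumerate_topologies(d.labels, max_n=max_n):
        fit = fit_branch_lengths(topo, d, m=m)
        if best is None or fit.rss < best.rss - 1e-12 or (
                abs(fit.rss - best.rss) <= 1e-12 and fit.tl < best.tl - 1e-12):
            best = fit
    assert best is not None
    return _finalize(d, best, "exhaustive")


# ---------------------------------------------------------------------------
# Brent / Nelder-Mead global optimisation with restarts
# ---------------------------------------------------------------------------

def impute_optimize(d: LabeledDistanceMatrix, m: int = 0, restarts: int = 10,
                    seed: int = 0, method: str = "auto",
                    tree_builder: Optional[Callable[[LabeledDistanceMatrix], FitResult]] = None,
                    fatol: float = 1e-10, xatol: float = 1e-8,
                    max_iter: int = 2000) -> ImputationResult:
    """Optimise the missing values directly, with the tree builder nested
    inside the objective.

    The objective f(v_1..v_M) is the masked RSS of the tree the builder
    produces on the matrix completed with candidate values v (clamped at 0).
    One missing value is handled by Brent's bounded line search on
    [0, 2 x initial fill]; several by the Nelder–Mead downhill simplex.
    ``restarts`` independent starts are used: start 0 is the
    triangle-inequality fill, the others multiply it by U[0.5, 1.5] jitter.
    Fully deterministic for a given seed.
    """
    if method not in ("auto", "brent", "simplex"):
        raise ValueError(f"unknown method {method!r}")
    if tree_builder is None:
        from .treebuild import build_tree
        tree_builder = lambda mat: build_tree(mat, m=m, refine=True)
    if not d.n_missing:
        fit = tree_builder(d)
        return _finalize(d, fit, "none", seed=seed)
    if not check_connectivity(d):
        raise DisconnectedError("observed-distance graph is disconnected")
    rng = np.random.default_rng(seed)
    start = initial_fill(d)
    pairs = d.missing_pairs()
    v0 = np.array([start.entries[d.index(a), d.index(b)] for a, b in pairs])
    M = len(pairs)
    masked = d.missing_mask

    def objective(v: np.ndarray) -> float:
        try:
            cand = LabeledDistanceMatrix(
                d.labels, _filled(d, v).entries, masked)
            return tree_builder(cand).rss
        except Exception:
            return np.inf

    use_brent = method == "brent" or (method == "auto" and M == 1)
    if use_brent and M != 1:
        raise ValueError("Brent's method applies to a single missing value")
    best_v: Optional[np.ndarray] = None
    best_f = np.inf
    trajectory: List[float] = []
    for r in range(max(restarts, 1)):
        jitter = np.ones(M) if r == 0 else rng.uniform(0.5, 1.5, size=M)
        x0 = v0 * jitter
        if use_brent:
            hi = max(2.0 * v0[0], 1e-6)
            res = minimize_scalar(lambda t: objective(np.array([t])),
                                  bounds=(0.0, hi), method="bounded",
                                  options={"xatol": xatol})
            vr, fr = np.array([res.x]), float(res.fun)
        else:
            res = minimize(objective, x0, method="Nelder-Mead",
                           options={"fatol": fatol, "xatol": xatol,
                                    "maxiter": max_iter, "maxfev": 4 * max_iter})
            vr, fr = np.maximum(res.x, 0.0), float(res.fun)
        if fr < best_f:
            best_f, best_v = fr, vr
        trajectory.append(best_f)
        if use_brent:
            break  # bounded Brent is deterministic; restarts add nothing
    assert best_v is not None
    cand = LabeledDistanceMatrix(d.labels, _filled(d, best_v).entries, masked)
    fit = tree_builder(cand)
    return _finalize(d, fit, "brent" if use_brent else "simplex",
                     restarts=1 if use_brent else max(restarts, 1),
                     trajectory=trajectory, seed=seed)


def impute(d: LabeledDistanceMatrix, m: int = 0, restarts: int = 10,
           seed: int = 0, exhaustive_max_n: int = 8) -> ImputationResult:
    """Dispatching front door: exhaustive search for small N, otherwise
    Brent (one missing value) or restarted simplex (several)."""
    if not d.n_missing:
        from .treebuild import build_tree
        return _finalize(d, build_tree(d, m=m), "none", seed=seed)
    if d.n <= exhaustive_max_n:
        return impute_exhaustive(d, m=m, max_n=exhaustive_max_n)
    return impute_optimize(d, m=m, restarts=restarts, seed=seed)
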