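"""Synthetic data generation and phylogenetic-accuracy evaluation.

The simulation design emulates a multi-gene concatenation study: a known
("true") 24-taxon tree, 10 genes evolved independently under HKY85 with
gene-specific transition bias kappa spread over [2, 6.5], concatenated per
taxon, and then per-taxon random gene deletion of intensity g (each taxon
loses g of its G genes, replaced by gap blocks).  With G = 10, any two
taxa that each retain at least 6 genes must share at least 2, so deletion
intensities g <= 4 can never produce a missing distance; from g = 5 on,
pairs that share no gene appear and their distances must be imputed.
Accuracy is scored by Robinson–Foulds bipartition recovery against the
true tree.

No indels are simulated: genes are gap-free and the alignment is exact by
construction, which isolates the imputation machinery from alignment error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .matrix_io import LabeledDistanceMatrix
from .trees import (Bipartition, UnrootedTree, bipartitions, patristic_matrix,
                    rf_distance)

__all__ = [
    "SimulationConfig", "random_tree", "additive_matrix", "mask_random",
    "simulate_hky85", "delete_genes", "rf_distance",
    "pct_bipartitions_recovered", "per_branch_recovery", "group_experiment",
]

BASES = "ACGT"


# ---------------------------------------------------------------------------
# random trees
# ---------------------------------------------------------------------------

def _leaf_names(n: int) -> List[str]:
    width = len(str(n))
    return [f"t{str(i + 1).zfill(width)}" for i in range(n)]


def random_tree(n: int, shape: str = "yule", branch_scale: float = 0.05,
                seed: int = 0, labels: Optional[Sequence[str]] = None
                ) -> UnrootedTree:
    """Random binary unrooted tree with positive branch lengths.

    ``shape='balanced'`` splits the taxa recursively into equal halves (a
    symmetric topology, as used for the 24-taxon simulations);
    ``shape='yule'`` grows the tree by splitting a uniformly chosen pendant
    branch, the standard Yule (pure-birth) topology model.  Branch lengths
    are U(0.5, 1.5) x ``branch_scale``, independent per branch.
    """
    if n < 4:
        raise ValueError("need at least 4 leaves")
    labels = list(labels) if labels is not None else _leaf_names(n)
    if len(labels) != n:
        raise ValueError("label count != n")
    rng = np.random.default_rng(seed)
    adj: Dict[int, Dict[int, Optional[float]]] = {}
    leaf_labels: Dict[int, str] = {}
    counter = [0]

    def new_node() -> int:
        counter[0] += 1
        return counter[0] - 1

    if shape == "balanced":
        def build(lo: int, hi: int) -> int:
            """Rooted balanced subtree over labels[lo:hi]; returns its root."""
            if hi - lo == 1:
                u = new_node()
                adj[u] = {}
                leaf_labels[u] = labels[lo]
                return u
            mid = (lo + hi) // 2
            u = new_node()
            adj[u] = {}
            for child in (build(lo, mid), build(mid, hi)):
                adj[u][child] = None
                adj[child][u] = None
            return u

        root = build(0, n)
        # unroot: the top node has degree 2; merge its two incident edges
        a, b = list(adj[root])
        adj[a].pop(root); adj[b].pop(root); adj.pop(root)
        adj[a][b] = None; adj[b][a] = None
    elif shape == "yule":
        a, b, c, hub = new_node(), new_node(), new_node(), new_node()
        adj = {a: {hub: None}, b: {hub: None}, c: {hub: None},
               hub: {a: None, b: None, c: None}}
        for i, lab in enumerate(labels[:3]):
            leaf_labels[[a, b, c][i]] = lab
        for lab in labels[3:]:
            pendants = sorted(leaf_labels)
            leaf = pendants[rng.integers(len(pendants))]
            parent = next(iter(adj[leaf]))
            mid, new_leaf = new_node(), new_node()
            adj[leaf].pop(parent); adj[parent].pop(leaf)
            adj[mid] = {leaf: None, parent: None, new_leaf: None}
            adj[leaf][mid] = None; adj[parent][mid] = None
            adj[new_leaf] = {mid: None}
            leaf_labels[new_leaf] = lab
    else:
        raise ValueError(f"unknown shape {shape!r}")
    tree = UnrootedTree(adj, leaf_labels)
    k = len(tree.branches())
    tree.set_branch_lengths(branch_scale * rng.uniform(0.5, 1.5, size=k))
    return tree


# ---------------------------------------------------------------------------
# additive matrices and masks (imputer test harness)
# ---------------------------------------------------------------------------

def additive_matrix(tree: UnrootedTree, noise_sd: float = 0.0, seed: int = 0
                    ) -> LabeledDistanceMatrix:
    """Patristic matrix, optionally perturbed per pair by N(0, noise_sd)
    (floored at 0).  With noise_sd = 0 the result is exactly additive."""
    d = patristic_matrix(tree)
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd == 0:
        return d
    rng = np.random.default_rng(seed)
    n = d.n
    noise = rng.normal(0.0, noise_sd, size=(n, n))
    noise = np.triu(noise, 1)
    noise = noise + noise.T
    entries = np.maximum(d.entries + noise, 0.0)
    np.fill_diagonal(entries, 0.0)
    return LabeledDistanceMatrix(d.labels, entries)


def mask_random(d: LabeledDistanceMatrix, n_missing: int, seed: int = 0,
                keep_connected: bool = True, avoid_pairs: Iterable = (),
                max_tries: int = 2000) -> LabeledDistanceMatrix:
    """Mask ``n_missing`` uniformly chosen pairs; by default the draw is
    rejected until the observed graph stays connected."""
    from .imputer import check_connectivity
    if n_missing > d.n_pairs - (d.n - 1):
        raise ValueError(
            f"masking {n_missing} of {d.n_pairs} pairs cannot leave a "
            f"connected graph on {d.n} taxa")
    pairs = d.pairs()
    avoid = {tuple(sorted(p)) for p in avoid_pairs}
    candidates = [p for p in pairs if p not in avoid]
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        pick = rng.choice(len(candidates), size=n_missing, replace=False)
        out = d.copy()
        for k in pick:
            a, b = candidates[k]
            i, j = out.index(a), out.index(b)
            out.missing_mask[i, j] = out.missing_mask[j, i] = True
        if not keep_connected or check_connectivity(out):
            return out
    raise ValueError("could not draw a connectivity-preserving mask")


# ---------------------------------------------------------------------------
# HKY85 sequence simulation
# ---------------------------------------------------------------------------

def hky85_rate_matrix(kappa: float, freqs: Sequence[float]) -> np.ndarray:
    """HKY85 generator normalised to one expected substitution per site.
    Transitions (A<->G, C<->T) are weighted by kappa relative to
    transversions; target frequencies are the stationary distribution."""
    pi = np.asarray(freqs, dtype=float)
    if pi.shape != (4,) or np.any(pi <= 0) or abs(pi.sum() - 1) > 1e-8:
        raise ValueError("freqs must be 4 positive numbers summing to 1")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    Q = np.empty((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            transition = {i, j} in ({0, 2}, {1, 3})
            Q[i, j] = (kappa if transition else 1.0) * pi[j]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -float(np.sum(pi * np.diag(Q)))
    return Q / mu


def simulate_hky85(tree: UnrootedTree, length: int, kappa: float = 2.0,
                   freqs: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
                   seed: int = 0) -> Dict[str, str]:
    """Evolve one gene of ``length`` sites along the tree (no indels).

    The root state is drawn from the stationary frequencies; each branch
    applies the transition matrix expm(Q t) with t the branch length in
    expected substitutions per site.  Returns {leaf label: sequence}.
    """
    if not tree.has_lengths():
        raise ValueError("tree must have branch lengths")
    rng = np.random.default_rng(seed)
    Q = hky85_rate_matrix(kappa, freqs)
    pmat_cache: Dict[float, np.ndarray] = {}

    def pmat(t: float) -> np.ndarray:
        if t not in pmat_cache:
            P = expm(Q * t)
            P = np.clip(P, 0.0, None)
            pmat_cache[t] = np.cumsum(P / P.sum(axis=1, keepdims=True), axis=1)
        return pmat_cache[t]

    pi = np.asarray(freqs, dtype=float)
    start = tree.leaf_node(tree.labels[0])
    root = next(iter(tree.neighbors(start)))
    states: Dict[int, np.ndarray] = {
        root: rng.choice(4, size=length, p=pi).astype(np.uint8)}
    stack = [root]
    seen = {root}
    while stack:
        u = stack.pop()
        for v, ln in sorted(tree.neighbors(u).items()):
            if v in seen:
                continue
            seen.add(v)
            cum = pmat(float(ln))
            r = rng.random(length)
            parent_states = states[u]
            child = (r[:, None] > cum[parent_states]).sum(axis=1)
            states[v] = child.astype(np.uint8)
            stack.append(v)
    base = np.array(list(BASES))
    return {tree._leaf_labels[nd]: "".join(base[states[nd]])
            for nd in states if tree.is_leaf(nd)}


def simulate_concatenated(tree: UnrootedTree, gene_lengths: Sequence[int],
                          kappas: Sequence[float],
                          freqs: Sequence[float], seed: int = 0
                          ) -> Dict[str, str]:
    """Concatenate independently simulated genes (one kappa per gene)."""
    if len(gene_lengths) != len(kappas):
        raise ValueError("one kappa per gene required")
    rng = np.random.default_rng(seed)
    parts: Dict[str, List[str]] = {lab: [] for lab in tree.labels}
    for L, kap in zip(gene_lengths, kappas):
        gene = simulate_hky85(tree, L, kap, freqs,
                              seed=int(rng.integers(2 ** 31)))
        for lab in parts:
            parts[lab].append(gene[lab])
    return {lab: "".join(chunks) for lab, chunks in parts.items()}


def delete_genes(seqs: Dict[str, str], gene_lengths: Sequence[int],
                 g: int, seed: int = 0) -> Dict[str, str]:
    """Per sequence, replace ``g`` uniformly chosen genes by all-gap blocks.

    Gene boundaries follow ``gene_lengths`` (concatenation order); each
    sequence draws its own deletion set independently.
    """
    G = len(gene_lengths)
    if not 0 <= g <= G - 1:
        raise ValueError(f"g must be in [0, {G - 1}]")
    total = sum(gene_lengths)
    starts = np.concatenate([[0], np.cumsum(gene_lengths)])
    rng = np.random.default_rng(seed)
    out: Dict[str, str] = {}
    for lab in seqs:  # iteration order = insertion order: deterministic
        s = seqs[lab]
        if len(s) != total:
            raise ValueError(f"sequence {lab!r} length {len(s)} != "
                             f"sum of gene lengths {total}")
        if g == 0:
            out[lab] = s
            continue
        drop = rng.choice(G, size=g, replace=False)
        chars = list(s)
        for k in drop:
            a, b = int(starts[k]), int(starts[k + 1])
            chars[a:b] = "-" * (b - a)
        out[lab] = "".join(chars)
    return out


# ---------------------------------------------------------------------------
# Robinson-Foulds evaluation
# ---------------------------------------------------------------------------

def _restricted_key(bp: Bipartition, labels: Sequence[str]):
    """Canonical hashable form of a split restricted to a label subset;
    None when the restriction is trivial there."""
    keep = sorted(labels)
    side = frozenset(bp.side) & set(keep)
    if min(keep) in side:
        side = frozenset(keep) - side
    if len(side) <= 1 or len(side) >= len(keep) - 1:
        return None
    return side


def pct_bipartitions_recovered(true_tree: UnrootedTree,
                               estimated: UnrootedTree) -> float:
    """Percentage of the true tree's N-3 non-trivial bipartitions present in
    the estimate.  The estimate may cover only a subset of the taxa (e.g.
    the largest connected component of a fragmented data set): a true split
    then counts as recovered when its restriction to the estimate's taxa is
    non-trivial and present."""
    true_bps = bipartitions(true_tree)
    denom = true_tree.n_leaves - 3
    est_labels = estimated.labels
    if set(est_labels) == set(true_tree.labels):
        est_keys = {bp.side for bp in bipartitions(estimated)}
        hits = sum(1 for bp in true_bps if bp.side in est_keys)
    else:
        if not set(est_labels) <= set(true_tree.labels):
            raise ValueError("estimate contains unknown taxa")
        est_keys = {_restricted_key(bp, est_labels)
                    for bp in bipartitions(estimated)} - {None}
        hits = sum(1 for bp in true_bps
                   if _restricted_key(bp, est_labels) in est_keys)
    return 100.0 * hits / denom


def per_branch_recovery(true_tree: UnrootedTree,
                        estimates: Sequence[UnrootedTree]) -> pd.DataFrame:
    """Per-internal-branch recovery table: for each non-trivial split of the
    true tree, the percentage of estimates containing it."""
    rows = []
    for bp in sorted(bipartitions(true_tree), key=lambda b: sorted(b.side)):
        hit = 0
        for est in estimates:
            keys = ({b.side for b in bipartitions(est)}
                    if set(est.labels) == set(true_tree.labels)
                    else {_restricted_key(b, est.labels)
                          for b in bipartitions(est)} - {None})
            key = (bp.side if set(est.labels) == set(true_tree.labels)
                   else _restricted_key(bp, est.labels))
            hit += int(key is not None and key in keys)
        rows.append({"bipartition": "|".join(sorted(bp.side)),
                     "size": len(bp.side),
                     "pct_recovered": 100.0 * hit / max(len(estimates), 1)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the grouped deletion experiment
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Study conditions for the gene-deletion experiment.

    Defaults: a balanced 24-taxon true tree, 10 genes with kappa evenly
    spaced on [2, 6.5], mildly unequal base frequencies, 300 bp per gene
    and 20 replicates per deletion intensity.
    """

    true_tree: Optional[UnrootedTree] = None
    n_taxa: int = 24
    n_genes: int = 10
    gene_length: int = 300
    kappas: Optional[Sequence[float]] = None
    base_freqs: Tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)
    deletion_intensities: Sequence[int] = tuple(range(10))
    replicates: int = 20
    model: str = "tn93"
    branch_scale: float = 0.05
    seed: int = 0

    def resolved_tree(self) -> UnrootedTree:
        if self.true_tree is not None:
            return self.true_tree
        return random_tree(self.n_taxa, shape="balanced",
                           branch_scale=self.branch_scale, seed=self.seed)

    def resolved_kappas(self) -> np.ndarray:
        if self.kappas is not None:
            k = np.asarray(self.kappas, dtype=float)
            if len(k) != self.n_genes:
                raise ValueError("one kappa per gene required")
            return k
        return np.linspace(2.0, 6.5, self.n_genes)


def _estimate_tree(d: LabeledDistanceMatrix, method: str,
                   seed: int) -> Optional[UnrootedTree]:
    """Impute-and-build pipeline for one replicate; None if hopeless
    (largest connected component below 4 taxa)."""
    from .imputer import check_connectivity, connected_components_labels, \
        em_refine
    from .treebuild import build_tree, ols_nni_refine
    refine = method.endswith("nni")
    if not check_connectivity(d):
        comp = connected_components_labels(d)[0]
        if len(comp) < 4:
            return None
        d = d.subset(sorted(comp))
    if d.n_missing == 0:
        return build_tree(d, refine=refine).tree
    res = em_refine(d)  # NJ inner builder; fast and monotone
    if refine:
        work = LabeledDistanceMatrix(d.labels,
                                     res.filled_matrix.entries.copy(),
                                     d.missing_mask)
        return ols_nni_refine(res.best_tree, work).tree
    return res.best_tree


def group_experiment(config: SimulationConfig, method: str = "impute+nni"
                     ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full deletion-intensity sweep.

    For each deletion intensity g: simulate ``replicates`` concatenated
    alignments on the true tree, delete g genes per sequence, compute
    pairwise-deletion distances, impute where needed, build the tree, and
    score bipartition recovery against the true tree.

    Returns ``(summary, log)``: one summary row per g (mean missing-distance
    count, mean and sd of recovery %), and the per-replicate log.
    """
    if method not in ("impute+nj", "impute+nni"):
        raise ValueError(f"unknown method {method!r}")
    from .seqdist import build_distance_matrix
    tree = config.resolved_tree()
    kappas = config.resolved_kappas()
    gene_lengths = [config.gene_length] * config.n_genes
    rng = np.random.default_rng(config.seed)
    records = []
    for g in config.deletion_intensities:
        for rep in range(config.replicates):
            s_sim = int(rng.integers(2 ** 31))
            s_del = int(rng.integers(2 ** 31))
            seqs = simulate_concatenated(tree, gene_lengths, kappas,
                                         config.base_freqs, seed=s_sim)
            seqs = delete_genes(seqs, gene_lengths, g, seed=s_del)
            d = build_distance_matrix(seqs, config.model,
                                      require_connected=False)
            est = _estimate_tree(d, method, seed=s_sim)
            rec = (pct_bipartitions_recovered(tree, est)
                   if est is not None else 0.0)
            records.append({"g": g, "replicate": rep,
                            "n_missing": d.n_missing,
                            "pct_recovered": rec})
    log = pd.DataFrame(records)
    summary = (log.groupby("g")
               .agg(mean_missing=("n_missing", "mean"),
                    mean_recovery=("pct_recovered", "mean"),
                    sd_recovery=("pct_recovered", "std"))
               .reset_index())
    return summary, log
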