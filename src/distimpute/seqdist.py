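"""Pairwise evolutionary distances from aligned sequences.

Distances are computed with *pairwise deletion*: for each sequence pair,
only alignment columns where both sequences carry an unambiguous nucleotide
(A, C, G or T) are used.  A pair that shares no such column — e.g. two
sequences whose retained genes do not overlap — has no computable distance
and is reported as MISSING, which is exactly the situation the imputation
machinery exists for.  Saturated pairs (a logarithm argument falling to or
below zero in the model correction) are likewise reported MISSING rather
than clipped, so they flow into the imputer the same way.

Supported models: p (uncorrected proportion), JC69, K80 and TN93; TN93 uses
per-pair empirical base frequencies and distinguishes the two transition
types.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log
from typing import Dict, Optional, Tuple

import numpy as np

from .matrix_io import LabeledDistanceMatrix

__all__ = ["PairCounts", "pair_counts", "distance", "build_distance_matrix",
           "MODELS"]

MODELS = ("p", "jc69", "k80", "tn93")

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i

# reason codes for a missing distance
NO_SHARED_SITES = "no_shared_sites"
SATURATED = "saturated"
DEGENERATE_FREQS = "degenerate_frequencies"


def encode(seq: str) -> np.ndarray:
    """Sequence -> uint8 codes; 255 for gaps and ambiguity characters."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class PairCounts:
    """Site-pattern counts for one sequence pair under pairwise deletion."""

    shared_sites: int          # columns unambiguous in both sequences
    p_identical: float         # fraction of shared columns with equal bases
    p_transition_AG: float     # A<->G fraction (purine transitions)
    p_transition_CT: float     # C<->T fraction (pyrimidine transitions)
    p_transversion: float      # all purine<->pyrimidine changes
    base_freqs: np.ndarray     # empirical (A, C, G, T) over both sequences

    @property
    def p_transition(self) -> float:
        return self.p_transition_AG + self.p_transition_CT

    @property
    def p_different(self) -> float:
        return self.p_transition + self.p_transversion


def pair_counts(a: str, b: str) -> PairCounts:
    """Count shared sites and substitution-type fractions for one pair."""
    if len(a) != len(b):
        raise ValueError(f"sequences have unequal lengths {len(a)} != {len(b)}")
    ca, cb = encode(a), encode(b)
    keep = (ca < 4) & (cb < 4)
    n = int(keep.sum())
    if n == 0:
        return PairCounts(0, 0.0, 0.0, 0.0, 0.0, np.zeros(4))
    xa, xb = ca[keep].astype(np.intp), cb[keep].astype(np.intp)
    joint = np.bincount(4 * xa + xb, minlength=16).reshape(4, 4)
    ident = np.trace(joint)
    ag = joint[0, 2] + joint[2, 0]
    ct = joint[1, 3] + joint[3, 1]
    tv = joint.sum() - ident - ag - ct
    freqs = (np.bincount(xa, minlength=4) + np.bincount(xb, minlength=4)) / (2 * n)
    return PairCounts(n, ident / n, ag / n, ct / n, tv / n, freqs)


def _safe_log(x: float) -> Optional[float]:
    return log(x) if x > 0.0 else None


def _tn93(c: PairCounts) -> Tuple[Optional[float], Optional[str]]:
    gA, gC, gG, gT = c.base_freqs
    gR, gY = gA + gG, gC + gT
    if min(gR, gY) <= 0.0 or gA * gG <= 0.0 or gC * gT <= 0.0:
        return None, DEGENERATE_FREQS
    P1, P2, Q = c.p_transition_AG, c.p_transition_CT, c.p_transversion
    k1 = 2 * gA * gG / gR
    k2 = 2 * gT * gC / gY
    k3 = 2 * (gR * gY - gA * gG * gY / gR - gT * gC * gR / gY)
    l1 = _safe_log(1.0 - P1 / k1 - Q / (2 * gR))
    l2 = _safe_log(1.0 - P2 / k2 - Q / (2 * gY))
    l3 = _safe_log(1.0 - Q / (2 * gR * gY))
    if l1 is None or l2 is None or l3 is None:
        return None, SATURATED
    return -k1 * l1 - k2 * l2 - k3 * l3, None


def distance_with_reason(a: str, b: str, model: str = "tn93"
                         ) -> Tuple[Optional[float], Optional[str]]:
    """(distance, None) or (None, reason) for one pair under the model."""
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    c = pair_counts(a, b)
    if c.shared_sites == 0:
        return None, NO_SHARED_SITES
    p = c.p_different
    if model == "p":
        return p, None
    if model == "jc69":
        l = _safe_log(1.0 - 4.0 * p / 3.0)
        return (-0.75 * l, None) if l is not None else (None, SATURATED)
    if model == "k80":
        P, Q = c.p_transition, c.p_transversion
        l1 = _safe_log(1.0 - 2.0 * P - Q)
        l2 = _safe_log(1.0 - 2.0 * Q)
        if l1 is None or l2 is None:
            return None, SATURATED
        return -0.5 * l1 - 0.25 * l2, None
    return _tn93(c)


def distance(a: str, b: str, model: str = "tn93") -> Optional[float]:
    """Model-corrected distance, or None when it cannot be computed
    (no shared homologous sites, saturation, degenerate frequencies)."""
    val, _ = distance_with_reason(a, b, model)
    return val


def build_distance_matrix(alignment: Dict[str, str], model: str = "tn93",
                          require_connected: bool = True
                          ) -> LabeledDistanceMatrix:
    """All-pairs distance matrix with incomputable pairs flagged missing.

    Raises on a disconnected observed-pair graph unless
    ``require_connected=False`` (downstream imputation needs connectivity;
    the error message names the isolated taxon groups).
    """
    labels = list(alignment)
    if len(labels) < 3:
        raise ValueError("need at least 3 sequences")
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("ragged alignment: sequences differ in length")
    n = len(labels)
    D = np.zeros((n, n))
    mask = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            val, _ = distance_with_reason(alignment[labels[i]],
                                          alignment[labels[j]], model)
            if val is None:
                mask[i, j] = mask[j, i] = True
            else:
                D[i, j] = D[j, i] = val
    d = LabeledDistanceMatrix(labels, D, mask)
    if require_connected:
        from .imputer import DisconnectedError, check_connectivity, \
            connected_components_labels
        if not check_connectivity(d):
            raise DisconnectedError(
                "observed-distance graph is disconnected; add taxa linking "
                "the groups: "
                + "; ".join(",".join(g)
                            for g in connected_components_labels(d)))
    return d
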