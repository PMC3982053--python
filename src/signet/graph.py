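"""Signed weighted graph measures: nodal strength and asymmetric modularity.

Signed functional networks need graph measures that treat positive and
negative correlations separately.  Nodal strength generalizes degree:

    s_i^+ = sum_j max(w_ij, 0)        s_i^- = sum_j |min(w_ij, 0)|

Modularity generalizes asymmetrically, because a negative weight *inside* a
module argues against the partition while a positive one argues for it, and
the two should not enter on equal footing.  With the configuration-model
null e_ij^± = s_i^± s_j^± / v^± (v^± = sum_i s_i^±):

    Q^± = (1/v^±) sum_ij (w_ij^± - e_ij^±) delta(M_i, M_j)
    Q*  = Q^+ - [v^- / (v^+ + v^-)] Q^-

so within-module negative weight excess penalizes Q*, down-weighted by the
share of negative edge mass.  The sum runs over all ordered node pairs
including i = j (w_ii = 0, e_ii > 0), which makes Q* vanish exactly on the
single-module partition.  Q^± is defined as 0 whenever v^± = 0; for a
positive-only graph Q* reduces to classic Newman weighted modularity.

Community detection maximizes Q* with a Louvain-style greedy scheme (local
node moves followed by module agglomeration, restarted over random node
orders); an exhaustive Bell-number enumeration is provided as an exact
oracle for small graphs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Literal, Mapping

import numpy as np

from .timeseries import ConnectivityMatrix

__all__ = [
    "NodalStrength",
    "ModularityResult",
    "nodal_strength_signed",
    "modularity_given_partition",
    "detect_communities_signed",
    "brute_force_max_modularity",
]

_BRUTE_FORCE_MAX_NODES = 10


@dataclass(frozen=True)
class NodalStrength:
    """Per-node positive, negative, and total strength.

    ``s_total`` defaults to the combined magnitude ``s_pos + s_neg``; the
    signed difference ``s_pos - s_neg`` is available via the ``total_mode``
    option of :func:`nodal_strength_signed`.
    """

    s_pos: np.ndarray
    s_neg: np.ndarray
    s_total: np.ndarray
    roi_labels: tuple[str, ...]


@dataclass(frozen=True)
class ModularityResult:
    """A partition together with its signed modularity decomposition."""

    partition: dict[str, int]
    q_star: float
    q_pos: float
    q_neg: float
    v_pos: float
    v_neg: float
    n_modules: int

    def labels_array(self, roi_labels) -> np.ndarray:
        return np.asarray([self.partition[lab] for lab in roi_labels], dtype=int)


def nodal_strength_signed(
    cm: ConnectivityMatrix, total_mode: Literal["sum", "difference"] = "sum"
) -> NodalStrength:
    """Positive/negative nodal strength of a signed weighted graph."""
    w = cm.weights
    s_pos = np.maximum(w, 0.0).sum(axis=1)
    s_neg = np.maximum(-w, 0.0).sum(axis=1)
    if total_mode == "sum":
        s_total = s_pos + s_neg
    elif total_mode == "difference":
        s_total = s_pos - s_neg
    else:
        raise ValueError(f"unknown total_mode {total_mode!r}")
    return NodalStrength(s_pos, s_neg, s_total, cm.roi_labels)


def _signed_parts(w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return np.maximum(w, 0.0), np.maximum(-w, 0.0)


def _modularity_matrix(w: np.ndarray) -> np.ndarray:
    """Symmetric matrix B with Q*(partition) = sum_ij B_ij delta(M_i, M_j)."""
    w_pos, w_neg = _signed_parts(w)
    s_pos = w_pos.sum(axis=1)
    s_neg = w_neg.sum(axis=1)
    v_pos = s_pos.sum()
    v_neg = s_neg.sum()
    b = np.zeros_like(w)
    if v_pos > 0:
        b += (w_pos - np.outer(s_pos, s_pos) / v_pos) / v_pos
    if v_neg > 0:
        b -= (w_neg - np.outer(s_neg, s_neg) / v_neg) / (v_pos + v_neg)
    return b


def _normalize_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel modules to contiguous 1..k in order of first appearance."""
    out = np.empty_like(labels)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def _partition_to_labels(
    cm: ConnectivityMatrix, partition: Mapping[str, int]
) -> np.ndarray:
    missing = [lab for lab in cm.roi_labels if lab not in partition]
    if missing:
        raise ValueError(f"partition missing node(s): {missing}")
    return np.asarray([partition[lab] for lab in cm.roi_labels], dtype=int)


def _result_from_labels(cm: ConnectivityMatrix, labels: np.ndarray) -> ModularityResult:
    labels = _normalize_labels(labels)
    w_pos, w_neg = _signed_parts(cm.weights)
    s_pos = w_pos.sum(axis=1)
    s_neg = w_neg.sum(axis=1)
    v_pos = float(s_pos.sum())
    v_neg = float(s_neg.sum())
    delta = labels[:, None] == labels[None, :]

    def q_component(w_part: np.ndarray, s: np.ndarray, v: float) -> float:
        if v == 0:
            return 0.0
        excess = w_part - np.outer(s, s) / v
        return float(excess[delta].sum() / v)

    q_pos = q_component(w_pos, s_pos, v_pos)
    q_neg = q_component(w_neg, s_neg, v_neg)
    total = v_pos + v_neg
    q_star = q_pos - (v_neg / total) * q_neg if total > 0 else 0.0
    return ModularityResult(
        partition=dict(zip(cm.roi_labels, (int(x) for x in labels))),
        q_star=q_star,
        q_pos=q_pos,
        q_neg=q_neg,
        v_pos=v_pos,
        v_neg=v_neg,
        n_modules=int(labels.max(initial=0)),
    )


def modularity_given_partition(
    cm: ConnectivityMatrix, partition: Mapping[str, int]
) -> ModularityResult:
    """Evaluate Q*, Q+, Q- of a fixed node -> module assignment."""
    return _result_from_labels(cm, _partition_to_labels(cm, partition))


def _louvain_level(b: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One Louvain level: greedy local moves on modularity matrix ``b``.

    Returns a community label per node.  Equal-gain candidate moves are
    broken toward the lowest community index; moves need a strictly positive
    gain above a small tolerance to avoid cycling on numerical ties.
    """
    n = b.shape[0]
    comm = np.arange(n)
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            # weight from i to every community, excluding the self-loop term
            k = np.bincount(comm, weights=b[i], minlength=n)
            k[comm[i]] -= b[i, i]
            gain = k - k[comm[i]]
            best = int(np.argmax(gain))  # argmax takes the lowest index on ties
            if gain[best] > 1e-13 and best != comm[i]:
                comm[i] = best
                improved = True
    return _normalize_labels(comm) - 1


def _louvain_once(b: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    labels = _louvain_level(b, rng)
    n_comms = labels.max() + 1
    if n_comms == b.shape[0]:
        return labels
    # agglomerate and recurse on the community graph
    agg = np.zeros((n_comms, n_comms))
    for a in range(n_comms):
        mask_a = labels == a
        for c in range(a, n_comms):
            mask_c = labels == c
            agg[a, c] = agg[c, a] = b[np.ix_(mask_a, mask_c)].sum()
    coarse = _louvain_once(agg, rng)
    return coarse[labels]


def detect_communities_signed(
    cm: ConnectivityMatrix, n_restarts: int = 100, seed: int | None = 0
) -> ModularityResult:
    """Maximize Q* by restarted greedy Louvain moves.

    The best partition over ``n_restarts`` random node orders is returned.
    The single-module partition (Q* = 0) is always a fallback, so the
    returned ``q_star`` is never negative.  Reproducible given ``seed``;
    the first k restarts of a longer run coincide with a shorter run at the
    same seed.
    """
    if cm.n_nodes < 2:
        raise ValueError("community detection needs at least 2 nodes")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    rng = np.random.default_rng(seed)
    b = _modularity_matrix(cm.weights)
    best: ModularityResult | None = None
    for _ in range(n_restarts):
        labels = _louvain_once(b, rng)
        result = _result_from_labels(cm, labels + 1)
        if best is None or result.q_star > best.q_star:
            best = result
    assert best is not None
    if best.q_star < 0:
        best = _result_from_labels(cm, np.ones(cm.n_nodes, dtype=int))
    return best


def _set_partitions(n: int) -> Iterator[np.ndarray]:
    """Yield all set partitions of range(n) as restricted-growth strings.

    RGS encoding: labels[0] = 0 and labels[i] <= max(labels[:i]) + 1.
    Enumeration is in lexicographic RGS order, which makes 'first maximum
    wins' equivalent to the lexicographically-smallest tie-break.
    """
    labels = np.zeros(n, dtype=int)
    maxes = np.zeros(n, dtype=int)
    while True:
        yield labels.copy()
        for i in range(n - 1, 0, -1):
            if labels[i] <= maxes[i - 1]:
                labels[i] += 1
                maxes[i] = max(maxes[i - 1], labels[i])
                labels[i + 1 :] = 0
                maxes[i + 1 :] = maxes[i]
                break
        else:
            return


def brute_force_max_modularity(cm: ConnectivityMatrix) -> ModularityResult:
    """Exact Q* maximizer by exhaustive enumeration of all set partitions.

    Intended as a test oracle; refuses graphs above 10 nodes (Bell-number
    blow-up).  Ties are broken toward the lexicographically smallest
    restricted-growth encoding.
    """
    n = cm.n_nodes
    if n > _BRUTE_FORCE_MAX_NODES:
        raise ValueError(
            f"exhaustive enumeration limited to {_BRUTE_FORCE_MAX_NODES} nodes; got {n}"
        )
    b = _modularity_matrix(cm.weights)
    best_q = -np.inf
    best_labels: np.ndarray | None = None
    for labels in _set_partitions(n):
        q = b[labels[:, None] == labels[None, :]].sum()
        if q > best_q:
            best_q = q
            best_labels = labels
    assert best_labels is not None
    return _result_from_labels(cm, best_labels + 1)
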