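"""The SPECS score: a prevalence-weighted, AUC-type specificity statistic.

For a feature with observations ``Y_d`` in state ``d`` and ``Y_k`` in every
other state, the score for state ``d`` is

    p_d = P{Y_-d < Y_d} = sum_{k != d} P{Y_k < Y_d} * w_k,

where ``P{Y_k < Y_d}`` is estimated by the empirical probability that a random
observation from state ``k`` lies *strictly* below one from state ``d``, and
``w_k`` are prevalence weights renormalized to sum to one over the off-target
states. A score of 1 means the feature's distribution in the target state sits
entirely above every other state; 0 means entirely below (or all ties, since
the comparison is strict); values near 0.5 indicate no specificity.

Ties contribute zero, never one half: a feature that is identically zero in
the target state and positive elsewhere scores exactly 0, and a constant
feature scores 0 for every state.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import CountMatrix, PrevalenceWeights, SampleGrouping, SpecsResult

__all__ = [
    "pairwise_probability",
    "specs_score",
    "specs_score_matrix",
    "classify_features",
]


def pairwise_probability(values_k, values_d) -> float:
    """Empirical probability that a state-k value lies strictly below a state-d value.

    Computes ``(1 / n_k n_d) * sum_i sum_j I{Y_ki < Y_dj}`` with a strict
    inequality; ties contribute 0. Implemented via sorting and binary search
    (O(n log n)), contract-equivalent to the brute-force double sum.
    """
    vk = np.asarray(values_k, dtype=float).ravel()
    vd = np.asarray(values_d, dtype=float).ravel()
    if vk.size == 0 or vd.size == 0:
        raise ValueError("pairwise probability undefined for an empty group")
    if not (np.all(np.isfinite(vk)) and np.all(np.isfinite(vd))):
        raise ValueError("non-finite values")
    vk_sorted = np.sort(vk)
    below = np.searchsorted(vk_sorted, vd, side="left")  # strictly-less counts
    return float(below.sum()) / (vk.size * vd.size)


def specs_score(
    feature_values,
    grouping: SampleGrouping,
    target_state,
    prevalences: PrevalenceWeights | None = None,
) -> float:
    """SPECS score of one feature for one target state.

    Parameters
    ----------
    feature_values : array-like
        Per-sample abundances aligned with ``grouping.samples``.
    grouping : SampleGrouping
    target_state : state label in ``grouping.states``
    prevalences : PrevalenceWeights, optional
        Defaults to equilibrated weights, under which the score is the plain
        mean of the ``m - 1`` pairwise exceedance probabilities.
    """
    y = np.asarray(feature_values, dtype=float).ravel()
    if y.size != len(grouping.samples):
        raise ValueError("feature_values length does not match grouping")
    if target_state not in grouping.states:
        raise KeyError(f"unknown target state {target_state!r}")
    if prevalences is None:
        prevalences = PrevalenceWeights.equilibrated(grouping.states)
    w = prevalences.offtarget(target_state, grouping.states)
    yd = y[grouping.indices(target_state)]
    score = 0.0
    for wk, k in zip(w, (s for s in grouping.states if s != target_state)):
        score += wk * pairwise_probability(y[grouping.indices(k)], yd)
    return float(score)


def _cross_below_counts(values: np.ndarray, idx_k: np.ndarray, idx_d: np.ndarray,
                        rmin_d: np.ndarray) -> np.ndarray:
    """Per-gene count of ordered pairs with the k value strictly below the d value.

    Uses the min-rank identity: for observation j of the target group, its
    min-rank in the pooled k+d block is 1 + #(pooled values < y_dj) and its
    min-rank within the d block is 1 + #(d values < y_dj); the difference is
    the number of k values strictly below y_dj, which is exact under ties.
    """
    pooled = values[:, np.concatenate([idx_k, idx_d])]
    rmin_pooled = rankdata(pooled, axis=1, method="min")[:, idx_k.size:]
    return (rmin_pooled - rmin_d).sum(axis=1)


def specs_score_matrix(
    counts: CountMatrix,
    grouping: SampleGrouping,
    prevalences: PrevalenceWeights | None = None,
) -> SpecsResult:
    """SPECS scores for every gene and every state, vectorized over genes.

    Returns a :class:`SpecsResult` whose ``scores`` DataFrame has genes as rows
    (order preserved) and states as columns (grouping order).
    """
    grouping = grouping.align_to(counts.sample_ids)
    if prevalences is None:
        prevalences = PrevalenceWeights.equilibrated(grouping.states)
    values = counts.values
    states = grouping.states
    idx = {d: grouping.indices(d) for d in states}
    # within-group min-ranks, reused across all opposing states
    rmin_within = {d: rankdata(values[:, idx[d]], axis=1, method="min") for d in states}
    scores = np.zeros((counts.n_genes, len(states)))
    for j, d in enumerate(states):
        w = prevalences.offtarget(d, states)
        nd = idx[d].size
        for wk, k in zip(w, (s for s in states if s != d)):
            cross = _cross_below_counts(values, idx[k], idx[d], rmin_within[d])
            scores[:, j] += wk * cross / (idx[k].size * nd)
    frame = pd.DataFrame(scores, index=counts.gene_ids, columns=states)
    return SpecsResult(scores=frame)


def classify_features(
    result: SpecsResult, upper: float = 0.95, lower: float = 0.05
) -> SpecsResult:
    """Label genes as specifically present/absent per state by thresholding.

    A gene gets ``(state, "present")`` for every state whose score is strictly
    above ``upper`` and ``(state, "absent")`` for every state strictly below
    ``lower``; a gene may carry several labels (multi-state specificity) or
    none.
    """
    if not (0 <= lower < upper <= 1):
        raise ValueError(f"need 0 <= lower < upper <= 1, got {lower}, {upper}")
    labels = []
    scores = result.scores
    arr = scores.to_numpy()
    genes = scores.index
    states = scores.columns
    for gi, dj in zip(*np.nonzero(arr > upper)):
        labels.append((genes[gi], states[dj], "present"))
    for gi, dj in zip(*np.nonzero(arr < lower)):
        labels.append((genes[gi], states[dj], "absent"))
    labels.sort(key=lambda t: (str(t[0]), str(t[1]), t[2]))
    return SpecsResult(scores=scores, labels=labels, upper=upper, lower=lower)
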