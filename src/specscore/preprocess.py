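"""Count normalization (median-of-ratios size factors) and background-gene selection.

The benchmark substrate is a set of low-abundance genes that are stable across
tissues: mean normalized count strictly between configurable bounds (default
0.1-10) and smallest standard deviation of the per-tissue means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import CountMatrix, SampleGrouping

__all__ = ["size_factors", "normalize_counts", "select_background", "BackgroundSet"]


def size_factors(counts: CountMatrix) -> np.ndarray:
    """Median-of-ratios per-sample size factors.

    Reference genes are those with strictly positive counts in every sample
    (a zero anywhere removes the gene from the reference set, as the log
    geometric mean would be -inf). Each sample's factor is the median over
    reference genes of count / geometric-mean-across-samples.
    """
    v = counts.values
    ref = np.all(v > 0, axis=1)
    if not ref.any():
        raise ValueError(
            "no gene has positive counts in every sample; median-of-ratios "
            "size factors are undefined (no silent pseudo-reference fallback)"
        )
    logs = np.log(v[ref])
    log_geo_mean = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_geo_mean, axis=0))
    if np.any(~np.isfinite(factors)) or np.any(factors <= 0):
        raise ValueError("degenerate size factors")
    return factors


def normalize_counts(counts: CountMatrix) -> CountMatrix:
    """Divide each sample's column by its size factor."""
    return CountMatrix(
        counts.gene_ids, counts.sample_ids, counts.values / size_factors(counts)
    )


@dataclass
class BackgroundSet:
    """Selected background gene ids plus the selection parameters used."""

    gene_ids: list
    size: int
    mean_bounds: tuple
    n_qualifying: int
    between_state_sd: dict = field(repr=False, default=None)


def select_background(
    normalized: CountMatrix,
    grouping: SampleGrouping,
    size: int = 1000,
    mean_bounds: tuple = (0.1, 10.0),
) -> BackgroundSet:
    """Pick the `size` most between-state-stable genes in a low-abundance band.

    Genes qualify when their overall mean normalized count lies strictly
    between ``mean_bounds``; among those, the genes with the smallest standard
    deviation of per-state mean values are returned (stability *between* the
    tissue types, not within). Ties break deterministically by gene id.
    """
    lo, hi = mean_bounds
    grouping = grouping.align_to(normalized.sample_ids)
    overall = normalized.values.mean(axis=1)
    mask = (overall > lo) & (overall < hi)
    n_qual = int(mask.sum())
    if n_qual < size:
        raise ValueError(
            f"only {n_qual} genes have mean in ({lo}, {hi}); {size} requested"
        )
    state_means = np.column_stack(
        [normalized.values[:, grouping.indices(d)].mean(axis=1) for d in grouping.states]
    )
    sd = state_means.std(axis=1, ddof=1)
    candidates = sorted(
        (sd[i], str(normalized.gene_ids[i]), normalized.gene_ids[i])
        for i in np.nonzero(mask)[0]
    )
    chosen = [g for _, _, g in candidates[:size]]
    return BackgroundSet(
        gene_ids=chosen,
        size=size,
        mean_bounds=(lo, hi),
        n_qualifying=n_qual,
        between_state_sd={g: s for s, _, g in candidates[:size]},
    )
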