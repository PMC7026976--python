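"""Synthetic negative-binomial count matrices with unbalanced group sizes.

Emulates the statistical structure of the benchmark substrate: low-abundance
genes (per-gene mean drawn log-uniformly, default 0.1-10) with a shared
overdispersion, identical means across groups (no intrinsic specificity), and
strongly unbalanced group sizes (default preset: 10 groups, sizes log-spaced
from 11 to 490, with a scale-down factor for fast runs). Gene-gene correlation
and real tissue biology are deliberately not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import CountMatrix, SampleGrouping

__all__ = ["FixtureConfig", "default_group_sizes", "generate_counts", "generate_specific_gene"]


def default_group_sizes(n_groups: int = 10, low: int = 11, high: int = 490,
                        scale: float = 1.0) -> list:
    """Log-spaced unbalanced group sizes, optionally scaled down (min size 2)."""
    sizes = np.geomspace(low, high, n_groups) * scale
    return [max(2, int(round(s))) for s in sizes]


@dataclass
class FixtureConfig:
    """Configuration for the synthetic count generator.

    ``dispersion`` is the negative-binomial dispersion alpha with
    variance mu + alpha * mu^2 (alpha -> 0 recovers Poisson). The default 0.4
    gives the strong overdispersion typical of counts pooled across
    heterogeneous tissues.
    """

    n_genes: int = 200
    group_sizes: list = field(default_factory=default_group_sizes)
    mean_range: tuple = (0.1, 10.0)
    dispersion: float = 0.4
    n_housekeeping: int = 50
    housekeeping_mean_range: tuple = (100.0, 1000.0)
    housekeeping_dispersion: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_housekeeping < 0:
            raise ValueError("n_housekeeping must be >= 0")
        if any(s < 2 for s in self.group_sizes) or len(self.group_sizes) < 2:
            raise ValueError("need >= 2 groups of >= 2 samples each")
        lo, hi = self.mean_range
        if not (0 < lo <= hi):
            raise ValueError("invalid mean_range")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


def _grouping_for(config: FixtureConfig) -> SampleGrouping:
    samples, labels = [], []
    for gi, n in enumerate(config.group_sizes):
        state = f"tissue{gi + 1:02d}"
        for si in range(n):
            samples.append(f"{state}_s{si + 1:03d}")
            labels.append(state)
    return SampleGrouping(samples, labels)


def generate_counts(config: FixtureConfig) -> tuple:
    """Generate a (CountMatrix, SampleGrouping) pair with no intrinsic specificity.

    Per-gene means are log-uniform over ``mean_range`` and identical in every
    group; counts are NB(mu, alpha) with shared dispersion. Fully determined
    by ``config.seed``.

    When ``n_housekeeping`` > 0, that many additional genes (ids prefixed
    ``hk``) are appended with high means and low dispersion; these emulate
    stably expressed housekeeping genes, which real matrices always contain
    and which give median-of-ratios normalization its all-positive reference
    genes.
    """
    rng = np.random.default_rng(config.seed)
    grouping = _grouping_for(config)
    n_samples = len(grouping.samples)

    def _nb_block(n, mean_range, dispersion):
        lo, hi = mean_range
        mu = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
        r = 1.0 / dispersion  # NB shape; p = r / (r + mu)
        p = r / (r + mu)
        return rng.negative_binomial(r, p[:, None], size=(n, n_samples))

    values = _nb_block(config.n_genes, config.mean_range, config.dispersion)
    genes = [f"gene{g + 1:05d}" for g in range(config.n_genes)]
    if config.n_housekeeping:
        hk = _nb_block(config.n_housekeeping, config.housekeeping_mean_range,
                       config.housekeeping_dispersion)
        values = np.vstack([values, hk])
        genes += [f"hk{g + 1:04d}" for g in range(config.n_housekeeping)]
    return CountMatrix(genes, grouping.samples, values.astype(float)), grouping


def generate_specific_gene(config: FixtureConfig, target_state, shift: float) -> tuple:
    """Background counts with `shift` added to the target state's entries.

    Returns (CountMatrix, SampleGrouping); each gene is a known-positive
    specific feature for ``target_state`` with effect size ``shift``. A shift
    of 0 degenerates to plain background.
    """
    if shift < 0:
        raise ValueError("shift must be >= 0")
    counts, grouping = generate_counts(config)
    if shift > 0:
        if target_state not in grouping.states:
            raise KeyError(f"unknown state {target_state!r}")
        values = counts.values.copy()
        values[:, grouping.indices(target_state)] += shift
        counts = CountMatrix(counts.gene_ids, counts.sample_ids, values)
    return counts, grouping
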