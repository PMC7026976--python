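import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from specscore import CountMatrix, FixtureConfig, SampleGrouping, generate_counts
from specscore.preprocess import normalize_counts, select_background
from specscore.simulate import default_group_sizes


def brute_force_pairwise(values_k, values_d) -> float:
    """Independent O(n^2) double-sum oracle: fraction of strictly-below pairs."""
    vk = np.asarray(values_k, float)
    vd = np.asarray(values_d, float)
    hits = sum(1 for a in vk for b in vd if a < b)
    return hits / (vk.size * vd.size)


def brute_force_specs(feature_values, grouping, target, weights=None) -> float:
    """Independent SPECS oracle via the double sum and explicit weighting."""
    y = np.asarray(feature_values, float)
    others = [d for d in grouping.states if d != target]
    if weights is None:
        w = {d: 1.0 / len(others) for d in others}
    else:
        total = sum(weights[d] for d in others)
        w = {d: weights[d] / total for d in others}
    yd = y[grouping.indices(target)]
    return sum(w[k] * brute_force_pairwise(y[grouping.indices(k)], yd) for k in others)


@pytest.fixture
def three_groups():
    """Six samples in three balanced states A, B, C."""
    return SampleGrouping(
        ["a1", "a2", "b1", "b2", "c1", "c2"], ["A", "A", "B", "B", "C", "C"]
    )


@pytest.fixture
def small_matrix(three_groups):
    """Four genes with known structure on the three-group design."""
    values = np.array(
        [
            [5, 6, 1, 2, 3, 4],  # specific for A
            [0, 0, 2, 5, 1, 7],  # absent in A
            [3, 3, 3, 3, 3, 3],  # constant -> all ties
            [1, 4, 2, 3, 0, 9],  # interleaved
        ],
        dtype=float,
    )
    return CountMatrix(["gA", "gAbs", "gConst", "gMix"], three_groups.samples, values)


@pytest.fixture(scope="session")
def sim_dataset():
    """Small seeded synthetic dataset: counts, grouping, normalized background."""
    config = FixtureConfig(
        n_genes=120,
        group_sizes=default_group_sizes(n_groups=5, high=60),
        n_housekeeping=30,
        seed=42,
    )
    counts, grouping = generate_counts(config)
    norm = normalize_counts(counts)
    background = norm.subset_genes(select_background(norm, grouping, size=100).gene_ids)
    return counts, grouping, norm, background
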