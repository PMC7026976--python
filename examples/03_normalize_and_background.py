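"""Normalize a synthetic count matrix and select the benchmark background set.

Median-of-ratios size factors make samples comparable; the background set is
the low-abundance (mean normalized count in 0.1-10), between-tissue-stable
gene subset that the spike-in benchmark perturbs.
"""

from specscore import FixtureConfig, default_group_sizes, generate_counts
from specscore.preprocess import normalize_counts, select_background, size_factors

config = FixtureConfig(
    n_genes=300,
    group_sizes=default_group_sizes(n_groups=6, scale=0.2),
    n_housekeeping=40,
    seed=11,
)
counts, grouping = generate_counts(config)
print(f"matrix: {counts.n_genes} genes x {counts.n_samples} samples, "
      f"groups {list(grouping.group_sizes.values())}")

factors = size_factors(counts)
print(f"size factors: min {factors.min():.3f}, median "
      f"{sorted(factors)[len(factors)//2]:.3f}, max {factors.max():.3f}")

norm = normalize_counts(counts)
background = select_background(norm, grouping, size=200)
sds = [background.between_state_sd[g] for g in background.gene_ids]
print(f"background: {background.size} of {background.n_qualifying} qualifying genes, "
      f"between-tissue SD range {min(sds):.3f}-{max(sds):.3f}")

# Size factors near 1 mean the synthetic samples share sequencing depth; the
# background genes are the quietest, most stable low expressors — the hardest
# place to detect induced specificity.
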