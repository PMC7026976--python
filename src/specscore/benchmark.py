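"""Spike-in benchmarking harness for specificity metrics.

The harness induces artificial specificity in a background of low-abundance,
between-tissue-stable genes — by multiplying counts in one tissue by a factor
(zeros stay zero) or adding a constant (a pure shift, preserving variance,
optionally with extra variance inflation) — then scores all metrics, converts
scores to ranks over all background genes (rank 1 = most specific), and
compares metrics by the summed ranks of the induced genes across repeated
random induction cycles (one-way ANOVA). Distributional overlap of an induced
gene with the other tissues is quantified by the rank-sum overlap statistic:
the sum of the target samples' descending expression ranks over all samples,
minimal (n_d(n_d+1)/2) when the target group sits entirely on top.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import f_oneway, rankdata, spearmanr

from .comparators import score_all_metrics
from .containers import CountMatrix, PrevalenceWeights, SampleGrouping
from .core import specs_score_matrix

__all__ = [
    "METRICS",
    "InductionSpec",
    "BenchmarkRun",
    "induce_specificity",
    "rank_sum_overlap",
    "rank_scores",
    "metric_rank_table",
    "run_benchmark_cycles",
    "overlap_score_correlations",
    "SubsampleResult",
    "subsample_experiment",
    "fold_change_to_second",
]

#: Metric names in reporting order. Per-tissue metrics (SPECS, zscore, JSD) are
#: ranked on their value for the induction target state; single-valued metrics
#: (Gini, Tau, TSI) are used as-is. All are oriented higher = more specific.
METRICS = ("SPECS", "zscore", "JSD", "Gini", "Tau", "TSI")


@dataclass
class InductionSpec:
    """How to make chosen genes artificially specific for one state.

    mode "multiply": scale the target-state entries by ``amount`` (zero counts
    remain zero). mode "add": add ``amount`` to every target-state entry (a
    pure shift that keeps the variance); ``variance_factor`` > 1 additionally
    spreads the shifted entries about their per-gene mean by sqrt(factor),
    which multiplies the variance by the factor while preserving the mean,
    clipped at zero and rounded when the input matrix is integral.
    """

    mode: str
    amount: float
    target_state: object
    genes: list
    variance_factor: float = 1.0

    def __post_init__(self):
        if self.mode not in ("multiply", "add"):
            raise ValueError(f"mode must be 'multiply' or 'add', got {self.mode!r}")
        if self.amount <= 0:
            raise ValueError("amount must be positive")
        if self.variance_factor < 1:
            raise ValueError("variance_factor must be >= 1")
        if self.variance_factor > 1 and self.mode != "add":
            raise ValueError("variance inflation applies to add mode only")
        self.genes = list(self.genes)


def induce_specificity(counts: CountMatrix, grouping: SampleGrouping,
                       spec: InductionSpec) -> CountMatrix:
    """Apply an :class:`InductionSpec`; entries outside the target block are untouched."""
    grouping = grouping.align_to(counts.sample_ids)
    cols = grouping.indices(spec.target_state)
    gene_pos = {g: i for i, g in enumerate(counts.gene_ids)}
    missing = [g for g in spec.genes if g not in gene_pos]
    if missing:
        raise KeyError(f"unknown genes: {missing[:10]}")
    rows = np.array([gene_pos[g] for g in spec.genes], dtype=int)
    values = counts.values.copy()
    integral = np.allclose(values, np.round(values))
    block = values[np.ix_(rows, cols)]
    if spec.mode == "multiply":
        block = block * spec.amount
    else:
        block = block + spec.amount
        if spec.variance_factor > 1:
            m = block.mean(axis=1, keepdims=True)
            block = m + np.sqrt(spec.variance_factor) * (block - m)
            block = np.clip(block, 0.0, None)
            if integral:
                block = np.round(block)
    values[np.ix_(rows, cols)] = block
    return CountMatrix(counts.gene_ids, counts.sample_ids, values)


def rank_sum_overlap(feature_values, grouping: SampleGrouping, target_state) -> float:
    """Sum of the target samples' descending expression ranks over all samples.

    Rank 1 is the sample with the highest abundance; ties get average ranks.
    The minimum n_d(n_d+1)/2 means the target group sits entirely above the
    rest (no overlap); larger sums mean more distributional overlap.
    """
    y = np.asarray(feature_values, dtype=float).ravel()
    if y.size != len(grouping.samples):
        raise ValueError("feature_values length does not match grouping")
    ranks = rankdata(-y, method="average")
    return float(ranks[grouping.indices(target_state)].sum())


def rank_scores(scores: pd.Series) -> pd.Series:
    """Per-gene ranks, 1 = most specific; NaN ranked last; ties averaged."""
    s = pd.Series(scores, dtype=float)
    return s.rank(ascending=False, method="average", na_option="bottom")


def metric_rank_table(metric_table: pd.DataFrame, target_state) -> pd.DataFrame:
    """Ranks per metric (columns METRICS) from a :func:`score_all_metrics` table."""
    cols = {
        "SPECS": f"SPECS_{target_state}",
        "zscore": f"zscore_{target_state}",
        "JSD": f"JSD_{target_state}",
        "Gini": "Gini",
        "Tau": "Tau",
        "TSI": "TSI",
    }
    return pd.DataFrame({m: rank_scores(metric_table[c]) for m, c in cols.items()})


@dataclass
class BenchmarkRun:
    """One induction cycle: configuration plus per-metric outcomes."""

    cycle: int
    spec: InductionSpec
    seed: int
    ranks: pd.DataFrame = field(repr=False)  # all genes x metrics
    overlap: pd.Series = field(repr=False)  # induced genes -> rank-sum overlap
    summed_ranks: pd.Series = None  # metric -> sum of induced-gene ranks

    def __post_init__(self):
        if self.summed_ranks is None:
            self.summed_ranks = self.ranks.loc[self.spec.genes].sum(axis=0)


def run_benchmark_cycles(
    counts: CountMatrix,
    grouping: SampleGrouping,
    mode: str,
    amount: float,
    n_induced: int = 50,
    n_cycles: int = 5,
    seed: int = 0,
    variance_factor: float = 1.0,
    prevalences: PrevalenceWeights | None = None,
) -> tuple:
    """Repeated random specificity induction with per-metric rank comparison.

    Per cycle: draw ``n_induced`` genes and a random target tissue, induce,
    score all six metrics, rank each metric over all genes, and sum the ranks
    of the induced genes. Across cycles the metrics' summed ranks are compared
    by one-way ANOVA (small summed ranks = metric puts induced genes on top).

    Returns ``(runs, anova_p)`` with one :class:`BenchmarkRun` per cycle.
    """
    if n_induced > counts.n_genes:
        raise ValueError("more induced genes requested than genes available")
    if len(METRICS) < 2:
        raise ValueError("ANOVA needs at least two metrics")
    grouping = grouping.align_to(counts.sample_ids)
    streams = np.random.SeedSequence(seed).spawn(n_cycles)
    runs = []
    for cycle, ss in enumerate(streams, start=1):
        rng = np.random.default_rng(ss)
        genes = [counts.gene_ids[i] for i in
                 rng.choice(counts.n_genes, size=n_induced, replace=False)]
        target = grouping.states[rng.integers(grouping.n_states)]
        spec = InductionSpec(mode=mode, amount=amount, target_state=target,
                             genes=genes, variance_factor=variance_factor)
        induced = induce_specificity(counts, grouping, spec)
        table = score_all_metrics(induced, grouping, prevalences)
        ranks = metric_rank_table(table, target)
        overlap = pd.Series(
            {g: rank_sum_overlap(induced.gene_row(g), grouping, target) for g in genes}
        )
        runs.append(BenchmarkRun(cycle=cycle, spec=spec,
                                 seed=int(ss.generate_state(1)[0] % (2**31)),
                                 ranks=ranks, overlap=overlap))
    groups = [[run.summed_ranks[m] for run in runs] for m in METRICS]
    anova_p = float(f_oneway(*groups).pvalue)
    return runs, anova_p


def benchmark_table(runs) -> pd.DataFrame:
    """Tidy per-(cycle, metric, gene) table of ranks and overlap for induced genes."""
    records = []
    for run in runs:
        for g in run.spec.genes:
            for m in METRICS:
                records.append({
                    "cycle": run.cycle,
                    "metric": m,
                    "gene": g,
                    "target_state": run.spec.target_state,
                    "rank": run.ranks.at[g, m],
                    "rank_sum_overlap": run.overlap[g],
                })
    return pd.DataFrame.from_records(records)


def overlap_score_correlations(runs, per_cycle: bool = False):
    """Spearman correlation, per metric, between expression overlap and score rank.

    A metric that penalizes distributional overlap (as SPECS does by
    construction) shows a positive correlation between an induced gene's
    rank-sum overlap and its score rank (more overlap -> worse, i.e.
    numerically larger, rank). The correlation is computed within each cycle
    and averaged: rank sums from cycles with different target tissues live on
    different scales (the sum grows with the group size), so pooling them
    would corrupt the ordering.

    Returns a Series (metric -> mean correlation), or the cycles x metrics
    DataFrame when ``per_cycle`` is true.
    """
    records = []
    for run in runs:
        ov = [run.overlap[g] for g in run.spec.genes]
        row = {}
        for m in METRICS:
            rho = spearmanr(ov, [run.ranks.at[g, m] for g in run.spec.genes]).statistic
            row[m] = float(rho) if np.isfinite(rho) else 0.0
        records.append(row)
    frame = pd.DataFrame(records, index=[run.cycle for run in runs])
    return frame if per_cycle else frame.mean(axis=0)


@dataclass
class SubsampleResult:
    table: pd.DataFrame  # repeat, fraction, gene, score
    anova_p: float  # across fractions, scores pooled over repeats
    per_repeat_p: list  # ANOVA across fractions within each repeat


def subsample_experiment(
    counts: CountMatrix,
    grouping: SampleGrouping,
    amount: float = 100.0,
    n_induced: int = 50,
    fractions=(0.2, 0.4, 0.6, 0.8, 1.0),
    n_repeats: int = 5,
    seed: int = 0,
    scope: str = "target",
    prevalences: PrevalenceWeights | None = None,
) -> SubsampleResult:
    """Group-size stability: SPECS scores of induced genes under subsampling.

    Per repeat a random tissue gets ``amount`` added to ``n_induced`` random
    genes; then, for each fraction, samples are drawn without replacement
    within the target group (``scope="target"``) or within every group
    (``scope="all"``, the robustness variant) and SPECS is recomputed on the
    reduced matrix. Scores of the induced genes are compared across fractions
    by one-way ANOVA; a large p-value means group size does not move the score.
    """
    if scope not in ("target", "all"):
        raise ValueError("scope must be 'target' or 'all'")
    grouping = grouping.align_to(counts.sample_ids)
    sizes = grouping.group_sizes
    for frac in fractions:
        checked = grouping.states if scope == "all" else []
        for d in checked:
            if int(round(sizes[d] * frac)) < 2:
                raise ValueError(
                    f"fraction {frac} leaves group {d!r} with fewer than 2 samples"
                )
    streams = np.random.SeedSequence(seed).spawn(n_repeats)
    records = []
    for rep, ss in enumerate(streams, start=1):
        rng = np.random.default_rng(ss)
        genes = [counts.gene_ids[i] for i in
                 rng.choice(counts.n_genes, size=n_induced, replace=False)]
        target = grouping.states[rng.integers(grouping.n_states)]
        spec = InductionSpec(mode="add", amount=amount, target_state=target, genes=genes)
        induced = induce_specificity(counts, grouping, spec)
        for frac in fractions:
            keep = []
            for d in grouping.states:
                idx = grouping.indices(d)
                if scope == "all" or d == target:
                    k = int(round(idx.size * frac))
                    if k < 2:
                        raise ValueError(
                            f"fraction {frac} leaves group {d!r} with fewer than 2 samples"
                        )
                    idx = np.sort(rng.choice(idx, size=k, replace=False))
                keep.extend(idx.tolist())
            keep = sorted(keep)
            sub_samples = [counts.sample_ids[i] for i in keep]
            sub = counts.subset_samples(sub_samples)
            sub_vals = induced.values[:, keep]
            sub = CountMatrix(counts.gene_ids, sub_samples, sub_vals)
            sub_grouping = SampleGrouping(
                sub_samples, [grouping.labels[i] for i in keep], grouping.states
            )
            scores = specs_score_matrix(sub, sub_grouping, prevalences).scores
            for g in genes:
                records.append({"repeat": rep, "fraction": frac, "gene": g,
                                "target_state": target,
                                "score": float(scores.at[g, target])})
    table = pd.DataFrame.from_records(records)

    def _anova(groups):
        if len(groups) < 2:
            return float("nan")  # a single fraction: no comparison to make
        if not any(np.ptp(g) > 0 for g in groups):
            return 1.0  # all scores identical: no fraction effect
        return float(f_oneway(*groups).pvalue)

    by_frac = [table.loc[table["fraction"] == f, "score"].to_numpy() for f in fractions]
    anova_p = _anova(by_frac)
    per_repeat = []
    for rep in range(1, n_repeats + 1):
        sub = table[table["repeat"] == rep]
        per_repeat.append(
            _anova([sub.loc[sub["fraction"] == f, "score"].to_numpy() for f in fractions])
        )
    return SubsampleResult(table=table, anova_p=anova_p, per_repeat_p=per_repeat)


def fold_change_to_second(profile, specific_state, pseudocount: float = 1.0) -> float:
    """Ratio of the specific state's mean to the largest remaining state mean.

    A pseudocount (default 1) is added to numerator and denominator so absent
    background expression yields a finite fold change.
    """
    prof = pd.Series(profile, dtype=float)
    if prof.size < 2:
        raise ValueError("profile needs at least 2 states")
    if specific_state not in prof.index:
        raise KeyError(f"unknown state {specific_state!r}")
    top = prof[specific_state]
    second = prof.drop(index=specific_state).max()
    return float((top + pseudocount) / (second + pseudocount))
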