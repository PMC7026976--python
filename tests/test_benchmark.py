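"""Tests for the spike-in benchmarking harness."""

import numpy as np
import pandas as pd
import pytest

from specscore import (
    CountMatrix,
    InductionSpec,
    SampleGrouping,
    fold_change_to_second,
    induce_specificity,
    rank_scores,
    rank_sum_overlap,
    run_benchmark_cycles,
    subsample_experiment,
)
from specscore.benchmark import METRICS, benchmark_table, overlap_score_correlations


class TestInduceSpecificity:
    @pytest.fixture
    def tiny(self):
        grouping = SampleGrouping(["t1", "t2", "t3", "u1", "u2"],
                                  ["T", "T", "T", "U", "U"])
        cm = CountMatrix(["g1", "g2"], grouping.samples,
                         [[0, 2, 4, 1, 1], [5, 5, 5, 5, 5]])
        return cm, grouping

    def test_multiply_factor_one_is_identity(self, tiny):
        cm, grouping = tiny
        spec = InductionSpec("multiply", 1.0, "T", ["g1"])
        out = induce_specificity(cm, grouping, spec)
        assert np.array_equal(out.values, cm.values)

    def test_multiply_keeps_zeros_at_zero(self, tiny):
        cm, grouping = tiny
        out = induce_specificity(cm, grouping, InductionSpec("multiply", 5.0, "T", ["g1"]))
        assert list(out.values[0]) == [0, 10, 20, 1, 1]
        assert list(out.values[1]) == [5, 5, 5, 5, 5]  # untargeted gene untouched

    def test_add_is_a_pure_shift_preserving_variance(self, tiny):
        cm, grouping = tiny
        out = induce_specificity(cm, grouping, InductionSpec("add", 100.0, "T", ["g1"]))
        assert list(out.values[0]) == [100, 102, 104, 1, 1]
        tgt = grouping.indices("T")
        assert out.values[0, tgt].var() == cm.values[0, tgt].var()

    def test_variance_inflation_preserves_mean_and_scales_variance(self):
        grouping = SampleGrouping([f"t{i}" for i in range(40)] + ["u1", "u2"],
                                  ["T"] * 40 + ["U", "U"])
        rng = np.random.default_rng(2)
        row = np.concatenate([rng.normal(50, 3, 40), [1.0, 1.0]])
        cm = CountMatrix(["g"], grouping.samples, row[None, :] + 10)  # non-integral
        f = 9.0
        out = induce_specificity(cm, grouping, InductionSpec("add", 100.0, "T", ["g"], f))
        tgt = grouping.indices("T")
        before = cm.values[0, tgt] + 100.0
        after = out.values[0, tgt]
        assert after.mean() == pytest.approx(before.mean())
        assert after.var() == pytest.approx(f * before.var())

    def test_variance_inflation_rounds_integral_input_and_clips(self):
        grouping = SampleGrouping(["t1", "t2", "t3", "u1", "u2"],
                                  ["T", "T", "T", "U", "U"])
        cm = CountMatrix(["g"], grouping.samples, [[0, 2, 400, 1, 1]])
        out = induce_specificity(cm, grouping, InductionSpec("add", 10.0, "T", ["g"], 50.0))
        tgt = out.values[0, :3]
        assert np.array_equal(tgt, np.round(tgt))
        assert tgt.min() >= 0

    def test_unknown_gene_or_state_rejected(self, tiny):
        cm, grouping = tiny
        with pytest.raises(KeyError):
            induce_specificity(cm, grouping, InductionSpec("add", 1.0, "T", ["nope"]))
        with pytest.raises(KeyError):
            induce_specificity(cm, grouping, InductionSpec("add", 1.0, "X", ["g1"]))


class TestRankSumOverlap:
    @pytest.fixture
    def ten(self):
        return SampleGrouping([f"s{i}" for i in range(10)],
                              ["T"] * 3 + ["U"] * 7)

    def test_target_on_top_attains_minimum(self, ten):
        y = [30, 20, 10] + [5, 4, 3, 2, 1, 0.5, 0.1]
        assert rank_sum_overlap(y, ten, "T") == 6  # 1+2+3

    def test_target_at_bottom_attains_maximum(self, ten):
        y = [0.3, 0.2, 0.1] + [5, 4, 3, 2, 1, 0.9, 0.5]
        assert rank_sum_overlap(y, ten, "T") == 27  # 8+9+10

    def test_interleaved_positions(self, ten):
        # target samples land at descending positions 1, 3, 5
        y = [100, 80, 60] + [90, 70, 50, 40, 30, 20, 10]
        assert rank_sum_overlap(y, ten, "T") == 9

    def test_ties_get_average_ranks(self, ten):
        y = [1.0] * 10
        assert rank_sum_overlap(y, ten, "T") == 3 * 5.5


class TestRankScores:
    def test_rank_one_is_most_specific(self):
        r = rank_scores(pd.Series([0.99, 0.5, 0.7], index=list("abc")))
        assert r.to_dict() == {"a": 1.0, "c": 2.0, "b": 3.0}

    def test_ties_averaged(self):
        r = rank_scores(pd.Series([0.9, 0.9, 0.1]))
        assert list(r) == [1.5, 1.5, 3.0]

    def test_missing_ranked_last(self):
        r = rank_scores(pd.Series([0.2, np.nan, 0.8]))
        assert r.iloc[1] == 3.0

    def test_ranks_are_a_permutation_when_no_ties(self):
        rng = np.random.default_rng(0)
        r = rank_scores(pd.Series(rng.normal(size=25)))
        assert sorted(r) == list(range(1, 26))


class TestBenchmarkCycles:
    def test_same_seed_reproduces_runs_exactly(self, sim_dataset):
        _, grouping, _, background = sim_dataset
        kw = dict(mode="multiply", amount=5.0, n_induced=8, n_cycles=2, seed=13)
        runs_a, p_a = run_benchmark_cycles(background, grouping, **kw)
        runs_b, p_b = run_benchmark_cycles(background, grouping, **kw)
        assert p_a == p_b
        for ra, rb in zip(runs_a, runs_b):
            assert ra.spec.genes == rb.spec.genes
            assert ra.spec.target_state == rb.spec.target_state
            pd.testing.assert_frame_equal(ra.ranks, rb.ranks)

    def test_strong_induction_puts_induced_genes_on_top_for_every_metric(self, sim_dataset):
        _, grouping, _, background = sim_dataset
        runs, _ = run_benchmark_cycles(
            background, grouping, mode="add", amount=1000.0,
            n_induced=8, n_cycles=2, seed=5,
        )
        floor = 8 * 9 / 2
        for run in runs:
            for m in METRICS:
                assert run.summed_ranks[m] == pytest.approx(floor), m

    def test_summed_ranks_respect_lower_bound(self, sim_dataset):
        _, grouping, _, background = sim_dataset
        runs, _ = run_benchmark_cycles(
            background, grouping, mode="multiply", amount=3.0,
            n_induced=8, n_cycles=2, seed=3,
        )
        for run in runs:
            assert (run.summed_ranks >= 8 * 9 / 2).all()
            assert (run.overlap >= 0).all()

    def test_benchmark_table_is_tidy(self, sim_dataset):
        _, grouping, _, background = sim_dataset
        runs, _ = run_benchmark_cycles(
            background, grouping, mode="multiply", amount=5.0,
            n_induced=5, n_cycles=2, seed=1,
        )
        table = benchmark_table(runs)
        assert len(table) == 2 * 5 * len(METRICS)
        assert set(table["metric"]) == set(METRICS)

    def test_overlap_correlation_strongest_for_specs(self, sim_dataset):
        """Mid-strength multiplication: only SPECS is sensitive to residual
        distributional overlap, so its score rank tracks the rank-sum overlap
        more strongly than any replicate-collapsing comparator."""
        _, grouping, _, background = sim_dataset
        runs, _ = run_benchmark_cycles(
            background, grouping, mode="multiply", amount=5.0,
            n_induced=10, n_cycles=3, seed=17,
        )
        corr = overlap_score_correlations(runs)
        assert corr["SPECS"] > 0
        assert corr["SPECS"] == corr.max()


class TestSubsampleExperiment:
    def test_fraction_one_reproduces_full_scores(self, sim_dataset):
        _, grouping, _, background = sim_dataset
        res = subsample_experiment(
            background, grouping, amount=1000.0, n_induced=5,
            fractions=(1.0,), n_repeats=2, seed=2,
        )
        assert (res.table["score"] == 1.0).all()  # forced perfect separation

    def test_perfect_separation_survives_any_fraction(self, sim_dataset):
        _, grouping, _, background = sim_dataset
        res = subsample_experiment(
            background, grouping, amount=5000.0, n_induced=5,
            fractions=(0.2, 0.6, 1.0), n_repeats=2, seed=8,
        )
        assert (res.table["score"] == 1.0).all()

    def test_same_seed_is_deterministic(self, sim_dataset):
        _, grouping, _, background = sim_dataset
        kw = dict(amount=10.0, n_induced=5, fractions=(0.5, 1.0), n_repeats=2, seed=4)
        a = subsample_experiment(background, grouping, **kw)
        b = subsample_experiment(background, grouping, **kw)
        pd.testing.assert_frame_equal(a.table, b.table)
        assert a.per_repeat_p == b.per_repeat_p

    def test_too_small_fraction_names_the_group(self, sim_dataset):
        _, grouping, _, background = sim_dataset
        with pytest.raises(ValueError, match="fewer than 2 samples"):
            subsample_experiment(
                background, grouping, fractions=(0.01,), n_repeats=1,
                n_induced=5, seed=0, scope="all",
            )


class TestFoldChangeToSecond:
    def test_direct_ratio_without_pseudocount(self):
        prof = pd.Series([100, 10, 5], index=list("abc"))
        assert fold_change_to_second(prof, "a", pseudocount=0) == 10.0

    def test_pseudocount_handles_absent_background(self):
        prof = pd.Series([100, 0, 0], index=list("abc"))
        assert fold_change_to_second(prof, "a", pseudocount=1) == 101.0

    def test_non_maximal_state_gives_fold_change_below_one(self):
        prof = pd.Series([10, 100, 5], index=list("abc"))
        assert fold_change_to_second(prof, "a", pseudocount=0) < 1.0
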