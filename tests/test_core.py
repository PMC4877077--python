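import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from gsanova.core import (
    F_CAP_DEFAULT,
    GeneLevelStats,
    GsanovaParams,
    estimate_pi0,
    expressed_mask,
    gene_f_statistics,
    nominal_p,
    permutation_null,
    pooled_p,
    qvalues,
    raw_set_score,
    run_gsanova,
    standardize_score,
)
from gsanova.io_formats import CountMatrix, GeneSetCollection, SampleDesign
from gsanova.normalize import ExpressionMatrix
from gsanova.simulate import simulate_dataset


def em_from(values, prefix="g"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        [f"{prefix}{i}" for i in range(values.shape[0])],
        [f"s{j}" for j in range(values.shape[1])],
        values,
    )


def design_for(labels):
    samples = [f"s{j}" for j in range(len(labels))]
    return SampleDesign(samples, dict(zip(samples, labels)))


class TestGeneFStatistics:
    def test_hand_worked_two_group_anova(self):
        # groups {1,2} vs {3,4}: between SS 4, within SS 1, scale 2 -> f=8
        em = em_from([[1.0, 2.0, 3.0, 4.0]])
        stats = gene_f_statistics(em, design_for(["A", "A", "B", "B"]))
        assert stats.f[0] == pytest.approx(8.0, abs=1e-12)

    def test_equal_group_means_give_zero(self):
        em = em_from([[1.0, 3.0, 2.0, 2.0]])
        stats = gene_f_statistics(em, design_for(["A", "A", "B", "B"]))
        assert stats.f[0] == pytest.approx(0.0, abs=1e-12)

    def test_unexpressed_genes_scored_zero(self):
        em = em_from([[1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0]])
        stats = gene_f_statistics(
            em, design_for(["A", "A", "B", "B"]), expressed=np.array([True, False])
        )
        assert stats.f[1] == 0.0 and stats.f[0] > 0

    def test_zero_within_with_signal_hits_cap(self):
        em = em_from([[1.0, 1.0, 2.0, 2.0]])
        stats = gene_f_statistics(em, design_for(["A", "A", "B", "B"]))
        assert stats.f[0] == F_CAP_DEFAULT

    def test_constant_gene_scores_zero(self):
        em = em_from([[5.0] * 6])
        stats = gene_f_statistics(em, design_for(["A", "A", "B", "B", "C", "C"]))
        assert stats.f[0] == 0.0

    def test_matches_scipy_oneway_oracle(self):
        rng = np.random.default_rng(7)
        labels = ["A", "A", "A", "B", "B", "B", "C", "C", "C"]
        design = design_for(labels)
        groups = design.labels()
        for _ in range(25):
            vals = rng.normal(size=(10, 9))
            ours = gene_f_statistics(em_from(vals), design).f
            for g in range(10):
                ref = sps.f_oneway(*(vals[g, groups == c] for c in range(3))).statistic
                assert ours[g] == pytest.approx(ref, abs=1e-9)

    def test_invariances_shift_scale_within_group_permutation(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(size=(5, 6))
        design = design_for(["A", "A", "B", "B", "C", "C"])
        base = gene_f_statistics(em_from(vals), design).f
        shifted = gene_f_statistics(em_from(vals + 7.3), design).f
        scaled = gene_f_statistics(em_from(vals * -2.5), design).f
        swapped = gene_f_statistics(em_from(vals[:, [1, 0, 3, 2, 5, 4]]), design).f
        for other in (shifted, scaled, swapped):
            assert np.allclose(base, other, atol=1e-8)

    def test_rejects_saturated_design(self):
        em = em_from([[1.0, 2.0]])
        with pytest.raises(ValueError, match="n > k"):
            gene_f_statistics(em, design_for(["A", "B"]))

    def test_rejects_missing_samples(self):
        em = em_from([[1.0, 2.0, 3.0]])
        design = SampleDesign(
            ["s0", "s1", "zz"], {"s0": "A", "s1": "A", "zz": "B"}
        )
        with pytest.raises(ValueError, match="absent"):
            gene_f_statistics(em, design)

    def test_expressed_mask_uses_total_counts(self):
        cm = CountMatrix(
            ["on", "off"], ["s1", "s2"], np.array([[3, 0], [0, 0]])
        )
        assert expressed_mask(cm).tolist() == [True, False]
        assert expressed_mask(cm, min_total=4).tolist() == [False, False]


def stats_from(f):
    f = np.asarray(f, dtype=float)
    return GeneLevelStats([f"g{i}" for i in range(f.size)], f, f >= 0)


class TestSetScores:
    def test_raw_score_is_mean_over_present_members(self):
        stats = stats_from([2.0, 3.0, 9.0])
        score, size = raw_set_score(stats, {"g0", "g1"})
        assert (score, size) == (2.5, 2)

    def test_absent_members_ignored(self):
        stats = stats_from([2.0, 3.0])
        score, size = raw_set_score(stats, {"g0", "g1", "nope"})
        assert (score, size) == (2.5, 2)

    def test_fully_absent_set_reports_empty(self):
        score, size = raw_set_score(stats_from([1.0]), {"nope"})
        assert size == 0 and np.isnan(score)

    def test_exhaustive_standardization_matches_enumeration(self):
        # universe f=(0,1,2,3), size-2 null means (0.5,1,1.5,1.5,2,2.5)
        stats = stats_from([0.0, 1.0, 2.0, 3.0])
        z = standardize_score(2.5, 2, stats, method="exhaustive")
        assert z == pytest.approx((2.5 - 1.5) / np.sqrt(0.5), abs=1e-12)

    def test_raw_at_null_mean_standardizes_to_zero(self):
        stats = stats_from([0.0, 1.0, 2.0, 3.0])
        assert standardize_score(1.5, 2, stats, method="exhaustive") == pytest.approx(0.0)

    def test_constant_universe_standardizes_to_zero(self):
        stats = stats_from([2.0] * 10)
        assert standardize_score(2.0, 3, stats, n_random=50, rng=0) == 0.0

    def test_sampled_agrees_with_exhaustive_on_moderate_universe(self):
        rng = np.random.default_rng(9)
        stats = stats_from(rng.exponential(size=12))
        exh = standardize_score(1.7, 3, stats, method="exhaustive")
        # C(12,3)=220 subsets > n_random here, so this is true sampling
        samp = standardize_score(1.7, 3, stats, n_random=200, rng=10)
        assert samp == pytest.approx(exh, abs=0.3)

    def test_size_larger_than_universe_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            standardize_score(1.0, 5, stats_from([1.0, 2.0]), rng=0)


class TestPermutationPValues:
    def test_observed_beyond_all_nulls(self):
        assert nominal_p(10.0, np.zeros(99)) == pytest.approx(1 / 100)

    def test_hand_counted_tail(self):
        assert nominal_p(2.0, np.array([0.5, 1.0, 2.5])) == pytest.approx(0.5)

    def test_observed_below_all_nulls(self):
        assert nominal_p(-5.0, np.zeros(9)) == 1.0

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            nominal_p(1.0, np.array([]))

    def test_pooled_with_single_set_equals_nominal(self):
        null = np.array([0.1, 0.9, 1.4, -0.3])
        assert pooled_p(1.0, null) == nominal_p(1.0, null)

    def test_pooled_p_monotone_in_observed(self):
        null = np.random.default_rng(11).normal(size=500)
        ps = [pooled_p(obs, null) for obs in np.linspace(-3, 3, 25)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestPermutationNull:
    def test_same_seed_bit_identical(self, toy_sets):
        cm, design, sets, _ = simulate_dataset("null", seed=1, n_genes=60, n_sets=4)
        from gsanova.normalize import vst_log

        em = vst_log(cm)
        params = GsanovaParams(n_random_sets=30, n_permutations=20, rng_seed=5)
        a = permutation_null(em, design, sets, params)
        b = permutation_null(em, design, sets, params)
        for name in sets:
            assert np.array_equal(a[name], b[name])

    def test_constant_data_yields_constant_null(self):
        em = em_from(np.full((8, 6), 3.0))
        design = design_for(["A", "A", "B", "B", "C", "C"])
        sets = GeneSetCollection()
        sets.add("S", {"g0", "g1", "g2"})
        params = GsanovaParams(n_random_sets=20, n_permutations=10, rng_seed=2)
        null = permutation_null(em, design, sets, params)
        assert np.allclose(null["S"], null["S"][0])

    def test_reuse_random_sets_mode_runs_and_is_deterministic(self):
        cm, design, sets, _ = simulate_dataset("null", seed=3, n_genes=80, n_sets=3)
        from gsanova.normalize import vst_log

        em = vst_log(cm)
        params = GsanovaParams(
            n_random_sets=25, n_permutations=15, rng_seed=6, reuse_random_sets=True
        )
        a = permutation_null(em, design, sets, params)
        b = permutation_null(em, design, sets, params)
        for name in sets:
            assert np.array_equal(a[name], b[name])


def bh_oracle(p):
    """Textbook Benjamini-Hochberg step-up, independent of the implementation."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        adjusted[idx] = running
    return np.minimum(adjusted, 1.0)


class TestQValues:
    def test_single_unit_pvalue(self):
        assert qvalues(np.array([1.0])).tolist() == [1.0]

    def test_hand_worked_bh(self):
        q = qvalues(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, 0.04)

    def test_out_of_range_p_rejected(self):
        for bad in ([0.0, 0.5], [0.5, 1.2]):
            with pytest.raises(ValueError):
                qvalues(np.array(bad))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=60))
    def test_fixed_pi0_equals_bh_everywhere(self, p):
        p = np.array(p)
        assert np.allclose(qvalues(p), bh_oracle(p), atol=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=2, max_size=40))
    def test_q_monotone_in_p(self, p):
        p = np.array(p)
        q = qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_storey_pi0_bounded_and_scales_q(self):
        rng = np.random.default_rng(12)
        p = np.concatenate([rng.uniform(size=300), rng.uniform(0, 0.01, size=60)])
        pi0 = estimate_pi0(p)
        assert 0 < pi0 <= 1
        q_fix = qvalues(p)
        q_sto = qvalues(p, pi0_method="storey_smoother")
        assert np.allclose(q_sto, np.clip(pi0 * q_fix, 0, 1), atol=1e-12)


@pytest.fixture(scope="module")
def spiked_run():
    cm, design, sets, truth = simulate_dataset(
        "spiked", seed=21, n_genes=2000, n_sets=12
    )
    params = GsanovaParams(n_random_sets=200, n_permutations=200, rng_seed=22)
    return run_gsanova(cm, design, sets, params), truth, params


class TestRunGsanova:
    def test_spiked_set_attains_top_standardized_score(self, spiked_run):
        results, truth, _ = spiked_run
        best = max(results, key=lambda r: r.standardized_score)
        assert best.set_name == truth.spiked_set_names[0]

    def test_significance_flag_matches_cutoff(self, spiked_run):
        results, _, params = spiked_run
        for r in results:
            assert r.significant == (r.q_value < params.q_cutoff)

    def test_results_sorted_by_q_then_pooled_p(self, spiked_run):
        results, _, _ = spiked_run
        keys = [(r.q_value, r.p_pooled) for r in results]
        assert keys == sorted(keys)

    def test_p_values_in_unit_interval(self, spiked_run):
        results, _, _ = spiked_run
        for r in results:
            assert 0 < r.p_nominal <= 1
            assert 0 < r.p_pooled <= 1
            assert 0 <= r.q_value <= 1

    def test_log_records_seed_and_skipped_sets(self):
        cm, design, sets, _ = simulate_dataset("null", seed=30, n_genes=100, n_sets=3)
        sets.add("ghost", {"not-a-gene"})
        params = GsanovaParams(n_random_sets=20, n_permutations=20, rng_seed=31)
        results = run_gsanova(cm, design, sets, params)
        assert results.log["seed"] == 31
        assert "ghost" in results.log["skipped_sets"]
        assert len(results) == 3

    def test_all_sets_skipped_is_error(self):
        cm, design, _, _ = simulate_dataset("null", seed=32, n_genes=50, n_sets=2)
        ghost = GeneSetCollection()
        ghost.add("ghost", {"not-a-gene"})
        with pytest.raises(ValueError, match="no gene set"):
            run_gsanova(cm, design, ghost, GsanovaParams(n_random_sets=5, n_permutations=5))

    def test_set_size_filters_applied(self):
        cm, design, sets, _ = simulate_dataset("null", seed=33, n_genes=300, n_sets=6)
        params = GsanovaParams(
            n_random_sets=20, n_permutations=20, rng_seed=34, min_set_size=25
        )
        results = run_gsanova(cm, design, sets, params)
        assert all(r.set_size_in_universe >= 25 for r in results)
        assert len(results) + len(results.log["skipped_sets"]) == 6
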