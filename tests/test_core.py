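"""Unit and property tests of the FCROS statistic itself."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from fcros import (
    build_pairing,
    classify_genes,
    compute_f_values,
    compute_pairwise_fc,
    fcros,
    fcros2,
    fit_rank_model,
    fold_changes,
    from_groups,
    gene_fold_change,
    rank_columns,
    selection_error_percent,
    theoretical_moments,
    trimmed_rank_means,
)
from fcros.datasets import worked_example


# --------------------------------------------------------------- oracles


def brute_force_midranks(column):
    """Independent midrank implementation: explicit tie-group averaging."""
    column = np.asarray(column, dtype=float)
    order = np.argsort(column, kind="stable")
    ranks = np.empty(column.size)
    i = 0
    while i < column.size:
        j = i
        while j + 1 < column.size and column[order[j + 1]] == column[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = np.mean(np.arange(i, j + 1) + 1.0)
        i = j + 1
    return ranks


def brute_force_trimmed_mean(row, trim, n):
    g = int(np.floor(len(row) * trim))
    kept = sorted(row)[g : len(row) - g]
    return sum(kept) / len(kept) / n


# --------------------------------------------------------------- pairing


class TestBuildPairing:
    def test_full_grid_control_major(self):
        assert build_pairing(2, 2, "all") == [(0, 0), (0, 1), (1, 0), (1, 1)]

    def test_ten_by_ten_grid_size(self):
        assert len(build_pairing(10, 10, "all")) == 100

    def test_prefix_of_canonical_order(self):
        full = build_pairing(3, 2, "all")
        assert build_pairing(3, 2, 5) == full[:5]

    @pytest.mark.parametrize("k", [0, 7, -1])
    def test_invalid_k_rejected(self, k):
        with pytest.raises(ValueError):
            build_pairing(3, 2, k)


# --------------------------------------------------------------- fold changes


class TestPairwiseFC:
    def test_constant_genes_give_zero_rows(self):
        v = np.repeat([[3.0], [8.0]], 3, axis=1)  # each gene flat everywhere
        m = from_groups(["a", "b"], v, v)
        fc = compute_pairwise_fc(m, build_pairing(3, 3, "all"))
        np.testing.assert_array_equal(fc, 0.0)

    def test_doubling_is_one_log2_unit(self):
        m = from_groups(["a", "b"], [[10.0], [5.0]], [[11.0], [5.0]])
        fc = compute_pairwise_fc(m, [(0, 0)])
        assert fc[0, 0] == pytest.approx(1.0)

    def test_worked_example_first_pair(self):
        fc = compute_pairwise_fc(worked_example(), [(0, 0)])
        assert fc[0, 0] == pytest.approx(-0.1060, abs=1e-10)

    def test_out_of_range_pair_rejected(self):
        m = from_groups(["a", "b"], [[1.0], [2.0]], [[1.0], [2.0]])
        with pytest.raises(ValueError, match="out of range"):
            compute_pairwise_fc(m, [(0, 1)])


class TestGeneFoldChange:
    def test_worked_example_values(self, example_matrix):
        assert gene_fold_change(example_matrix, 0) == pytest.approx(0.8806, abs=5e-5)
        assert gene_fold_change(example_matrix, 1) == pytest.approx(6.2570, abs=2e-4)

    def test_identical_groups_give_unity(self):
        v = np.arange(6, dtype=float).reshape(2, 3)
        m = from_groups(["a", "b"], v, v)
        np.testing.assert_allclose(fold_changes(m), 1.0)

    def test_log2_ratio_data_uses_geometric_mean(self):
        m = from_groups(["a", "b"], [[0.0, 0.0], [1.0, 3.0]],
                        [[2.0, 2.0], [1.0, 3.0]], scale_tag="log2-ratio")
        np.testing.assert_allclose(fold_changes(m), [4.0, 1.0])


# --------------------------------------------------------------- ranking


class TestRankColumns:
    def test_strict_ordering(self):
        np.testing.assert_array_equal(
            rank_columns(np.array([0.5, -1.0, 2.0]))[:, 0], [2, 1, 3]
        )

    def test_midrank_ties_preserve_sum(self):
        r = rank_columns(np.array([1.0, 1.0, 3.0]))[:, 0]
        np.testing.assert_array_equal(r, [1.5, 1.5, 3])
        assert r.sum() == 6

    @settings(deadline=None, max_examples=30)
    @given(
        hnp.arrays(
            float, st.tuples(st.integers(2, 40), st.integers(1, 5)),
            elements=st.floats(-5, 5, width=16),
        )
    )
    def test_rank_sum_conserved_and_matches_oracle(self, fc):
        ranks = rank_columns(fc)
        n = fc.shape[0]
        np.testing.assert_allclose(ranks.sum(axis=0), n * (n + 1) / 2)
        for j in range(fc.shape[1]):
            np.testing.assert_array_equal(ranks[:, j], brute_force_midranks(fc[:, j]))

    def test_oracle_agreement_on_many_random_columns(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            col = rng.integers(0, 8, size=rng.integers(2, 30)).astype(float)
            np.testing.assert_array_equal(
                rank_columns(col)[:, 0], brute_force_midranks(col)
            )


# --------------------------------------------------------------- trimmed means


class TestTrimmedRankMeans:
    def test_symmetric_trim_of_symmetric_set(self):
        ranks = np.array([[1.0, 2, 3, 4, 5]])
        # n is the rank scale; here a 5-gene column context is implied
        rbar = trimmed_rank_means(np.vstack([ranks] * 5), trim=0.2)
        np.testing.assert_allclose(rbar, 3.0 / 5.0)

    def test_constant_rank_vector(self):
        ranks = np.full((4, 6), 2.0)
        np.testing.assert_allclose(trimmed_rank_means(ranks, 0.3), 2.0 / 4.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        n, k = 200, 9
        ranks = rng.integers(1, n + 1, size=(n, k)).astype(float)
        rbar = trimmed_rank_means(ranks, trim=0.3)
        expect = [brute_force_trimmed_mean(row, 0.3, n) for row in ranks]
        np.testing.assert_allclose(rbar, expect)

    def test_invalid_trim_fraction_rejected(self):
        with pytest.raises(ValueError, match="trim"):
            trimmed_rank_means(np.ones((3, 2)), trim=0.5)


# --------------------------------------------------------------- rank model


class TestFitRankModel:
    def test_ideal_equally_spaced_grid(self):
        n = 100
        rbar = np.arange(1, n + 1) / n
        s = fit_rank_model(rbar)
        assert s.R_bar == pytest.approx((n + 1) / (2 * n))
        assert s.delta_hat == pytest.approx(1.0 / n)
        assert s.a == pytest.approx(1.0 / n) and s.b == 1.0
        assert s.sigma2_hat == pytest.approx(np.var(rbar, ddof=1))

    @settings(deadline=None, max_examples=50)
    @given(
        hnp.arrays(float, st.integers(2, 200),
                   elements=st.floats(0.001, 1.0))
    )
    def test_delta_hat_telescopes(self, rbar):
        try:
            s = fit_rank_model(rbar)
        except ValueError:
            return  # degenerate constant vector
        n = rbar.size
        assert s.delta_hat == pytest.approx((s.b - s.a) / (n - 1), rel=1e-9, abs=1e-13)

    def test_degenerate_variance_raises(self):
        with pytest.raises(ValueError, match="variance"):
            fit_rank_model(np.full(5, 0.5))


class TestTheoreticalMoments:
    def test_ideal_situation(self):
        n = 101
        mean, var = theoretical_moments(1, n, n, 1)
        assert mean == (n + 1) / 2
        assert var == (n * n - 1) / 12

    def test_two_point_case(self):
        assert theoretical_moments(1, 2, 2, 1) == (1.5, 0.25)

    @pytest.mark.parametrize("n", [3, 10, 137, 1000])
    def test_matches_enumeration_of_equally_spaced_grid(self, n):
        a, delta = 0.7, 0.013
        grid = a + delta * np.arange(n)
        mean, var = theoretical_moments(a, grid[-1], n, delta)
        assert mean == pytest.approx(grid.mean())
        assert var == pytest.approx(grid.var())  # population variance


# --------------------------------------------------------------- f-values


class TestFValues:
    def _summary(self, n=100, seed=5):
        rng = np.random.default_rng(seed)
        rbar = np.sort(rng.uniform(0.01, 1.0, n))
        return rbar, fit_rank_model(rbar)

    def test_cdf_at_mean_is_half(self):
        _, s = self._summary()
        assert compute_f_values(np.array([s.R_bar]), s)[0] == pytest.approx(0.5)

    def test_normal_quantile_identity(self):
        _, s = self._summary()
        x = s.R_bar + 1.959964 * np.sqrt(s.sigma2_hat)
        assert compute_f_values(np.array([x]), s)[0] == pytest.approx(0.975, abs=1e-6)

    def test_dominant_gene_gets_maximal_f_value(self):
        rng = np.random.default_rng(3)
        n, m = 100, 4
        ctl = rng.normal(8, 0.5, size=(n, m))
        tst = rng.normal(8, 0.5, size=(n, m))
        tst[17] = ctl[17] + 20.0  # exceeds every other gene's log-FC everywhere
        res = fcros(from_groups([f"g{i}" for i in range(n)], ctl, tst))
        assert int(np.argmax(res.f_value)) == 17
        assert 0.0 < res.f_value.min() and res.f_value.max() < 1.0


# --------------------------------------------------------------- classification


class TestClassifyGenes:
    @pytest.mark.parametrize(
        "a1, a2, err",
        [(0.0228, 0.9773, 4.55), (0.0356, 0.9644, 7.12), (0.025, 0.975, 5.0)],
    )
    def test_error_percent_formula(self, a1, a2, err):
        assert selection_error_percent(a1, a2) == pytest.approx(err)

    def test_threeway_calls_follow_thresholds(self):
        f = np.array([0.01, 0.025, 0.5, 0.975, 0.99])
        call, err = classify_genes(f, 0.025, 0.975)
        assert list(call) == ["down", "down", "EE", "up", "up"]
        assert err == pytest.approx(5.0)

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ValueError):
            classify_genes(np.array([0.5]), 0.6, 0.4)


# --------------------------------------------------------------- full pipeline


class TestFcrosPipeline:
    def test_shifted_gene_dominates_flat_background(self):
        rng = np.random.default_rng(0)
        n = 50
        base = rng.normal(8, 0.01, size=(n, 6))
        tst = base.copy()
        tst[7] += 3.0
        res = fcros(from_groups([f"g{i}" for i in range(n)], base[:, :3], tst[:, 3:]))
        assert int(np.argmax(res.f_value)) == 7

    def test_group_swap_maps_f_to_one_minus_f(self, random_matrix):
        m = random_matrix(n=80, m1=4, m2=5, seed=9)
        f = fcros(m).f_value
        f_sw = fcros(m.swapped()).f_value
        assert np.abs(f_sw - (1.0 - f)).max() < 1e-12

    def test_within_group_permutation_invariance(self, random_matrix):
        m = random_matrix(n=60, m1=4, m2=3, seed=2)
        res = fcros(m)
        rng = np.random.default_rng(1)
        perm = ( list(rng.permutation(m.control_indices))
               + list(rng.permutation(m.test_indices)) )
        m2 = from_groups(m.gene_ids, m.values[:, perm[:4]], m.values[:, perm[4:]])
        np.testing.assert_array_equal(res.f_value, fcros(m2).f_value)

    def test_constant_shift_leaves_f_values_unchanged(self, random_matrix):
        m = random_matrix(n=60, m1=3, m2=3, seed=4)
        shifted = from_groups(m.gene_ids, m.control_values + 7.3,
                              m.test_values + 7.3)
        np.testing.assert_array_equal(fcros(m).f_value, fcros(shifted).f_value)

    def test_planted_up_and_down_genes_recovered(self):
        rng = np.random.default_rng(21)
        n = 500
        base = rng.uniform(6, 10, n)
        ctl = base[:, None] + rng.normal(0, 0.1, (n, 5))
        tst = base[:, None] + rng.normal(0, 0.1, (n, 5))
        up, down = np.arange(10), np.arange(10, 20)
        tst[up] += 3.0
        tst[down] -= 3.0
        res = fcros(from_groups([f"g{i}" for i in range(n)], ctl, tst))
        assert set(np.argsort(res.f_value)[-10:]) == set(up)
        assert set(np.argsort(res.f_value)[:10]) == set(down)

    def test_recovers_simulator_truth(self, planted_dataset):
        res = fcros(planted_dataset.matrix)
        top = np.argsort(np.abs(res.f_value - 0.5))[-planted_dataset.n_de:]
        assert set(top) == planted_dataset.truth_set()


class TestFcros2:
    def test_duplicate_batch_matches_single_batch(self, random_matrix):
        # k = 4 and trim = 0.3: floor(2k*trim) = 2*floor(k*trim), so the
        # duplicated rank sets trim to exactly the same kept values
        m = random_matrix(n=40, m1=2, m2=2, seed=6)
        single = fcros(m, trim=0.3)
        double = fcros2(m, m, trim=0.3)
        np.testing.assert_allclose(double.rbar, single.rbar)
        np.testing.assert_array_equal(
            np.argsort(double.f_value), np.argsort(single.f_value)
        )

    def test_global_batch_offset_is_ignored(self, random_matrix):
        m = random_matrix(n=40, m1=2, m2=2, seed=8)
        shifted = from_groups(m.gene_ids, m.control_values + 5.0,
                              m.test_values + 5.0)
        np.testing.assert_array_equal(
            fcros2(m, m).f_value, fcros2(m, shifted).f_value
        )

    def test_gene_id_mismatch_names_first_discrepancy(self, random_matrix):
        m1 = random_matrix(n=10, seed=1)
        m2 = random_matrix(n=10, seed=1)
        m2.gene_ids[3] = "weird"
        with pytest.raises(ValueError, match="'g3' vs 'weird'"):
            fcros2(m1, m2)
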