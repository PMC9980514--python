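"""Dirichlet-multinomial mixture, rarefaction, diversity, PERMANOVA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from milkgut import (
    alpha_diversity,
    assign_gmc,
    bray_curtis,
    dm_log_pmf,
    dmm_fit,
    dmm_select,
    permanova,
    rarefy,
    rescale_to_counts,
    simulate_dmm_counts,
)


def _enumerate_counts(N, J):
    """All count vectors of length J with total N (stars and bars)."""
    for cuts in itertools.combinations_with_replacement(range(N + 1), J - 1):
        cuts = (0,) + cuts + (N,)
        yield tuple(cuts[i + 1] - cuts[i] for i in range(J))


class TestDMLogPmf:
    def test_uniform_case_by_enumeration(self):
        # alpha=(1,1) makes all compositions of N equally likely: 3 of N=2
        assert dm_log_pmf([1, 1], [1, 1]) == pytest.approx(np.log(1 / 3), abs=1e-12)

    def test_exchangeability_for_symmetric_alpha(self):
        a = [0.7, 0.7, 0.7]
        assert dm_log_pmf([5, 0, 0], a) == pytest.approx(dm_log_pmf([0, 0, 5], a))

    @pytest.mark.parametrize("N,J,alpha", [
        (5, 3, (2.0, 0.5, 1.3)),
        (6, 2, (0.2, 3.0)),
        (4, 3, (1.0, 1.0, 1.0)),
    ])
    def test_normalizes_over_all_count_vectors(self, N, J, alpha):
        total = sum(np.exp(dm_log_pmf(x, alpha)) for x in _enumerate_counts(N, J))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            dm_log_pmf([-1, 2], [1.0, 1.0])


class TestDMMFit:
    def test_single_component_parameter_recovery(self):
        alpha_true = np.array([50.0, 30.0, 10.0, 10.0])
        counts, _ = simulate_dmm_counts(
            200, pi=(1.0,), alphas=[alpha_true], depth=2000, seed=0
        )
        m = dmm_fit(counts, K=1, seed=0)
        assert np.allclose(m.responsibilities.to_numpy(), 1.0)
        mean_fit = m.alpha[0] / m.alpha[0].sum()
        mean_true = alpha_true / alpha_true.sum()
        assert np.abs(mean_fit - mean_true).max() < 0.05

    def test_loglik_monotone_and_responsibilities_normalized(self):
        counts, _ = simulate_dmm_counts(
            80, pi=(0.5, 0.5), alphas=[(40, 2, 2), (2, 40, 2)], depth=1000, seed=1
        )
        m = dmm_fit(counts, K=2, seed=1)
        trace = np.array(m.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-8)
        assert np.allclose(m.responsibilities.sum(axis=1), 1.0, atol=1e-12)
        assert m.pi.sum() == pytest.approx(1.0)
        assert np.all(m.alpha > 0)

    def test_sample_order_equivariance(self):
        counts, _ = simulate_dmm_counts(
            60, pi=(0.5, 0.5), alphas=[(40, 2, 2), (2, 40, 2)], depth=1000, seed=2
        )
        m1 = dmm_fit(counts, K=2, seed=3)
        perm = np.random.default_rng(0).permutation(len(counts))
        m2 = dmm_fit(counts.iloc[perm], K=2, seed=3)
        r1 = m1.responsibilities.loc[counts.index[perm]].to_numpy()
        r2 = m2.responsibilities.to_numpy()
        # components may be relabeled; compare best-matched columns
        match = [int(np.argmax(r1.T @ r2[:, k])) for k in range(2)]
        assert sorted(match) == [0, 1]
        assert np.allclose(r1[:, match], r2, atol=1e-3)

    def test_k_exceeding_n_rejected(self):
        counts, _ = simulate_dmm_counts(3, pi=(1.0,), alphas=[(5, 5)], depth=100, seed=0)
        with pytest.raises(ValueError):
            dmm_fit(counts, K=5, seed=0)


class TestDMMSelect:
    def test_single_component_data_selects_k1(self):
        counts, _ = simulate_dmm_counts(
            120, pi=(1.0,), alphas=[(20.0, 10.0, 5.0)], depth=1000, seed=4
        )
        best_K, models = dmm_select(counts, range(1, 4), seed=4, n_restarts=2)
        assert best_K == 1
        assert all(np.isfinite(m.laplace_score) for m in models.values())

    def test_empty_range_rejected(self):
        counts, _ = simulate_dmm_counts(10, pi=(1.0,), alphas=[(5, 5)], depth=100, seed=0)
        with pytest.raises(ValueError):
            dmm_select(counts, [], seed=0)


class TestAssignGMC:
    def test_relabeling_by_prevalence_and_tie_break(self):
        resp = pd.DataFrame(
            [[0.9, 0.1], [0.8, 0.2], [0.6, 0.4], [0.1, 0.9], [0.5, 0.5]],
            index=list("abcde"),
            columns=["C1", "C2"],
        )
        model = type("M", (), {})()
        model.K = 2
        model.responsibilities = resp
        out = assign_gmc(model)
        # component 1 wins 4 samples (incl. the 0.5/0.5 tie -> lower index)
        assert list(out.gmc_type) == [1, 1, 1, 2, 1]
        assert out.max_responsibility.iloc[-1] == pytest.approx(0.5)

    def test_three_way_relabeling(self):
        rng = np.random.default_rng(0)
        n = (10, 80, 15)
        rows, idx = [], []
        for k, nk in enumerate(n):
            for i in range(nk):
                r = np.full(3, 0.05)
                r[k] = 0.9
                rows.append(r)
                idx.append(f"s{k}_{i}")
        model = type("M", (), {})()
        model.K = 3
        model.responsibilities = pd.DataFrame(rows, index=idx, columns=list("ABC"))
        out = assign_gmc(model)
        # sizes (10, 80, 15): component 2 -> type 1, 3 -> type 2, 1 -> type 3
        assert set(out[out.sample_id.str.startswith("s1")].gmc_type) == {1}
        assert set(out[out.sample_id.str.startswith("s2")].gmc_type) == {2}
        assert set(out[out.sample_id.str.startswith("s0")].gmc_type) == {3}


class TestRarefy:
    def test_depth_equal_to_total_is_identity(self, small_counts):
        depth = int(small_counts.sum(axis=1).min())
        out = rarefy(small_counts, depth=None, seed=0)
        assert (out.sum(axis=1) == depth).all()
        full = rarefy(small_counts.iloc[:1], depth=int(small_counts.iloc[0].sum()), seed=0)
        pd.testing.assert_frame_equal(full, small_counts.iloc[:1])

    def test_absent_taxon_stays_absent(self):
        counts = pd.DataFrame([[1000, 0]], columns=["a", "b"])
        out = rarefy(counts, depth=100, seed=1)
        assert out.iloc[0].tolist() == [100, 0]

    def test_expected_counts_match_hypergeometric_mean(self):
        counts = pd.DataFrame([[600, 300, 100]])
        reps = np.array([
            rarefy(counts, depth=100, seed=s).iloc[0].to_numpy() for s in range(1000)
        ])
        assert np.abs(reps.mean(axis=0) - [60, 30, 10]).max() < 1.5

    def test_invalid_depth_rejected(self, small_counts):
        with pytest.raises(ValueError):
            rarefy(small_counts, depth=0, seed=0)


class TestRescaleToCounts:
    def test_rows_sum_exactly_and_proportions_preserved(self):
        rel = pd.DataFrame([[0.333333, 0.333333, 0.333334], [0.5, 0.2, 0.3]])
        out = rescale_to_counts(rel, pseudo_total=10000)
        assert (out.sum(axis=1) == 10000).all()
        assert np.abs(out.to_numpy() / 10000 - rel.to_numpy()).max() < 1e-4


class TestAlphaDiversity:
    def test_closed_forms(self):
        counts = pd.DataFrame(
            [[25, 25, 25, 25], [100, 0, 0, 0], [50, 25, 25, 0]],
            columns=list("wxyz"),
        )
        div = alpha_diversity(counts)
        assert div.richness.tolist() == [4, 1, 3]
        assert div.shannon.iloc[0] == pytest.approx(np.log(4), rel=1e-12)
        assert div.shannon.iloc[1] == pytest.approx(0.0, abs=1e-12)
        assert div.shannon.iloc[2] == pytest.approx(1.5 * np.log(2), rel=1e-12)
        assert div.inv_simpson.tolist() == pytest.approx([4.0, 1.0, 8 / 3], rel=1e-12)

    def test_all_zero_row_rejected(self):
        with pytest.raises(ValueError):
            alpha_diversity(pd.DataFrame([[0, 0]]))


class TestBrayCurtis:
    def test_hand_example_and_extremes(self):
        counts = pd.DataFrame([[6, 2], [2, 6], [6, 2], [0, 8]])
        D = bray_curtis(counts).to_numpy()
        assert D[0, 1] == pytest.approx(0.5)
        assert D[0, 2] == pytest.approx(0.0)
        # disjoint supports
        D2 = bray_curtis(pd.DataFrame([[5, 0], [0, 7]])).to_numpy()
        assert D2[0, 1] == pytest.approx(1.0)

    @given(arrays(np.float64, (5, 4), elements=st.floats(0, 100)))
    def test_symmetry_identity_range(self, X):
        X = X + 1e-6  # avoid all-zero rows
        D = bray_curtis(pd.DataFrame(X)).to_numpy()
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)
        assert np.all((D >= -1e-12) & (D <= 1 + 1e-12))


class TestPermanova:
    def test_matches_skbio_pseudo_f(self):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as sk_permanova

        rng = np.random.default_rng(1)
        X = np.abs(rng.normal(size=(18, 5)))
        labels = ["a"] * 9 + ["b"] * 5 + ["c"] * 4
        D = bray_curtis(pd.DataFrame(X)).to_numpy()
        f, _ = permanova(D, labels, n_perm=99, seed=0)
        ref = sk_permanova(DistanceMatrix(D), grouping=labels, permutations=9)
        assert f == pytest.approx(float(ref["test statistic"]), rel=1e-10)

    def test_complete_separation_minimum_p(self):
        rng = np.random.default_rng(2)
        X = np.abs(rng.normal(size=(16, 3)))
        X[:8] += 50.0
        D = bray_curtis(pd.DataFrame(X)).to_numpy()
        _, p = permanova(D, ["a"] * 8 + ["b"] * 8, n_perm=999, seed=0)
        assert p == pytest.approx(1 / 1000)

    def test_singleton_group_rejected(self):
        D = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(ValueError):
            permanova(D, ["a", "a", "a", "b"])
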