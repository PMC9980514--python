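"""Group statistics, BH-FDR, CLR, SparCC and network construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from milkgut import (
    bh_fdr,
    build_network,
    chi_squared,
    clr_transform,
    dunn_posthoc,
    kruskal_wallis,
    mann_whitney,
    simulate_correlated_counts,
    sparcc,
)


class TestKruskalWallis:
    def test_hand_computed_three_groups(self):
        # ranks 1..9 without ties: H = 12/(9*10) * sum n (rbar - 5)^2 = 7.2
        values = [1, 2, 3, 4, 5, 6, 7, 8, 9]
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        H, p = kruskal_wallis(values, groups)
        assert H == pytest.approx(7.2, abs=1e-12)
        assert p == pytest.approx(sps.chi2.sf(7.2, 2), rel=1e-10)
        assert p == pytest.approx(0.0273, abs=5e-4)

    def test_all_tied_degenerates_to_p_one(self):
        H, p = kruskal_wallis([5.0] * 6, ["a", "a", "b", "b", "c", "c"])
        assert (H, p) == (0.0, 1.0)

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=30)
        g = np.repeat(["a", "b", "c"], 10)
        assert kruskal_wallis(v, g) == pytest.approx(kruskal_wallis(np.exp(v), g))

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1, 2, 3], ["a", "a", "a"])


class TestMannWhitney:
    def test_exact_enumeration_no_overlap(self):
        # all 6 arrangements of ranks: P(U <= 0) * 2 = 2/6
        U, p = mann_whitney([1, 2], [3, 4])
        assert U == 0
        assert p == pytest.approx(1 / 3, rel=1e-12)

    def test_identical_multisets_p_one_exact(self):
        _, p = mann_whitney([1, 2, 3], [1, 2, 3])
        # ties force the asymptotic path; symmetric data gives p ~ 1
        assert p > 0.9

    def test_swap_symmetry(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=20), rng.normal(1, 1, size=15)
        assert mann_whitney(x, y)[1] == pytest.approx(mann_whitney(y, x)[1], rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


def _dunn_oracle(values, groups):
    """Independent re-derivation of Dunn's z statistics: manual average
    ranks, manual tie correction."""
    values = list(map(float, values))
    N = len(values)
    order = sorted(range(N), key=lambda i: values[i])
    ranks = [0.0] * N
    i = 0
    while i < N:
        j = i
        while j + 1 < N and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j + 2) / 2.0  # ranks are 1-based
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    tie_sum = 0.0
    for v in set(values):
        t = values.count(v)
        tie_sum += t**3 - t
    T = tie_sum / (12.0 * (N - 1))
    levels = list(dict.fromkeys(groups))
    out = {}
    for a_i in range(len(levels)):
        for b_i in range(a_i + 1, len(levels)):
            a, b = levels[a_i], levels[b_i]
            ra = np.mean([ranks[i] for i in range(N) if groups[i] == a])
            rb = np.mean([ranks[i] for i in range(N) if groups[i] == b])
            na = groups.count(a)
            nb = groups.count(b)
            se = np.sqrt((N * (N + 1) / 12.0 - T) * (1.0 / na + 1.0 / nb))
            z = (ra - rb) / se
            out[(a, b)] = (z, 2 * sps.norm.sf(abs(z)))
    return out


class TestDunn:
    def test_matches_independent_oracle_on_random_data(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(4, 10))
            values = list(rng.integers(0, 12, size=3 * n).astype(float))
            groups = list(np.repeat(["a", "b", "c"], n))
            res = dunn_posthoc(values, groups).set_index(["group_a", "group_b"])
            oracle = _dunn_oracle(values, groups)
            for pair, (z, p) in oracle.items():
                assert res.loc[pair, "z"] == pytest.approx(z, abs=1e-10)
                assert res.loc[pair, "p"] == pytest.approx(p, abs=1e-10)

    def test_identical_groups_give_z_zero(self):
        values = [1, 2, 3, 1, 2, 3, 7, 8, 9]
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = dunn_posthoc(values, groups).set_index(["group_a", "group_b"])
        assert res.loc[("a", "b"), "z"] == pytest.approx(0.0, abs=1e-12)
        assert res.loc[("a", "b"), "p"] == pytest.approx(1.0)

    def test_two_groups_deferred(self):
        with pytest.raises(ValueError):
            dunn_posthoc([1, 2, 3, 4], ["a", "a", "b", "b"])


class TestBHFDR:
    def test_step_up_hand_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04], abs=1e-15)

    def test_single_and_all_ones(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_matches_statsmodels_and_brute_force(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        for _ in range(100):
            p = rng.uniform(size=int(rng.integers(1, 30)))
            q = bh_fdr(p)
            q_sm = multipletests(p, method="fdr_bh")[1]
            assert q == pytest.approx(q_sm, abs=1e-10)
            # brute-force definition q_i = min over j with p_j >= p_i of p_j*m/rank_j
            m = len(p)
            order = np.argsort(p)
            for i in range(m):
                rank_i = int(np.where(order == i)[0][0]) + 1
                cands = [
                    p[order[j]] * m / (j + 1)
                    for j in range(rank_i - 1, m)
                ]
                assert q[i] == pytest.approx(min(min(cands), 1.0), abs=1e-10)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=25))
    def test_q_at_least_p_and_permutation_equivariant(self, p):
        p = np.asarray(p)
        q = bh_fdr(p)
        assert np.all(q >= p - 1e-15)
        assert np.all(q <= 1.0)
        perm = np.random.default_rng(0).permutation(len(p))
        assert bh_fdr(p[perm]) == pytest.approx(q[perm], abs=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestChiSquared:
    def test_independent_table(self):
        x2, p = chi_squared([[10, 10], [10, 10]])
        assert x2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_perfect_association(self):
        x2, p = chi_squared([[20, 0], [0, 20]])
        assert x2 == pytest.approx(40.0)
        assert p == pytest.approx(sps.chi2.sf(40, 1), rel=1e-10)

    def test_row_column_swap_invariance(self):
        t = np.array([[12, 5, 9], [3, 14, 6]])
        assert chi_squared(t)[0] == pytest.approx(chi_squared(t.T)[0])
        assert chi_squared(t)[0] == pytest.approx(chi_squared(t[::-1])[0])

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_squared([[0, 0], [5, 5]])


class TestCLR:
    def test_uniform_composition_maps_to_zero(self):
        out = clr_transform(pd.DataFrame([[10, 10, 10, 10]]), pseudocount=0.5)
        assert np.allclose(out, 0.0)

    def test_rows_sum_to_zero(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.integers(0, 100, size=(10, 8)))
        assert np.allclose(clr_transform(X).sum(axis=1), 0.0, atol=1e-12)

    def test_asymptotic_scale_invariance(self):
        x = pd.DataFrame([[1000.0, 2000.0, 4000.0]])
        diff = clr_transform(10 * x).to_numpy() - clr_transform(x).to_numpy()
        assert np.abs(diff).max() < 1e-3


class TestSparCC:
    def test_symmetric_unit_diagonal_bounded(self):
        X = simulate_correlated_counts(50, pd.DataFrame(np.eye(6)), depth=5000, seed=0)
        r = sparcc(X).to_numpy()
        assert np.allclose(r, r.T)
        assert np.allclose(np.diag(r), 1.0)
        assert np.all(np.abs(r) <= 1.0)

    def test_planted_pair_recovered(self):
        C = np.eye(12)
        C[2, 5] = C[5, 2] = 0.8
        X = simulate_correlated_counts(300, pd.DataFrame(C), depth=50000, seed=0)
        r = sparcc(X)
        assert abs(r.iloc[2, 5] - 0.8) < 0.15

    def test_null_estimates_track_basis_oracle(self):
        # independent taxa: estimates should stay inside a high-probability
        # envelope for the max of 66 correlation estimates at n=300
        # (sd ~ 1/sqrt(n); 0.30 ~ 5 sd)
        X = simulate_correlated_counts(300, pd.DataFrame(np.eye(12)), depth=50000, seed=1)
        r = sparcc(X).to_numpy()
        off = r[~np.eye(12, dtype=bool)]
        assert np.abs(off).max() < 0.30

    def test_too_few_taxa_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).integers(1, 50, size=(20, 3)))
        with pytest.raises(ValueError):
            sparcc(X)


class TestNetwork:
    def test_planted_edge_found_and_thresholds_respected(self):
        names = [f"sp{i:02d}" for i in range(20)]
        C = pd.DataFrame(np.eye(20), index=names, columns=names)
        C.iloc[0, 1] = C.iloc[1, 0] = 0.8
        X = simulate_correlated_counts(300, C, depth=50000, seed=2)
        net = build_network(X, top_n=20, prevalence_min=0.25, corr_threshold=0.2)
        pairs = set(map(tuple, net.edges[["taxon_a", "taxon_b"]].to_numpy()))
        assert tuple(sorted((names[0], names[1]))) in pairs
        assert (net.edges["correlation"].abs() >= 0.2).all()
        assert (net.edges["taxon_a"] < net.edges["taxon_b"]).all()

    def test_threshold_one_empty_edges(self):
        X = simulate_correlated_counts(50, pd.DataFrame(np.eye(8)), depth=5000, seed=3)
        net = build_network(X, top_n=8, corr_threshold=1.0)
        assert net.edges.empty

    def test_prevalence_filter_excludes_rare_taxon(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.integers(10, 100, size=(40, 8)),
                         columns=[f"sp{i}" for i in range(8)])
        X["rare"] = 0
        X.loc[X.index[:4], "rare"] = 5  # 10% prevalence
        net = build_network(X, top_n=9, prevalence_min=0.25, corr_threshold=0.2)
        assert "rare" not in set(net.nodes["taxon"])
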