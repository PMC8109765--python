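import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from metabridge.corrnet import (
    differential_correlations,
    fisher_z_test,
    harmonize_pairs,
    significance_filter,
    spearman_matrix,
    spearman_rho_pvalue,
)


def brute_force_spearman_p(x, y):
    """Independent oracle: enumerate every pairing permutation directly."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    count = total = 0
    for perm in itertools.permutations(range(len(x))):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        if abs(r) >= obs - 1e-12:
            count += 1
        total += 1
    return count / total


def _tables(blood_values, csf_values, names=("m1", "m2")):
    n = len(next(iter(blood_values.values())))
    meta = {
        "sample_id": [f"s{i}" for i in range(n)],
        "sex": ["male"] * n,
        "genotype": ["WT"] * n,
        "age_point": ["early"] * n,
    }
    blood = pd.DataFrame({**meta, "fluid": ["blood"] * n, **blood_values})
    csf = pd.DataFrame({**meta, "fluid": ["csf"] * n, **csf_values})
    return blood, csf


class TestSpearmanPvalue:
    def test_perfect_antimonotone(self):
        rho, p = spearman_rho_pvalue(np.arange(1.0, 6.0), np.arange(5.0, 0.0, -1.0))
        assert rho == pytest.approx(-1.0)
        assert p == pytest.approx(2 / 120)

    def test_self_correlation(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0])
        rho, _ = spearman_rho_pvalue(x, x)
        assert rho == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_exact_p_matches_enumeration(self, n, rng):
        for _ in range(5):
            x, y = rng.normal(size=n), rng.normal(size=n)
            _, p = spearman_rho_pvalue(x, y)
            assert p == pytest.approx(brute_force_spearman_p(x, y), abs=1e-12)

    def test_exact_p_with_ties_matches_enumeration(self, rng):
        for _ in range(5):
            x = rng.integers(0, 3, size=6).astype(float)  # heavy ties
            y = rng.integers(0, 3, size=6).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            _, p = spearman_rho_pvalue(x, y)
            assert p == pytest.approx(brute_force_spearman_p(x, y), abs=1e-12)

    def test_large_n_uses_t_approximation(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        rho, p = spearman_rho_pvalue(x, y)
        t = rho * np.sqrt(28 / (1 - rho**2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), df=28), rel=1e-12)

    def test_zero_variance_warns(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            rho, p = spearman_rho_pvalue(np.ones(5), np.arange(5.0))
        assert (rho, p) == (0.0, 1.0)

    @given(st.integers(0, 2**32 - 1))
    def test_monotone_transform_invariance(self, seed):
        g = np.random.default_rng(seed)
        x, y = g.normal(size=8), g.normal(size=8)
        rho1, p1 = spearman_rho_pvalue(x, y)
        rho2, p2 = spearman_rho_pvalue(np.exp(x), y**3)  # strictly increasing maps
        assert rho1 == pytest.approx(rho2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)


class TestSpearmanMatrix:
    def test_matrix_entries_and_transpose_relation(self, rng):
        b = {"m1": rng.normal(size=6), "m2": rng.normal(size=6)}
        c = {"m1": rng.normal(size=6), "m2": rng.normal(size=6)}
        blood, csf = _tables(b, c)
        net = spearman_matrix(blood, csf)
        for i, bi in enumerate(["m1", "m2"]):
            for j, cj in enumerate(["m1", "m2"]):
                expect = stats.spearmanr(b[bi], c[cj]).statistic
                assert net.rho[i, j] == pytest.approx(expect, abs=1e-12)
        t = net.transpose()
        np.testing.assert_array_equal(t.rho, net.rho.T)
        np.testing.assert_array_equal(t.pvals, net.pvals.T)

    def test_unmatched_sample_ids_error(self, rng):
        blood, csf = _tables({"m1": rng.normal(size=5)}, {"m1": rng.normal(size=5)})
        csf.loc[0, "sample_id"] = "other"
        with pytest.raises(ValueError, match="unmatched sample ids"):
            spearman_matrix(blood, csf, shared=["m1"])

    def test_pairing_is_by_sample_id_not_row_order(self, rng):
        vals = rng.normal(size=6)
        blood, csf = _tables({"m1": vals}, {"m1": vals})
        shuffled = csf.sample(frac=1.0, random_state=0).reset_index(drop=True)
        net = spearman_matrix(blood, shuffled, shared=["m1"])
        assert net.rho[0, 0] == pytest.approx(1.0)

    def test_too_few_samples_error(self, rng):
        blood, csf = _tables({"m1": rng.normal(size=2)}, {"m1": rng.normal(size=2)})
        with pytest.raises(ValueError, match="at least 3"):
            spearman_matrix(blood, csf, shared=["m1"])


class TestSignificanceFilter:
    def test_all_insignificant_gives_zero_adjacency(self, rng):
        blood, csf = _tables({"m1": rng.normal(size=5)}, {"m1": rng.normal(size=5)})
        net = spearman_matrix(blood, csf)
        net = significance_filter(net, alpha=1e-6)
        np.testing.assert_array_equal(net.A, 0.0)

    def test_exact_small_p_pair_retained(self):
        x = np.arange(1.0, 6.0)
        blood, csf = _tables({"m1": x}, {"m1": x})
        net = significance_filter(spearman_matrix(blood, csf), alpha=0.05)
        # perfectly monotone pair at n=5: exact p = 2/120 < 0.05
        assert net.A[0, 0] == pytest.approx(1.0)

    def test_alpha_one_keeps_everything(self, rng):
        blood, csf = _tables({"m1": rng.normal(size=5)}, {"m1": rng.normal(size=5)})
        net = significance_filter(spearman_matrix(blood, csf), alpha=1.0)
        np.testing.assert_array_equal(net.A, net.rho)


class TestHarmonizePairs:
    def _nets(self, rng, strength=0.0):
        x = np.arange(1.0, 7.0)
        blood_wt, csf_wt = _tables({"m1": x, "m2": rng.normal(size=6)},
                                   {"m1": x, "m2": rng.normal(size=6)})
        blood_app, csf_app = _tables({"m1": rng.normal(size=6), "m2": rng.normal(size=6)},
                                     {"m1": rng.normal(size=6), "m2": rng.normal(size=6)})
        wt = significance_filter(spearman_matrix(blood_wt, csf_wt), 0.05)
        app = significance_filter(spearman_matrix(blood_app, csf_app), 0.05)
        return wt, app

    def test_union_rule_and_carryover(self, rng):
        wt, app = self._nets(rng)
        pairs_wt, pairs_app = harmonize_pairs(wt, app)
        assert list(pairs_wt["blood"]) == list(pairs_app["blood"])
        assert list(pairs_wt["csf"]) == list(pairs_app["csf"])
        # the perfectly monotone WT pair is significant only in WT, yet the
        # APP list carries APP's raw rho for it
        row = pairs_wt[(pairs_wt.blood == "m1") & (pairs_wt.csf == "m1")]
        assert len(row) == 1
        assert row["rho"].iloc[0] == pytest.approx(1.0)
        app_row = pairs_app[(pairs_app.blood == "m1") & (pairs_app.csf == "m1")]
        assert app_row["rho"].iloc[0] == pytest.approx(app.rho[0, 0])

    def test_nothing_significant_gives_empty_lists(self, rng):
        b1, c1 = _tables({"m1": rng.normal(size=5)}, {"m1": rng.normal(size=5)})
        b2, c2 = _tables({"m1": rng.normal(size=5)}, {"m1": rng.normal(size=5)})
        n1 = significance_filter(spearman_matrix(b1, c1), alpha=1e-9)
        n2 = significance_filter(spearman_matrix(b2, c2), alpha=1e-9)
        pairs1, pairs2 = harmonize_pairs(n1, n2)
        assert pairs1.empty and pairs2.empty

    def test_name_mismatch_errors(self, rng):
        wt, app = self._nets(rng)
        app.blood_names = ["x", "y"]
        with pytest.raises(ValueError, match="name lists"):
            harmonize_pairs(wt, app)

    def test_unfiltered_networks_rejected(self, rng):
        b, c = _tables({"m1": rng.normal(size=5)}, {"m1": rng.normal(size=5)})
        net = spearman_matrix(b, c)
        with pytest.raises(ValueError, match="significance_filter"):
            harmonize_pairs(net, net)


class TestDifferentialCorrelations:
    def test_equal_correlations_not_significant(self):
        stat, p = fisher_z_test(0.5, 0.5, 10, 10)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_strongly_opposed_pair_detected(self):
        # r_APP = 0.89, r_WT = -0.43 at n = 10 per group
        stat, p = fisher_z_test(0.89, -0.43, 10, 10)
        assert stat == pytest.approx(3.52, abs=0.01)
        assert p == pytest.approx(4.3e-4, rel=0.02)

    def test_small_n_small_difference_not_significant(self):
        stat, _ = fisher_z_test(0.2, 0.1, 4, 4)
        assert abs(stat) < 1.96

    def test_minimum_group_size_enforced(self):
        with pytest.raises(ValueError, match=r"1/\(n-3\)"):
            fisher_z_test(0.2, 0.1, 3, 10)

    def test_perfect_correlation_clamped(self):
        with pytest.warns(UserWarning, match="clamped"):
            stat, p = fisher_z_test(1.0, 0.0, 10, 10)
        assert np.isfinite(stat) and 0 <= p <= 1

    def test_pair_table_output(self):
        pairs_a = pd.DataFrame({"blood": ["m1"], "csf": ["m2"], "rho": [0.89]})
        pairs_b = pd.DataFrame({"blood": ["m1"], "csf": ["m2"], "rho": [-0.43]})
        out = differential_correlations(pairs_a, pairs_b, 10, 10)
        assert out.loc[0, "significant"]
        assert out.loc[0, "z_stat"] == pytest.approx(3.5206, abs=1e-3)

    def test_mismatched_pair_lists_rejected(self):
        pairs_a = pd.DataFrame({"blood": ["m1"], "csf": ["m2"], "rho": [0.5]})
        pairs_b = pd.DataFrame({"blood": ["m2"], "csf": ["m1"], "rho": [0.5]})
        with pytest.raises(ValueError, match="pair lists differ"):
            differential_correlations(pairs_a, pairs_b, 10, 10)

    def test_empty_pair_lists_allowed(self):
        empty = pd.DataFrame(columns=["blood", "csf", "rho"])
        out = differential_correlations(empty, empty, 10, 10)
        assert out.empty
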