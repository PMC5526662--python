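"""Statistical core: z maps, cluster permutation (with a brute-force
oracle), correlations, Fisher-z tests, BH-FDR, paired tests."""

import numpy as np
import pytest
from scipy import ndimage
from scipy import stats as st

from stopgamma.stats import (
    Z_GUARD,
    bh_fdr,
    cluster_permutation,
    cluster_permutation_1d,
    fisherz_group_test,
    group_z_map,
    max_corr_search,
    paired_test,
    spearman_bootstrap,
)


class TestGroupZMap:
    def test_equal_conditions_give_zero(self):
        a = np.random.default_rng(0).standard_normal((4, 3, 5))
        t, z = group_z_map(a, a.copy())
        np.testing.assert_allclose(t, 0.0)
        np.testing.assert_allclose(z, 0.0)

    def test_hand_computed_t(self):
        # differences {1,2,3}: mean 2, SD 1, t = 2*sqrt(3)
        a = np.array([[1.0], [2.0], [3.0]])
        t, z = group_z_map(a, np.zeros_like(a))
        assert t[0] == pytest.approx(2 * np.sqrt(3))
        p = 2 * st.t.sf(2 * np.sqrt(3), 2)
        assert z[0] == pytest.approx(st.norm.isf(p / 2))

    def test_sign_flip_antisymmetry(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((5, 4))
        b = rng.standard_normal((5, 4))
        t1, z1 = group_z_map(a, b)
        t2, z2 = group_z_map(b, a)
        np.testing.assert_allclose(t1, -t2)
        np.testing.assert_allclose(z1, -z2)

    def test_zero_variance_guard(self):
        a = np.ones((3, 2))
        with pytest.warns(UserWarning):
            _, z = group_z_map(a, np.zeros_like(a))
        np.testing.assert_allclose(np.abs(z), Z_GUARD)


def _brute_force_cluster_masses(diffs, thr_p=0.05):
    """Independent oracle: observed suprathreshold cluster masses via a
    direct scipy.stats t-test per pixel and 4-connected labeling."""
    n = diffs.shape[0]
    t = st.ttest_1samp(diffs, 0.0, axis=0)
    z = st.norm.isf(np.clip(t.pvalue / 2, 1e-300, 1)) * np.sign(t.statistic)
    z_thr = st.norm.isf(thr_p / 2)
    struct = ndimage.generate_binary_structure(z.ndim, 1)
    masses = []
    for sign in (1, -1):
        lab, nlab = ndimage.label(sign * z > z_thr, structure=struct)
        for k in range(1, nlab + 1):
            masses.append(z[lab == k].sum())
    return sorted(masses)


class TestClusterPermutation:
    def test_all_zero_differences_empty(self):
        res = cluster_permutation(np.zeros((4, 6, 6)), n_perm=200, seed=0)
        assert res.clusters == []
        assert not res.sig_mask.any()

    def test_observed_masses_match_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        diffs = rng.standard_normal((8, 10, 12)) + 0.6
        res = cluster_permutation(diffs, n_perm=200, seed=1)
        got = sorted(c.mass for c in res.clusters)
        expected = _brute_force_cluster_masses(diffs)
        np.testing.assert_allclose(got, expected, rtol=1e-8)

    def test_injected_block_effect_detected(self):
        # Cohen's d = 2 over a 5x10 block
        rng = np.random.default_rng(3)
        diffs = rng.standard_normal((9, 20, 30))
        diffs[:, 5:10, 10:20] += 2.0
        res = cluster_permutation(diffs, n_perm=500, seed=2)
        sig = res.significant()
        assert sig
        block = np.zeros((20, 30), bool)
        block[5:10, 10:20] = True
        assert any(c.sign == 1 and (c.mask & block).any() for c in sig)

    def test_relabel_invariance_up_to_sign(self):
        rng = np.random.default_rng(4)
        diffs = rng.standard_normal((6, 8, 8)) + 0.4
        r1 = cluster_permutation(diffs, n_perm=300, seed=5)
        r2 = cluster_permutation(-diffs, n_perm=300, seed=5)
        m1 = sorted(round(c.mass, 9) for c in r1.clusters)
        m2 = sorted(round(-c.mass, 9) for c in r2.clusters)
        assert m1 == m2
        np.testing.assert_allclose(r1.null_max_mass, r2.null_max_mass)

    def test_p_lower_bound_and_seed_determinism(self):
        rng = np.random.default_rng(5)
        diffs = rng.standard_normal((7, 6, 6)) + 1.5
        r1 = cluster_permutation(diffs, n_perm=300, seed=9)
        r2 = cluster_permutation(diffs, n_perm=300, seed=9)
        for c1, c2 in zip(r1.clusters, r2.clusters):
            assert c1.p_perm == c2.p_perm
            assert c1.p_perm >= 1.0 / 301.0
        np.testing.assert_array_equal(r1.null_max_mass, r2.null_max_mass)

    def test_1d_step_effect(self):
        rng = np.random.default_rng(6)
        diffs = rng.standard_normal((9, 40)) * 0.5
        diffs[:, 20:] += 1.5
        res = cluster_permutation_1d(diffs, n_perm=300, seed=3)
        sig = res.significant()
        assert len(sig) >= 1
        top = max(sig, key=lambda c: abs(c.mass))
        start, stop = top.bbox()[0]
        assert start >= 15 and stop == 40  # cluster spans the step region

    def test_null_p_values_roughly_uniform(self):
        # smallest cluster p over null data should not be systematically tiny
        rng = np.random.default_rng(7)
        n_sig = 0
        for _ in range(40):
            diffs = rng.standard_normal((8, 10, 10))
            res = cluster_permutation(diffs, n_perm=200,
                                      seed=int(rng.integers(2**31)))
            n_sig += bool(res.significant())
        # family-wise error ~ alpha: expect ~2 of 40, allow wide slack
        assert n_sig <= 8


class TestSpearmanBootstrap:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        rho, (lo, hi) = spearman_bootstrap(x, x**3, n_boot=200, seed=0)
        assert rho == pytest.approx(1.0) and lo == pytest.approx(1.0) \
            and hi == pytest.approx(1.0)
        rho_neg, _ = spearman_bootstrap(x, -x, n_boot=50, seed=0)
        assert rho_neg == pytest.approx(-1.0)

    def test_constant_input_undefined(self):
        rho, ci = spearman_bootstrap(np.ones(10), np.arange(10.0), n_boot=50, seed=0)
        assert np.isnan(rho) and np.isnan(ci[0])

    def test_seed_determinism(self):
        rng = np.random.default_rng(8)
        x, y = rng.standard_normal((2, 30))
        assert spearman_bootstrap(x, y, 300, seed=4) == spearman_bootstrap(x, y, 300, seed=4)


class TestFisherZ:
    def test_zero_rhos(self):
        t, p, ci = fisherz_group_test([0.0, 0.0, 0.0, 0.0])
        assert t == 0.0 and p == 1.0

    def test_symmetric_rhos_cancel(self):
        t, p, _ = fisherz_group_test([0.5, -0.5, 0.3, -0.3])
        assert t == pytest.approx(0.0, abs=1e-12)

    def test_atanh_value(self):
        assert np.arctanh(0.5) == pytest.approx(0.5493, abs=1e-4)
        t, p, ci = fisherz_group_test([0.5, 0.5, 0.5, 0.5, 0.5])
        # all z identical -> degenerate zero-variance case
        assert np.isinf(t) and p == 0.0

    def test_unit_rho_excluded(self):
        with pytest.warns(UserWarning):
            t, p, _ = fisherz_group_test([1.0, 0.2, 0.3])


class TestBHFDR:
    def test_reference_seven_pvalues(self):
        # worked example: step-up adjustment of a seven-test family
        p = [0.020, 0.174, 0.460, 0.061, 0.377, 0.952, 0.810]
        adj = bh_fdr(p)
        np.testing.assert_allclose(
            adj, [0.140, 0.406, 0.644, 0.2135, 0.644, 0.952, 0.945], atol=5e-4)

    def test_monotone_and_dominates_raw(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=25)
        adj = bh_fdr(p)
        assert np.all(adj >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_single_and_equal_inputs(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)
        np.testing.assert_allclose(bh_fdr([0.5, 0.5, 0.5]), 0.5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestMaxCorrSearch:
    def _epochs(self, rng, n_trials=40):
        freqs = np.arange(60.0, 92.0, 2.0)
        times = np.arange(-0.1, 0.2, 0.005)
        ep = rng.standard_normal((n_trials, len(freqs), len(times)))
        return ep, freqs, times

    def test_injected_negative_coupling_found(self):
        rng = np.random.default_rng(10)
        ep, freqs, times = self._epochs(rng)
        extent = rng.uniform(0, 100, 40)
        fi = np.argmin(np.abs(freqs - 70.0))
        ti = np.argmin(np.abs(times - 0.1))
        ep[:, fi, ti] = -0.05 * extent + 0.5 * rng.standard_normal(40)
        rho, fhz, tsec, ci = max_corr_search(ep, freqs, times, extent)
        assert rho < -0.5
        assert abs(fhz - 70.0) <= 4.0 and abs(tsec - 0.1) <= 0.01

    def test_constant_extent_missing(self):
        rng = np.random.default_rng(11)
        ep, freqs, times = self._epochs(rng, 10)
        rho, *_ = max_corr_search(ep, freqs, times, np.full(10, 50.0))
        assert np.isnan(rho)

    def test_single_pixel_window(self):
        rng = np.random.default_rng(12)
        ep, freqs, times = self._epochs(rng, 12)
        extent = rng.uniform(0, 100, 12)
        rho, fhz, tsec, _ = max_corr_search(ep, freqs, times, extent,
                                            band=(70, 70), window=(0.1, 0.105))
        expected = st.spearmanr(extent, ep[:, np.argmin(np.abs(freqs - 70)),
                                           np.argmin(np.abs(times - 0.1))]).statistic
        assert rho == pytest.approx(expected)


class TestPairedTest:
    def test_equal_samples_degenerate(self):
        a = np.arange(8.0)
        stat, p, used = paired_test(a, a.copy())
        assert p == 1.0 and used == "degenerate"

    def test_skewed_differences_take_wilcoxon_branch(self):
        rng = np.random.default_rng(13)
        b = rng.standard_normal(40)
        a = b + rng.exponential(1.0, 40) ** 3  # heavily skewed differences
        _, _, used = paired_test(a, b)
        assert used == "wilcoxon"

    def test_normal_shift_takes_t_branch_and_detects(self):
        rng = np.random.default_rng(14)
        hits, t_used = 0, 0
        for _ in range(20):
            b = rng.standard_normal(9)
            a = b + 2.0 + 1.0 * rng.standard_normal(9)  # d ~ 2
            stat, p, used = paired_test(a, b)
            t_used += used == "ttest"
            hits += (p < 0.05) and (used in ("ttest", "wilcoxon"))
        assert t_used >= 15  # normality rarely rejected for normal data
        assert hits >= 18  # power at d=2, n=9
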