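import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vbm_motormap.voxelstats import (
    GMVolumeStack,
    MaskVolume,
    bonferroni_threshold,
    build_analysis_mask,
    fisher_z,
    fit_voxelwise_glm,
    fwe_maxT,
    r_to_t,
    small_volume_correction,
    voxelwise_pearson,
)


def flat_stack(Y, ids=None):
    """Wrap an (n, V) matrix as a stack of V voxels on a (V,1,1) grid."""
    n, V = Y.shape
    data = Y.reshape(n, V, 1, 1)
    return GMVolumeStack(data=data, affine=np.eye(4),
                         subject_ids=ids or [f"s{i}" for i in range(n)])


def full_mask(stack):
    return MaskVolume(np.ones(stack.shape, dtype=bool), "all voxels")


class TestAnalysisMask:
    def test_all_zero_stack_errors(self):
        stack = flat_stack(np.zeros((4, 5)))
        with pytest.raises(ValueError, match="empty"):
            build_analysis_mask(stack, 0.0)

    def test_constant_stack_has_no_testable_voxels(self):
        stack = flat_stack(np.full((4, 5), 2.0))
        with pytest.raises(ValueError, match="empty"):
            build_analysis_mask(stack, 0.1)

    def test_recovers_planted_foreground(self):
        rng = np.random.default_rng(0)
        Y = np.zeros((6, 10))
        fg = [1, 3, 4, 8]
        Y[:, fg] = 1.0 + rng.random((6, len(fg)))
        mask = build_analysis_mask(flat_stack(Y), min_mean_intensity=0.5)
        assert mask.n_voxels == len(fg)
        assert sorted(np.flatnonzero(mask.data[:, 0, 0])) == fg


class TestPearson:
    def test_matches_hand_expanded_covariance_formula(self):
        # 5-subject toy voxel, r from the raw sum formulation
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        y = np.array([2.0, 7.0, 1.0, 8.0, 2.0])
        n = 5
        num = n * (x * y).sum() - x.sum() * y.sum()
        den = math.sqrt(n * (x**2).sum() - x.sum() ** 2) * math.sqrt(
            n * (y**2).sum() - y.sum() ** 2
        )
        expected_r = num / den
        stack = flat_stack(y.reshape(5, 1))
        stat = voxelwise_pearson(stack, x, full_mask(stack), tail="two")
        assert stat.r[0, 0, 0] == pytest.approx(expected_r, abs=1e-12)
        assert stat.df == 3

    def test_perfect_correlation_clamps_t(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        stack = flat_stack(x.reshape(4, 1))
        with pytest.warns(RuntimeWarning, match="clamped"):
            stat = voxelwise_pearson(stack, x, full_mask(stack), tail="one_pos")
        assert stat.r[0, 0, 0] == pytest.approx(1.0)
        assert stat.p[0, 0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_null_voxels_rarely_cross_critical_r(self):
        # independent voxels at n = 364 stay under |r| = 0.1028 ~95% of the time
        rng = np.random.default_rng(7)
        Y = rng.random((364, 2000))
        x = rng.normal(size=364)
        stat = voxelwise_pearson(flat_stack(Y), x, full_mask(flat_stack(Y)), tail="two")
        frac = (np.abs(stat.r[:, 0, 0]) < 0.1028).mean()
        assert 0.93 < frac < 0.97

    def test_nan_outside_mask_and_sign_consistency(self):
        rng = np.random.default_rng(1)
        Y = rng.random((8, 6))
        stack = flat_stack(Y)
        mask = np.zeros(stack.shape, dtype=bool)
        mask[:4] = True
        stat = voxelwise_pearson(stack, rng.normal(size=8), MaskVolume(mask), tail="two")
        assert np.isnan(stat.r[~mask]).all()
        inside = np.isfinite(stat.r)
        assert np.all(np.sign(stat.t[inside]) == np.sign(stat.r[inside]))
        assert np.all((stat.p[inside] >= 0) & (stat.p[inside] <= 1))

    def test_rank_order_identical_across_r_z_t(self):
        rng = np.random.default_rng(2)
        Y = rng.random((10, 30))
        stack = flat_stack(Y)
        stat = voxelwise_pearson(stack, rng.normal(size=10), full_mask(stack), tail="two")
        r, z, t = (v[np.isfinite(v)] for v in (stat.r, stat.z, stat.t))
        np.testing.assert_array_equal(np.argsort(r), np.argsort(z))
        np.testing.assert_array_equal(np.argsort(r), np.argsort(t))

    def test_zero_variance_score_rejected(self):
        stack = flat_stack(np.random.default_rng(0).random((5, 3)))
        with pytest.raises(ValueError, match="variance"):
            voxelwise_pearson(stack, np.ones(5), full_mask(stack))

    def test_invariant_to_joint_subject_reordering_and_gain(self):
        rng = np.random.default_rng(3)
        Y = rng.random((12, 20)) + 0.5
        x = rng.normal(size=12)
        stack = flat_stack(Y)
        stat = voxelwise_pearson(stack, x, full_mask(stack), tail="two")
        perm = rng.permutation(12)
        stat_p = voxelwise_pearson(flat_stack(Y[perm]), x[perm], full_mask(stack), tail="two")
        np.testing.assert_allclose(stat.r, stat_p.r, atol=1e-12)
        stat_g = voxelwise_pearson(flat_stack(3.7 * Y), x, full_mask(stack), tail="two")
        np.testing.assert_allclose(stat.t, stat_g.t, atol=1e-9)


class TestRtoT:
    def test_zero_maps_to_zero(self):
        assert r_to_t(0.0, 10) == 0.0

    def test_critical_r_maps_to_critical_t(self):
        t = r_to_t(0.1028, 362)
        assert t == pytest.approx(stats.t.isf(0.025, 362), abs=2e-3)

    def test_closed_form_oracle(self):
        r, df = -0.5, 8
        assert r_to_t(r, df) == pytest.approx(r * math.sqrt(df / (1 - r * r)), abs=1e-14)

    def test_clamped_at_unit_r(self):
        with pytest.warns(RuntimeWarning):
            assert r_to_t(1.0, 5) == 1e6

    def test_monotone_in_r(self):
        rs = np.linspace(-0.99, 0.99, 41)
        ts = r_to_t(rs, 20)
        assert np.all(np.diff(ts) > 0)
        zs = fisher_z(rs)
        assert np.all(np.diff(zs) > 0)


class TestGLM:
    def test_noiseless_slope_recovered_exactly(self):
        rng = np.random.default_rng(4)
        n = 12
        updrs = rng.normal(20, 8, n)
        age = rng.normal(60, 9, n)
        sex = rng.integers(0, 2, n).astype(float)
        y = 2.0 + 3.0 * updrs
        stack = flat_stack((y - y.min() + 1).reshape(n, 1))
        covs = pd.DataFrame({"UPDRS3": updrs, "Age": age, "Sex": sex})
        res = fit_voxelwise_glm(stack, covs, full_mask(stack))
        assert res.coef["UPDRS3"][0, 0, 0] == pytest.approx(3.0, abs=1e-9)
        assert res.residual_df == n - 4

    def test_score_only_design_reproduces_pearson_t(self):
        rng = np.random.default_rng(5)
        Y = rng.random((15, 40)) + 0.1
        x = rng.normal(size=15)
        stack = flat_stack(Y)
        mask = full_mask(stack)
        stat = voxelwise_pearson(stack, x, mask, tail="two")
        res = fit_voxelwise_glm(stack, pd.DataFrame({"UPDRS3": x}), mask)
        assert res.residual_df == stat.df
        np.testing.assert_allclose(res.t_coef["UPDRS3"], stat.t, atol=1e-10)

    def test_rank_deficient_design_names_columns(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=10)
        stack = flat_stack(rng.random((10, 3)))
        covs = pd.DataFrame({"UPDRS3": x, "Age": 2 * x})
        with pytest.raises(ValueError, match="UPDRS3~Age"):
            fit_voxelwise_glm(stack, covs, full_mask(stack))


def brute_force_tmap(Y, xp):
    """Per-voxel Pearson t for one score labelling (oracle arithmetic)."""
    n, V = Y.shape
    df = n - 2
    ts = []
    for v in range(V):
        r = np.corrcoef(xp, Y[:, v])[0, 1]
        ts.append(r * math.sqrt(df / (1 - r * r)))
    return np.array(ts)


def brute_force_maxT(Y, x, alpha, tail, exhaustive_perms):
    """Independent enumeration oracle: per-permutation extreme Pearson t."""
    out = []
    for perm in exhaustive_perms:
        ts = brute_force_tmap(Y, x[list(perm)])
        out.append(ts.min() if tail == "one_neg" else
                   (ts.max() if tail == "one_pos" else np.abs(ts).max()))
    return np.array(out)


class TestPermutationFWE:
    def test_exhaustive_enumeration_matches_brute_force(self):
        # 6 subjects, 3 voxels: all 720 permutations, oracle vs pipeline
        rng = np.random.default_rng(8)
        Y = rng.random((6, 3)) + 0.2
        x = rng.normal(size=6)
        stack = flat_stack(Y)
        mask = full_mask(stack)
        with pytest.warns(RuntimeWarning, match="enumerating"):
            null = fwe_maxT(stack, pd.DataFrame({"UPDRS3": x}), "pearson", mask,
                            alpha=0.05, n_perm=720, seed=0, tail="one_neg")
        assert null.exhaustive and null.n_perm == 720
        oracle = brute_force_maxT(Y, x, 0.05, "one_neg",
                                  itertools.permutations(range(6)))
        np.testing.assert_allclose(np.sort(null.max_stats), np.sort(oracle), atol=1e-9)
        thr_oracle = np.quantile(oracle, 0.05, method="lower")
        assert null.threshold == pytest.approx(thr_oracle, abs=1e-9)
        # corrected p: add-one count of permutation minima at or below the
        # oracle's own observed t (self-consistent tie handling)
        t_obs = brute_force_tmap(Y, x)
        p_oracle = (1 + (oracle[:, None] <= t_obs[None, :]).sum(axis=0)) / (720 + 1)
        np.testing.assert_allclose(null.corrected_p[mask.data], p_oracle, atol=1e-12)

    def test_single_voxel_equals_univariate_permutation_p(self):
        rng = np.random.default_rng(9)
        Y = rng.random((10, 1)) + 0.2
        x = rng.normal(size=10)
        stack = flat_stack(Y)
        null = fwe_maxT(stack, pd.DataFrame({"UPDRS3": x}), "pearson", full_mask(stack),
                        alpha=0.05, n_perm=300, seed=5, tail="one_neg")
        # univariate oracle replaying the same seeded permutation stream
        r_obs = np.corrcoef(x, Y[:, 0])[0, 1]
        t_obs = r_obs * math.sqrt(8 / (1 - r_obs**2))
        gen = np.random.default_rng(5)
        count = 0
        for _ in range(300):
            xp = x[gen.permutation(10)]
            r = np.corrcoef(xp, Y[:, 0])[0, 1]
            if r * math.sqrt(8 / (1 - r * r)) <= t_obs + 1e-12:
                count += 1
        assert null.corrected_p[0, 0, 0] == pytest.approx((1 + count) / 301, abs=1e-12)

    def test_glm_b_observed_stat_matches_glm_fit(self):
        rng = np.random.default_rng(10)
        n = 20
        Y = rng.random((n, 15)) + 0.2
        covs = pd.DataFrame({"UPDRS3": rng.normal(20, 8, n),
                             "Age": rng.normal(60, 9, n),
                             "Sex": rng.integers(0, 2, n).astype(float)})
        stack = flat_stack(Y)
        mask = full_mask(stack)
        null = fwe_maxT(stack, covs, "glm_b", mask, alpha=0.05, n_perm=100,
                        seed=1, tail="two")
        res = fit_voxelwise_glm(stack, covs, mask)
        np.testing.assert_allclose(null.observed_t, res.t_coef["UPDRS3"], atol=1e-9)
        null_c = fwe_maxT(stack, covs, "glm_c", mask, alpha=0.05, n_perm=100,
                          seed=1, tail="two")
        np.testing.assert_allclose(null_c.observed_t, res.t_coef["Age"], atol=1e-9)

    def test_svc_equals_whole_mask_when_masks_coincide(self):
        rng = np.random.default_rng(11)
        Y = rng.random((12, 25)) + 0.2
        x = rng.normal(size=12)
        stack = flat_stack(Y)
        mask = full_mask(stack)
        d = pd.DataFrame({"UPDRS3": x})
        a = fwe_maxT(stack, d, "pearson", mask, alpha=0.05, n_perm=200, seed=3,
                     tail="one_neg")
        b = small_volume_correction(stack, d, "pearson", mask, mask, alpha=0.05,
                                    n_perm=200, seed=3, tail="one_neg")
        assert a.threshold == b.threshold
        np.testing.assert_allclose(a.max_stats, b.max_stats)

    def test_svc_disjoint_mask_errors(self):
        rng = np.random.default_rng(12)
        stack = flat_stack(rng.random((6, 10)) + 0.2)
        m1 = np.zeros(stack.shape, bool); m1[:5] = True
        m2 = np.zeros(stack.shape, bool); m2[5:] = True
        with pytest.raises(ValueError, match="disjoint"):
            small_volume_correction(stack, pd.DataFrame({"UPDRS3": np.arange(6.0)}),
                                    "pearson", MaskVolume(m1), MaskVolume(m2),
                                    n_perm=100)

    def test_maxT_no_more_conservative_than_bonferroni(self):
        # independent voxels: the maxT threshold should not exceed Bonferroni
        rng = np.random.default_rng(13)
        n, V = 30, 50
        Y = rng.random((n, V)) + 0.2
        x = rng.normal(size=n)
        stack = flat_stack(Y)
        null = fwe_maxT(stack, pd.DataFrame({"UPDRS3": x}), "pearson",
                        full_mask(stack), alpha=0.05, n_perm=1000, seed=4,
                        tail="one_neg")
        bonf = bonferroni_threshold(0.05, V, n - 2, "one_neg")
        assert null.threshold >= bonf - 0.3  # MC slack


class TestBonferroni:
    def test_single_voxel_is_uncorrected_critical_t(self):
        assert bonferroni_threshold(0.05, 1, 30, "one_pos") == pytest.approx(
            stats.t.isf(0.05, 30))

    def test_threshold_grows_with_n_voxels(self):
        vals = [abs(bonferroni_threshold(0.05, v, 30, "one_neg")) for v in (1, 10, 100, 1000)]
        assert all(a < b for a, b in zip(vals, vals[1:]))
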