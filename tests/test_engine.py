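"""Permutation plans, corrected thresholds/p-values, parametric comparisons."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import permfmri as pf
from permfmri.engine import (
    FweCalibrationConfig,
    MaxNullDistribution,
    PermutationConfig,
    ThresholdVariabilityConfig,
    _Pipeline,
    _t_ec_densities,
    bonferroni_threshold,
    corrected_pvalue,
    count_permutations,
    expected_euler_characteristic,
    fwe_calibration,
    make_plan,
    relative_sd_pvalue,
    rft_threshold,
    run_permutation_test,
    threshold_variability,
)
from permfmri.exceptions import DomainError


pytestmark = pytest.mark.filterwarnings(
    "ignore:accumulated whitening operator truncated"
)


def _white_dataset(shape, nt, seed):
    rng = np.random.default_rng(seed)
    return pf.FmriDataset(
        data=rng.standard_normal(shape + (nt,)),
        mask=np.ones(shape, dtype=bool),
        tr=2.0,
        voxel_size=(3.75, 3.75, 3.75),
    )


class TestPlan:
    def test_every_row_is_a_bijection(self):
        plan = make_plan(nt=30, np_=50, seed=1)
        expected = np.arange(30)
        for row in plan.indices:
            assert np.array_equal(np.sort(row), expected)

    def test_same_seed_identical(self):
        a = make_plan(20, 40, seed=7).indices
        b = make_plan(20, 40, seed=7).indices
        assert np.array_equal(a, b)

    def test_different_seeds_differ(self):
        a = make_plan(20, 40, seed=7).indices
        b = make_plan(20, 40, seed=8).indices
        assert not np.array_equal(a, b)


class TestCountPermutations:
    def test_small_factorials(self):
        assert count_permutations(1) == 1
        assert count_permutations(5) == 120

    def test_80_samples_to_three_significant_digits(self):
        n = count_permutations(80)
        mantissa = n / 10 ** (len(str(n)) - 1)
        assert len(str(n)) - 1 == 118
        assert round(mantissa, 2) == 7.16


class TestCorrectedPvalue:
    def test_extremes(self):
        maxima = np.array([1.0, 2.0, 3.0, 4.0])
        assert corrected_pvalue(10.0, maxima) == 0.0
        assert corrected_pvalue(0.5, maxima) == 1.0

    def test_direct_count(self):
        assert corrected_pvalue(2.5, np.array([1.0, 2.0, 3.0, 4.0])) == 0.5

    def test_tie_counts_toward_numerator(self):
        assert corrected_pvalue(3.0, np.array([1.0, 2.0, 3.0, 4.0])) == 0.5

    @settings(derandomize=True, max_examples=30)
    @given(
        st.lists(
            st.floats(min_value=-50, max_value=50), min_size=3, max_size=40
        ),
        st.floats(min_value=-60, max_value=60),
    )
    def test_values_lie_on_the_permutation_grid(self, maxima, t):
        p = corrected_pvalue(t, np.array(maxima))
        np_ = len(maxima)
        assert 0.0 <= p <= 1.0
        assert (p * np_) == pytest.approx(round(p * np_), abs=1e-9)


class TestThresholdIndex:
    def test_position_9500_of_10000(self):
        rng = np.random.default_rng(0)
        maxima = rng.permutation(np.arange(1.0, 10001.0))
        null = MaxNullDistribution(maxima=maxima, statistic_label="GLM-t")
        # sorted ascending, 1-based position ceil(0.95 * 10000) = 9500
        assert null.threshold(0.05) == 9500.0

    def test_insufficient_permutations_warn(self):
        null = MaxNullDistribution(
            maxima=np.arange(10.0), statistic_label="GLM-t"
        )
        with pytest.warns(RuntimeWarning, match="fewer permutations"):
            null.threshold(0.05)


class TestBonferroni:
    def test_per_comparison_rate_for_20000_voxels(self):
        thr, rate = bonferroni_threshold(0.05, 20_000, df=78)
        assert rate == pytest.approx(0.05 / 20_000, rel=1e-12)
        assert thr == pytest.approx(sps.t.isf(2.5e-6, 78), abs=1e-10)

    def test_single_voxel_reduces_to_uncorrected(self):
        thr, rate = bonferroni_threshold(0.05, 1, df=78)
        assert rate == 0.05
        assert round(thr, 2) == 1.66


class TestRft:
    MASK = np.ones((12, 12, 8), dtype=bool)
    VOX = (3.75, 3.75, 3.75)

    def test_threshold_decreases_with_smoothness(self):
        thrs = [
            rft_threshold(0.05, self.MASK, f, self.VOX, df=78)
            for f in (6.0, 9.0, 14.0)
        ]
        assert thrs[0] >= thrs[1] >= thrs[2]

    def test_threshold_at_least_uncorrected_quantile(self):
        thr = rft_threshold(0.05, self.MASK, 8.0, self.VOX, df=78)
        assert thr >= sps.t.isf(0.05, 78)

    def test_expected_ec_matches_independent_formula(self):
        # independently re-derived: resel counts of a full n1 x n2 x n3 box
        # and the standard t-field EC densities
        df, fwhm = 78, 7.5
        t = rft_threshold(0.05, self.MASK, fwhm, self.VOX, df)
        n1, n2, n3 = self.MASK.shape
        f = fwhm / 3.75  # FWHM in voxels, isotropic
        # box intrinsic volumes on the voxel lattice
        R0 = 1.0
        R1 = ((n1 - 1) + (n2 - 1) + (n3 - 1)) / f
        R2 = (
            (n1 - 1) * (n2 - 1) + (n1 - 1) * (n3 - 1) + (n2 - 1) * (n3 - 1)
        ) / f**2
        R3 = (n1 - 1) * (n2 - 1) * (n3 - 1) / f**3
        nu = float(df)
        base = (1 + t**2 / nu) ** (-(nu - 1) / 2)
        l2 = 4 * math.log(2)
        rho = [
            sps.t.sf(t, df),
            math.sqrt(l2) / (2 * math.pi) * base,
            l2
            / (2 * math.pi) ** 1.5
            * math.exp(math.lgamma((nu + 1) / 2) - math.lgamma(nu / 2))
            / math.sqrt(nu / 2)
            * t
            * base,
            l2**1.5 / (2 * math.pi) ** 2 * base * ((nu - 1) / nu * t**2 - 1),
        ]
        expected = R0 * rho[0] + R1 * rho[1] + R2 * rho[2] + R3 * rho[3]
        assert expected == pytest.approx(0.05, abs=1e-6)
        ours = expected_euler_characteristic(t, self.MASK, fwhm, self.VOX, df)
        assert ours == pytest.approx(expected, abs=1e-9)

    def test_sub_voxel_smoothness_warns(self):
        with pytest.warns(RuntimeWarning, match="below one voxel"):
            rft_threshold(0.05, self.MASK, 2.0, self.VOX, df=78)


class TestRelativeSd:
    @pytest.mark.parametrize(
        "p,np_,expected",
        [(0.01, 1000, 31.46), (0.01, 10_000, 9.95), (0.1, 100_000, 0.95)],
    )
    def test_tabulated_values(self, p, np_, expected):
        assert 100 * relative_sd_pvalue(p, np_) == pytest.approx(
            expected, abs=0.005
        )

    def test_square_root_law(self):
        assert relative_sd_pvalue(0.03, 1000) / relative_sd_pvalue(
            0.03, 100_000
        ) == pytest.approx(10.0, rel=1e-12)


class TestPermutationExecution:
    def _pipe(self, preprocess, seed=0, statistic="glm", fwhm=0.0):
        ds = _white_dataset((6, 6, 3), 80, seed)
        par = pf.Paradigm.block_design(20, 20, 160)
        cfg = PermutationConfig(
            statistic=statistic,
            fwhm_mm=fwhm,
            n_permutations=50,
            seed=seed,
            preprocess=preprocess,
        )
        return _Pipeline(ds, par, cfg), cfg

    def test_execution_order_does_not_change_sorted_maxima(self):
        for preprocess in (False, True):
            pipe, cfg = self._pipe(preprocess)
            plan = make_plan(80, 50, 3)
            forward = pipe.max_stats(plan.indices)
            shuffled_order = np.random.default_rng(9).permutation(50)
            shuffled = pipe.max_stats(plan.indices[shuffled_order])
            assert np.allclose(
                np.sort(forward), np.sort(shuffled), atol=1e-12
            )
            assert np.allclose(forward[shuffled_order], shuffled, atol=1e-12)

    def test_fast_glm_path_matches_direct_computation(self):
        from permfmri.stats import glm_tstat_matrix

        pipe, cfg = self._pipe(preprocess=False)
        plan = make_plan(80, 30, 5)
        fast = pipe.max_stats(plan.indices)
        W = pipe.innovations
        expected = np.array(
            [
                glm_tstat_matrix(W[idx], pipe.X, pipe.c).max()
                for idx in plan.indices
            ]
        )
        assert np.allclose(fast, expected, atol=1e-10)

    def test_identical_voxels_stay_identical_through_surrogates(self):
        # the same permutation is applied to every voxel, so two voxels
        # with identical series produce identical surrogate series
        from permfmri.whitening import _inverse_whiten_sequence

        ds = _white_dataset((4, 4, 2), 80, 11)
        ds.data[1, 1, 1] = ds.data[2, 2, 1]
        par = pf.Paradigm.block_design(20, 20, 160)
        # no spatial pooling, so identical series get identical AR filters
        cfg = PermutationConfig(
            statistic="glm", fwhm_mm=0.0, ar_smooth_fwhm_mm=0.0,
            n_permutations=5,
        )
        pipe = _Pipeline(ds, par, cfg)
        flat = pipe.mask.ravel()
        iv1 = np.flatnonzero(flat)[np.ravel_multi_index((1, 1, 1), (4, 4, 2))]
        plan = make_plan(80, 3, 2)
        E = pipe.innovations[plan.indices]
        Y = _inverse_whiten_sequence(E, pipe.hist)
        v1 = np.ravel_multi_index((1, 1, 1), (4, 4, 2))
        v2 = np.ravel_multi_index((2, 2, 1), (4, 4, 2))
        assert np.allclose(Y[:, :, v1], Y[:, :, v2], atol=1e-10)

    def test_whiten_permute_inverse_roundtrip_identity(self):
        from permfmri.whitening import _inverse_whiten_sequence

        pipe, cfg = self._pipe(preprocess=True, seed=21)
        identity = np.arange(80)[None, :]
        back = _inverse_whiten_sequence(
            pipe.innovations[identity], pipe.hist
        )[0]
        # reproduces the detrended, BOLD-removed residual exactly
        from permfmri.design import cubic_detrend, remove_bold

        ds = _white_dataset((6, 6, 3), 80, 21)
        S = ds.masked_series()
        R = remove_bold(cubic_detrend(S), pipe.X)
        assert np.allclose(back, R, atol=1e-10)


class TestRunPermutationTest:
    def test_threshold_pvalue_consistency_and_grid(self):
        ds = _white_dataset((6, 6, 3), 80, 3)
        par = pf.Paradigm.block_design(20, 20, 160)
        cfg = PermutationConfig(
            statistic="glm", fwhm_mm=0.0, n_permutations=100, seed=4
        )
        res, null = run_permutation_test(ds, par, cfg)
        assert null.n_permutations == 100
        pvals = res.pmap[res.mask]
        assert np.all((pvals * 100) % 1 < 1e-9)
        stat = res.stat_map[res.mask]
        # above-threshold iff corrected p below alpha, up to ties
        strict = stat > null.threshold(cfg.alpha)
        assert np.all(pvals[strict] < cfg.alpha + 1e-12)

    def test_deterministic_given_seed(self):
        ds = _white_dataset((5, 5, 2), 80, 6)
        par = pf.Paradigm.block_design(20, 20, 160)
        cfg = PermutationConfig(
            statistic="glm", fwhm_mm=0.0, n_permutations=60, seed=9
        )
        _, null1 = run_permutation_test(ds, par, cfg)
        _, null2 = run_permutation_test(ds, par, cfg)
        assert np.array_equal(null1.maxima, null2.maxima)

    def test_cca3d_statistic_runs_and_bounds(self):
        ds = _white_dataset((6, 6, 4), 80, 13)
        par = pf.Paradigm.block_design(20, 20, 160)
        cfg = PermutationConfig(
            statistic="cca3d", fwhm_mm=8.0, n_permutations=20, seed=1
        )
        res, null = run_permutation_test(ds, par, cfg)
        rho = res.stat_map[res.mask]
        assert np.all((rho >= 0) & (rho <= 1))
        assert 0 < null.threshold(0.25) <= 1

    def test_exclude_nonwhite_keeps_a_mask_subset(self):
        ds = _white_dataset((6, 6, 3), 80, 17)
        par = pf.Paradigm.block_design(20, 20, 160)
        cfg = PermutationConfig(
            statistic="glm", fwhm_mm=0.0, n_permutations=30, seed=2,
            exclude_nonwhite=True,
        )
        res, _ = run_permutation_test(ds, par, cfg)
        assert res.mask.sum() <= ds.mask.sum()
        assert res.mask.sum() > 0
        assert np.all(ds.mask[res.mask])

    def test_two_sided_mode_uses_absolute_maxima(self):
        ds = _white_dataset((5, 5, 2), 80, 6)
        par = pf.Paradigm.block_design(20, 20, 160)
        base = dict(statistic="glm", fwhm_mm=0.0, n_permutations=40, seed=2,
                    preprocess=False)
        _, one = run_permutation_test(
            ds, par, PermutationConfig(**base)
        )
        _, two = run_permutation_test(
            ds, par, PermutationConfig(two_sided=True, **base)
        )
        assert np.all(two.maxima >= one.maxima - 1e-12)


class TestFweCalibration:
    def test_alpha_half_sanity(self):
        cfg = FweCalibrationConfig(
            shape=(6, 6, 2),
            nt=40,
            n_permutations=400,
            n_datasets=400,
            alpha=0.5,
            seed=3,
        )
        res = fwe_calibration(cfg)
        assert res.rate == pytest.approx(0.5, abs=0.09)

    def test_independent_streams_for_threshold_and_fresh_data(self):
        cfg = FweCalibrationConfig(
            shape=(5, 5, 2), nt=40, n_permutations=200, n_datasets=100,
            alpha=0.2, seed=8,
        )
        r1 = fwe_calibration(cfg)
        cfg2 = FweCalibrationConfig(
            shape=(5, 5, 2), nt=40, n_permutations=200, n_datasets=100,
            alpha=0.2, seed=9,
        )
        r2 = fwe_calibration(cfg2)
        assert r1.threshold != r2.threshold  # different noise and plans


class TestThresholdVariability:
    def test_thresholds_positive_finite_and_sqrt10_scaling(self):
        base = dict(shape=(6, 6, 2), nt=80, n_replicates=60, seed=5)
        res_small = threshold_variability(
            ThresholdVariabilityConfig(n_permutations=400, **base)
        )
        res_large = threshold_variability(
            ThresholdVariabilityConfig(n_permutations=4000, **base)
        )
        for res in (res_small, res_large):
            assert np.all(np.isfinite(res.thresholds))
            assert np.all(res.thresholds > 0)
        ratio = res_small.sd / res_large.sd
        # ten times more permutations: sd smaller by about sqrt(10)
        assert 1.9 < ratio < 5.3

    def test_threshold_distribution_roughly_symmetric(self):
        res = threshold_variability(
            ThresholdVariabilityConfig(
                shape=(6, 6, 2), nt=80, n_permutations=500,
                n_replicates=200, seed=6,
            )
        )
        g1 = sps.skew(res.thresholds)
        assert abs(g1) < 0.5


class TestConfigValidation:
    def test_unknown_statistic_rejected(self):
        with pytest.raises(DomainError):
            PermutationConfig(statistic="anova")

    def test_alpha_domain(self):
        with pytest.raises(DomainError):
            PermutationConfig(alpha=1.5)

    def test_ar_order_range(self):
        with pytest.raises(DomainError):
            PermutationConfig(ar_order=9)
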