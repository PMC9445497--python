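import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import saibr
from saibr import (
    CollinearityError,
    ConfigurationError,
    DegeneratePredictorError,
    InsufficientDataError,
    ParameterError,
    PixelPool,
    SceneParams,
    build_pixel_pool,
    estimate_spillover,
    fit_three_channel,
    fit_two_channel,
    fit_whole_sample,
    gaussian_prefilter,
    make_cohort,
    make_scene,
)
from conftest import stack_from


# ---------------------------------------------------------------------------
# Gaussian pre-filter
# ---------------------------------------------------------------------------

class TestGaussianPrefilter:
    def test_constant_image_preserved(self):
        out = gaussian_prefilter(np.full((9, 9), 7.0), radius=2.0)
        np.testing.assert_allclose(out, 7.0, rtol=0, atol=1e-12)

    def test_radius_zero_is_identity(self):
        img = np.random.default_rng(0).uniform(size=(5, 5))
        assert gaussian_prefilter(img, 0) is img

    def test_negative_radius_rejected(self):
        with pytest.raises(ParameterError):
            gaussian_prefilter(np.zeros((3, 3)), -1.0)

    def test_matches_brute_force_normalized_kernel(self):
        # independent oracle: explicit truncated Gaussian taps, separable 2-D
        # convolution on an interior bright pixel
        radius = 2.0
        img = np.zeros((33, 33))
        img[16, 16] = 10.0
        half = int(4.0 * radius + 0.5)
        taps = np.exp(-0.5 * (np.arange(-half, half + 1) / radius) ** 2)
        taps /= taps.sum()
        expected = np.outer(taps, taps) * 10.0
        out = gaussian_prefilter(img, radius)
        np.testing.assert_allclose(out[16 - half:16 + half + 1, 16 - half:16 + half + 1],
                                   expected, rtol=1e-10, atol=1e-14)
        # normalized kernel conserves total intensity for interior sources
        assert out.sum() == pytest.approx(10.0, rel=1e-12)


# ---------------------------------------------------------------------------
# Pixel pooling
# ---------------------------------------------------------------------------

class TestBuildPixelPool:
    def _stack(self, seed, sid):
        rng = np.random.default_rng(seed)
        roi = np.zeros((10, 10), bool)
        roi.ravel()[:100][:100] = False
        roi[:10, :10] = True
        return stack_from(rng.uniform(0, 50, (10, 10)), rng.uniform(0, 50, (10, 10)),
                          roi=roi, sample_id=sid)

    def test_pool_concatenates_with_provenance(self):
        stacks = [self._stack(i, f"s{i}") for i in range(3)]
        pool = build_pixel_pool(stacks, 1.0)
        assert pool.n_pixels == 300
        assert pool.sample_ids == ["s0", "s1", "s2"]

    def test_single_pixel_roi(self):
        roi = np.zeros((4, 4), bool)
        roi[2, 2] = True
        pool = build_pixel_pool([stack_from(np.ones((4, 4)), np.ones((4, 4)), roi=roi)], 0)
        assert pool.n_pixels == 1

    def test_radius_changes_values_not_membership(self):
        stacks = [self._stack(5, "s")]
        p0 = build_pixel_pool(stacks, 0)
        p2 = build_pixel_pool(stacks, 2.0)
        assert p0.n_pixels == p2.n_pixels
        assert not np.array_equal(p0.g, p2.g)

    def test_missing_rfp_channel_rejected_when_required(self):
        with pytest.raises(ConfigurationError):
            build_pixel_pool([self._stack(0, "s")], 1.0, require_rfp=True)

    def test_saturated_pixels_excluded(self):
        img = np.full((4, 4), 100.0)
        img[0, 0] = 255.0
        pool = build_pixel_pool([stack_from(img, np.full((4, 4), 10.0))],
                                0, saturation_max=255.0)
        assert pool.n_pixels == 15

    def test_empty_stack_list_rejected(self):
        with pytest.raises(InsufficientDataError):
            build_pixel_pool([], 1.0)


# ---------------------------------------------------------------------------
# Two-channel fit
# ---------------------------------------------------------------------------

def _normal_equation_oracle(columns, y):
    """Independent OLS oracle: explicitly solved normal equations."""
    X = np.column_stack(list(columns) + [np.ones(len(y))])
    return np.linalg.solve(X.T @ X, X.T @ y)


class TestFitTwoChannel:
    def test_exactly_collinear_points(self):
        pool = PixelPool(g=[1, 3, 5], a=[0, 1, 2])
        model = fit_two_channel(pool)
        assert model.m == pytest.approx(2.0, abs=1e-12)
        assert model.c == pytest.approx(1.0, abs=1e-12)
        assert model.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_normal_equations_case(self):
        # (a,g) = (0,0),(1,1),(2,0),(3,1): Sxy=1, Sxx=5 -> m=0.2, c=0.2
        model = fit_two_channel(PixelPool(g=[0, 1, 0, 1], a=[0, 1, 2, 3]))
        assert model.m == pytest.approx(0.2, abs=1e-12)
        assert model.c == pytest.approx(0.2, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_normal_equation_oracle_on_tiny_pools(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 11)
        a = rng.uniform(0, 100, n)
        g = rng.uniform(0, 100, n)
        model = fit_two_channel(PixelPool(g=g, a=a))
        m_ref, c_ref = _normal_equation_oracle([a], g)
        assert model.m == pytest.approx(m_ref, rel=1e-10)
        assert model.c == pytest.approx(c_ref, rel=1e-10)

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(DegeneratePredictorError):
            fit_two_channel(PixelPool(g=[1, 2, 3], a=[5, 5, 5]))

    def test_too_few_observations_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_two_channel(PixelPool(g=[1, 2], a=[0, 1]))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(k=st.floats(0.1, 10), b=st.floats(-50, 50))
    def test_scale_and_shift_covariance(self, k, b):
        # scaling a by k maps m -> m/k, c unchanged; shifting g by b maps
        # c -> c+b, m unchanged
        a = np.array([0.0, 1.0, 2.0, 3.0, 5.0])
        g = np.array([1.0, 2.5, 5.5, 6.0, 11.0])
        base = fit_two_channel(PixelPool(g=g, a=a))
        scaled = fit_two_channel(PixelPool(g=g, a=k * a))
        assert scaled.m == pytest.approx(base.m / k, rel=1e-9)
        assert scaled.c == pytest.approx(base.c, rel=1e-9, abs=1e-9)
        shifted = fit_two_channel(PixelPool(g=g + b, a=a))
        assert shifted.m == pytest.approx(base.m, rel=1e-9)
        assert shifted.c == pytest.approx(base.c + b, rel=1e-9, abs=1e-9)

    def test_per_sample_diagnostics_are_reported(self, fitted_model):
        assert len(fitted_model.per_sample) == 10
        for d in fitted_model.per_sample:
            assert d["r_squared"] > 0.99


# ---------------------------------------------------------------------------
# Three-channel fit
# ---------------------------------------------------------------------------

class TestFitThreeChannel:
    def test_exact_plane(self):
        a = np.array([0.0, 1.0, 0.0, 1.0])
        r = np.array([0.0, 0.0, 1.0, 1.0])
        g = 1.0 * a + 2.0 * r + 3.0
        model = fit_three_channel(PixelPool(g=g, a=a, r=r))
        assert model.m1 == pytest.approx(1.0, abs=1e-10)
        assert model.m2 == pytest.approx(2.0, abs=1e-10)
        assert model.c == pytest.approx(3.0, abs=1e-10)
        assert model.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_red_predictor_named_in_error(self):
        with pytest.raises(CollinearityError, match="'r'"):
            fit_three_channel(PixelPool(g=[0, 1, 2, 3], a=[0, 1, 2, 3], r=[4, 4, 4, 4]))

    def test_collinear_predictors_rejected(self):
        a = np.array([0.0, 1.0, 2.0, 3.0])
        with pytest.raises(CollinearityError):
            fit_three_channel(PixelPool(g=[0, 1, 2, 3], a=a, r=2 * a + 1))

    def test_missing_red_channel_rejected(self):
        with pytest.raises(ConfigurationError):
            fit_three_channel(PixelPool(g=[0, 1, 2, 3], a=[0, 1, 2, 3]))

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_normal_equation_oracle_on_tiny_pools(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = rng.integers(4, 11)
        a, r = rng.uniform(0, 100, n), rng.uniform(0, 100, n)
        g = rng.uniform(0, 100, n)
        model = fit_three_channel(PixelPool(g=g, a=a, r=r))
        m1_ref, m2_ref, c_ref = _normal_equation_oracle([a, r], g)
        assert model.m1 == pytest.approx(m1_ref, rel=1e-10)
        assert model.m2 == pytest.approx(m2_ref, rel=1e-10)
        assert model.c == pytest.approx(c_ref, rel=1e-10)

    def test_recovers_generator_truth_on_red_only_scenes(self):
        params = SceneParams(seed=3, rfp_amplitude=300.0, rfp_bleed_true=0.05)
        scenes = make_cohort(params, 5)
        pool = build_pixel_pool([s.stack for s in scenes], 2.0, require_rfp=True)
        model = fit_three_channel(pool)
        # red bleedthrough into A mimics AF absent from the primary channel,
        # so the fitted coefficient on R is -m_true * bleed
        assert model.m1 == pytest.approx(params.m_true, rel=0.05)
        assert model.m2 == pytest.approx(-params.m_true * params.rfp_bleed_true, rel=0.05)
        assert model.c == pytest.approx(params.c_true, rel=0.05)


# ---------------------------------------------------------------------------
# Recovery / consistency on synthetic scenes
# ---------------------------------------------------------------------------

class TestRecovery:
    def test_two_channel_recovery_within_two_percent(self, fitted_model, unlabeled_params):
        assert fitted_model.m == pytest.approx(unlabeled_params.m_true, rel=0.02)
        assert abs(fitted_model.c - unlabeled_params.c_true) < 5.0
        assert fitted_model.n_pixels >= 10_000

    def test_error_decreases_with_pool_size(self, calibration_scenes, unlabeled_params):
        pool = build_pixel_pool([s.stack for s in calibration_scenes], 2.0)
        rng = np.random.default_rng(123)
        errors = []
        for n in (100, 1000, 10_000):
            errs = []
            for _ in range(5):
                idx = rng.choice(pool.n_pixels, n, replace=False)
                sub = PixelPool(g=pool.g[idx], a=pool.a[idx], radius=pool.radius)
                errs.append(abs(fit_two_channel(sub).m - unlabeled_params.m_true))
            errors.append(np.mean(errs))
        assert errors[0] > errors[1] > errors[2]

    def test_r_squared_nondecreasing_in_filter_radius(self):
        scenes = make_cohort(SceneParams(seed=6, noise_sd=15.0), 3)
        stacks = [s.stack for s in scenes]
        r2 = [fit_two_channel(build_pixel_pool(stacks, r)).r_squared for r in (0, 1, 2)]
        assert r2[0] <= r2[1] <= r2[2]

    def test_red_bleedthrough_biases_two_channel_slope(self):
        # fitting the two-channel model on red-expressing calibration data
        # drags the slope down, in proportion to red level
        slopes = []
        for amp in (0.0, 150.0, 300.0):
            scenes = make_cohort(SceneParams(seed=7, rfp_amplitude=amp), 4)
            pool = build_pixel_pool([s.stack for s in scenes], 2.0)
            slopes.append(fit_two_channel(pool).m)
        assert slopes[0] > slopes[1] > slopes[2]
        assert slopes[0] - slopes[2] > 0.02


# ---------------------------------------------------------------------------
# Whole-sample fit
# ---------------------------------------------------------------------------

class TestFitWholeSample:
    def test_exact_line_through_sample_means(self):
        stacks = [stack_from(np.full((4, 4), g), np.full((4, 4), a), sample_id=f"s{a}")
                  for a, g in [(10, 21), (20, 41), (30, 61)]]
        model = fit_whole_sample(stacks)
        assert model.m == pytest.approx(2.0, abs=1e-10)
        assert model.c == pytest.approx(1.0, abs=1e-10)

    def test_too_few_samples_rejected(self):
        stacks = [stack_from(np.full((4, 4), 1.0), np.full((4, 4), 1.0))] * 2
        with pytest.raises(InsufficientDataError):
            fit_whole_sample(stacks)

    def test_agrees_with_pixel_fit_on_synthetic_cohort(self, calibration_scenes, fitted_model):
        model = fit_whole_sample([s.stack for s in calibration_scenes])
        assert model.m == pytest.approx(fitted_model.m, rel=0.05)
        assert model.c == pytest.approx(fitted_model.c, abs=10.0)


# ---------------------------------------------------------------------------
# Spillover estimation
# ---------------------------------------------------------------------------

class TestEstimateSpillover:
    # spillover samples: strong structured fluorophore, ROI restricted to the
    # sample interior so fluorophore structure varies independently of AF
    def _gfp_scenes(self, seed, s_true):
        params = SceneParams(seed=seed, gfp_layout="nuclear_void",
                             gfp_amplitude=400.0, s_true=s_true, roi_margin=0.0)
        return [sc.stack for sc in make_cohort(params, 5)]

    def test_null_scene_gives_near_zero_s(self, fitted_model):
        model = estimate_spillover(self._gfp_scenes(41, 0.0), fitted_model)
        assert abs(model.s) < 0.02

    def test_recovers_ten_percent_spillover(self, fitted_model):
        model = estimate_spillover(self._gfp_scenes(40, 0.1), fitted_model)
        assert model.s == pytest.approx(0.1, rel=0.10)

    def test_pure_af_scene_indistinguishable_from_zero(self, fitted_model):
        # no fluorophore at all: the excess-vs-corrected regression finds no
        # physical (positive) leak and reports s = 0
        scenes = make_cohort(SceneParams(seed=42, roi_margin=0.0), 5)
        with pytest.warns(UserWarning):
            model = estimate_spillover([s.stack for s in scenes], fitted_model)
        assert model.s == 0.0

    def test_negative_estimate_truncated_with_warning(self, fitted_model):
        # membrane-band fluorophore overlaps the AF edge falloff, violating
        # the independence assumption towards negative slopes
        params = SceneParams(seed=43, gfp_layout="membrane_band",
                             gfp_amplitude=400.0, s_true=0.0, roi_margin=0.0)
        stacks = [sc.stack for sc in make_cohort(params, 3)]
        with pytest.warns(UserWarning, match="negative"):
            model = estimate_spillover(stacks, fitted_model)
        assert model.s == 0.0
        # and s=0 leaves the correction unchanged
        from saibr import correct
        assert np.array_equal(correct(model, stacks[0]).corrected,
                              correct(fitted_model, stacks[0]).corrected)


def test_pool_sample_export_is_seeded(tmp_path, calibration_scenes):
    import pandas as pd

    pool = build_pixel_pool([s.stack for s in calibration_scenes[:2]], 1.0)
    saibr.export_pool_sample(pool, tmp_path / "a.csv", fraction=0.1, seed=5)
    saibr.export_pool_sample(pool, tmp_path / "b.csv", fraction=0.1, seed=5)
    a = pd.read_csv(tmp_path / "a.csv")
    assert len(a) == round(0.1 * pool.n_pixels)
    assert a.equals(pd.read_csv(tmp_path / "b.csv"))
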