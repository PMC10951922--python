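"""Unit and property tests for gaussianization and random-field quantities."""

import numpy as np
import pytest
from scipy import ndimage, stats

from fibermap import (
    FlatFieldError,
    GRFModel,
    ParametricMap,
    estimate_field_params,
    expected_cluster_count,
    expected_cluster_extent,
    expected_suprathreshold_area,
    gaussianize,
    learn_model,
    p_intensity,
    p_surface,
    simulate_grf,
)


def _grf_map(seed, shape=(128, 128), w=3.0):
    return ParametricMap(simulate_grf(shape, w, 1.0, seed=seed).image)


# ---------------------------------------------------------------------------
# gaussianize
# ---------------------------------------------------------------------------

class TestGaussianize:
    def test_moments_and_rank_preservation(self, rng):
        """Output is zero-mean with the native variance; ranks unchanged."""
        v = np.exp(rng.normal(size=(64, 64)))  # heavily skewed
        pm = ParametricMap(v)
        g = gaussianize(pm)
        sd = v.std()
        assert abs(g.values.mean()) < 0.01 * sd
        assert g.values.std() == pytest.approx(sd, rel=0.01)
        assert np.array_equal(
            np.argsort(v.ravel(), kind="stable"),
            np.argsort(g.values.ravel(), kind="stable"),
        )
        # histogram is Gaussian: KS against N(0, sd)
        d, _ = stats.kstest(g.values.ravel() / sd, "norm")
        assert d < 0.01

    def test_gaussian_input_is_near_fixed_point(self):
        """A map that is already ~N(0, s^2) passes through almost unchanged.

        The residual is the deviation of the sample's order statistics
        from the ideal quantile grid, which shrinks as 1/sqrt(N); at the
        512x512 study scale its RMS is below 1% of sigma.
        """
        pm = _grf_map(0, shape=(512, 512))
        g = gaussianize(pm)
        sd = pm.values.std()
        rms = np.sqrt(np.mean((g.values - pm.values) ** 2))
        assert rms < 0.01 * sd

    def test_monotone_invariance(self, rng):
        """gaussianize(h(m)) has the same pixel ranks as gaussianize(m)."""
        v = rng.normal(size=(32, 32))
        g1 = gaussianize(ParametricMap(v))
        g2 = gaussianize(ParametricMap(np.exp(2.0 * v) + 7.0))
        assert np.array_equal(
            np.argsort(g1.values.ravel(), kind="stable"),
            np.argsort(g2.values.ravel(), kind="stable"),
        )

    def test_idempotent(self, rng):
        v = rng.gamma(2.0, size=(48, 48))
        g1 = gaussianize(ParametricMap(v))
        g2 = gaussianize(g1)
        assert np.allclose(g1.values, g2.values, rtol=1e-6, atol=0)

    def test_constant_map_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            gaussianize(ParametricMap(np.full((16, 16), 3.0)))


# ---------------------------------------------------------------------------
# estimate_field_params / learn_model
# ---------------------------------------------------------------------------

def _mc_gradient_cov_oracle(n_real=50, shape=(128, 128), w=3.0):
    """Central-difference Monte-Carlo oracle for the gradient covariance.

    A different stencil from the estimator under test (one-pixel forward
    increments); for a kernel of width 3 px the two agree within a few
    percent.
    """
    covs = []
    for s in range(n_real):
        f = simulate_grf(shape, w, 1.0, seed=10_000 + s).image
        gx = 0.5 * (f[:, 2:] - f[:, :-2])[1:-1, :]
        gy = 0.5 * (f[2:, :] - f[:-2, :])[:, 1:-1]
        covs.append(np.cov(np.vstack([gx.ravel(), gy.ravel()])))
    return np.mean(covs, axis=0)


class TestFieldParams:
    def test_ramp_is_degenerate(self):
        r, c = np.mgrid[0:32, 0:32].astype(float)
        with pytest.raises(FlatFieldError):
            estimate_field_params(ParametricMap(2.0 * c + 3.0 * r))

    def test_gradient_variance_matches_analytic_kernel_constant(self):
        """Smoothed white noise: gradient variance vs closed-form constant.

        For unit-variance smoothed noise the one-pixel increment
        variance per axis is 2 (1 - rho(1)), with rho the discrete
        autocorrelation of the smoothing kernel (~ 1/(2 w^2) for a wide
        Gaussian of width w).  The determinant is its square (isotropy).
        """
        delta = np.zeros(81)
        delta[40] = 1.0
        k = ndimage.gaussian_filter1d(delta, 3.0)
        rho = np.correlate(k, k, mode="full")
        rho /= rho.max()
        var_axis = 2.0 * (1.0 - rho[len(rho) // 2 + 1])
        assert var_axis == pytest.approx(1.0 / (2.0 * 3.0**2), rel=0.02)
        dets = []
        for s in range(10):
            ld, sd = estimate_field_params(_grf_map(s))
            dets.append(ld)
            assert sd == pytest.approx(1.0, rel=0.02)
        assert np.mean(dets) == pytest.approx(var_axis**2, rel=0.10)

    def test_gradient_variance_matches_mc_oracle(self):
        """Per-axis gradient variance vs a central-difference MC oracle.

        The oracle applies an independent stencil to 50 fresh
        realizations; both stencils agree within 10% for a kernel of
        width 3 px.
        """
        oracle = _mc_gradient_cov_oracle()
        per_axis = []
        for s in range(10):
            ld, _ = estimate_field_params(_grf_map(s))
            per_axis.append(np.sqrt(ld))  # isotropic: sqrt(det) ~ marginal var
        assert np.mean(per_axis) == pytest.approx(oracle[0, 0], rel=0.10)

    def test_isotropy_makes_det_product_of_marginals(self):
        """Off-diagonal covariance ~ 0: det ~ product of per-axis variances."""
        oracle = _mc_gradient_cov_oracle()
        assert abs(oracle[0, 1]) < 0.03 * oracle[0, 0]
        assert np.linalg.det(oracle) == pytest.approx(
            oracle[0, 0] * oracle[1, 1], rel=0.05
        )

    def test_learn_model_is_arithmetic_mean(self):
        m1 = _grf_map(1)
        model_single = learn_model([m1])
        model_rep = learn_model([m1, m1, m1])
        assert model_rep.lambda_det == pytest.approx(model_single.lambda_det)
        assert model_rep.sigma == pytest.approx(model_single.sigma)
        # two maps with different sigma average linearly
        m2 = ParametricMap(3.0 * m1.values)
        pair = learn_model([m1, m2])
        s1 = estimate_field_params(m1)[1]
        assert pair.sigma == pytest.approx(2.0 * s1, rel=1e-12)

    def test_learn_model_empty_errors(self):
        with pytest.raises(ValueError):
            learn_model([])


# ---------------------------------------------------------------------------
# closed-form expectations and probabilities
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def toy_model():
    return GRFModel(lambda_det=(1.0 / 18.0) ** 2, sigma=1.0, n_pixels=512 * 512)


class TestExpectations:
    def test_count_decreasing_and_vanishing(self, toy_model):
        ts = np.linspace(1.0, 8.0, 50)
        vals = [expected_cluster_count(toy_model, t) for t in ts]
        assert all(a > b for a, b in zip(vals, vals[1:]))  # decreasing past sigma
        assert vals[-1] < 1e-8

    def test_count_ratio_cancels_area_and_roughness(self, toy_model):
        other = GRFModel(lambda_det=0.5, sigma=1.0, n_pixels=10_000)
        t, x = 2.0, 3.0
        for m in (toy_model, other):
            ratio = expected_cluster_count(m, x) / expected_cluster_count(m, t)
            assert ratio == pytest.approx((x / t) * np.exp(-(x**2 - t**2) / 2.0))

    def test_count_rejects_nonpositive_threshold(self, toy_model):
        with pytest.raises(ValueError):
            expected_cluster_count(toy_model, 0.0)

    def test_area_at_zero_is_half_the_image(self, toy_model):
        assert expected_suprathreshold_area(toy_model, 0.0) == pytest.approx(
            toy_model.n_pixels / 2.0
        )

    def test_area_matches_normal_tail(self):
        m = GRFModel(lambda_det=1e-3, sigma=1.0, n_pixels=10**6)
        assert expected_suprathreshold_area(m, 2.0) == pytest.approx(22750, abs=1)

    def test_area_monotone_decreasing(self, toy_model):
        ts = np.linspace(0.0, 5.0, 30)
        vals = [expected_suprathreshold_area(toy_model, t) for t in ts]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_extent_decreasing_past_sigma(self, toy_model):
        ts = np.linspace(1.0, 6.0, 40)
        vals = [expected_cluster_extent(toy_model, t) for t in ts]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_extent_scales_inverse_sqrt_roughness(self, toy_model):
        scaled = GRFModel(
            lambda_det=4.0 * toy_model.lambda_det,
            sigma=toy_model.sigma,
            n_pixels=toy_model.n_pixels,
        )
        assert expected_cluster_extent(scaled, 2.5) == pytest.approx(
            expected_cluster_extent(toy_model, 2.5) / 2.0
        )


class TestProbabilities:
    def test_p_intensity_at_threshold_is_one(self, toy_model):
        assert p_intensity(toy_model, 2.0, 2.0) == pytest.approx(1.0)

    def test_p_intensity_known_value(self, toy_model):
        # (3/2) exp(-2.5) for sigma = 1
        assert p_intensity(toy_model, 2.0, 3.0) == pytest.approx(
            1.5 * np.exp(-2.5), rel=1e-12
        )

    def test_p_intensity_matches_full_count_ratio(self, toy_model):
        t, x = 2.2, 3.7
        full = expected_cluster_count(toy_model, x) / expected_cluster_count(toy_model, t)
        assert p_intensity(toy_model, t, x) == pytest.approx(full)

    def test_p_intensity_monotone_in_x(self, toy_model):
        xs = np.linspace(2.0, 6.0, 30)
        ps = [p_intensity(toy_model, 2.0, x) for x in xs]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        assert all(0.0 <= p <= 1.0 for p in ps)

    def test_p_intensity_rejects_x_below_t(self, toy_model):
        with pytest.raises(ValueError):
            p_intensity(toy_model, 2.0, 1.5)

    def test_p_surface_extremes(self, toy_model):
        assert p_surface(toy_model, 2.5, 0.0) == pytest.approx(1.0)
        es = expected_cluster_extent(toy_model, 2.5)
        assert p_surface(toy_model, 2.5, es) == pytest.approx(np.exp(-1.0))

    def test_p_surface_monotone_in_s0(self, toy_model):
        s0s = np.linspace(0.0, 300.0, 40)
        ps = [p_surface(toy_model, 2.5, s) for s in s0s]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        assert all(0.0 <= p <= 1.0 for p in ps)


# ---------------------------------------------------------------------------
# calibration of the per-cluster tests on pure GRF maps
# ---------------------------------------------------------------------------

def test_false_positive_rate_calibrated(grf_batch, grf_model):
    """On pure-GRF maps each criterion flags ~pval of clusters at most.

    Checked per criterion at t = 2 sigma over held-out realizations
    (seeds disjoint from the learning batch), allowing 3 Monte-Carlo
    standard errors over the per-image flagged fractions.
    """
    from fibermap import DetectionConfig, detect

    t = 2.0 * grf_model.sigma
    config = DetectionConfig(thresholds=(t,), pval=0.05, criterion="intensity")
    frac_int, frac_surf = [], []
    for s in range(50, 70):
        pm = gaussianize(ParametricMap(simulate_grf((256, 256), 3.0, 1.0, seed=s).image))
        res = detect(pm, grf_model, config)
        recs = res.clusters[t]
        if not recs:
            continue
        frac_int.append(np.mean([c.intensity_sig for c in recs]))
        frac_surf.append(np.mean([c.surface_sig for c in recs]))
    for fracs in (frac_int, frac_surf):
        fracs = np.asarray(fracs)
        se = fracs.std(ddof=1) / np.sqrt(len(fracs))
        assert fracs.mean() <= 0.05 + 3.0 * se
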