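import cmath
import math

import numpy as np
import pytest

from mrarfi import (
    ComplexImageSeries,
    FitOptions,
    Grid,
    TriggerSchedule,
    ValidationError,
    analytic_baseline,
    build_basis,
    eval_phase,
    fit,
    forward_model,
    loss,
    result_to_map,
    resolve_lambda,
    simulate,
    SimulationConfig,
)


def naive_loss(series, baseline, coeffs, theta, basis, lam, eps):
    """Independent double-loop evaluation of the penalized loss."""
    nt = series.n_timepoints
    rows, cols = series.grid_shape
    total = 0.0
    for n in range(nt):
        sign = (-1) ** series.schedule.indicators[n]
        for r in range(rows):
            for c in range(cols):
                poly = 0.0
                for k, (px, py) in enumerate(basis.term_exponents):
                    xr = 0.0 if cols == 1 else -1 + 2 * c / (cols - 1)
                    yr = 0.0 if rows == 1 else -1 + 2 * r / (rows - 1)
                    poly += coeffs[n][k] * xr**px * yr**py
                pred = baseline[r, c] * cmath.exp(
                    1j * (poly + sign * theta[r, c])
                )
                total += abs(series.data[n, r, c] - pred) ** 2
    penalty = sum(
        math.sqrt(theta[r, c] ** 2 + eps) - math.sqrt(eps)
        for r in range(rows)
        for c in range(cols)
    )
    return total / nt + lam * penalty


def random_instance(seed, nt=5, shape=(4, 3), order=2):
    rng = np.random.default_rng(seed)
    basis = build_basis(shape, order)
    baseline = rng.normal(size=shape) + 1j * rng.normal(size=shape)
    coeffs = 0.3 * rng.normal(size=(nt, basis.n_terms))
    theta = 0.2 * rng.normal(size=shape)
    data = rng.normal(size=(nt, *shape)) + 1j * rng.normal(size=(nt, *shape))
    indicators = tuple(int(v) for v in rng.integers(0, 2, nt))
    if len(set(indicators)) < 2:
        indicators = (0, 1) + indicators[2:]
    series = ComplexImageSeries(
        data=data, grid=Grid(), schedule=TriggerSchedule(indicators),
        params=__import__("mrarfi").default_params(),
    )
    return series, basis, baseline, coeffs, theta


class TestForwardModel:
    def test_zero_phase_returns_baseline(self, small_series):
        basis = build_basis(small_series.grid_shape, 2)
        baseline = small_series.data[0]
        pred = forward_model(
            baseline, np.zeros(6), np.zeros(small_series.grid_shape), 0, basis
        )
        np.testing.assert_array_equal(pred, baseline)

    def test_indicator_flip_doubles_phase_difference(self):
        basis = build_basis((4, 4), 2)
        baseline = np.ones((4, 4), dtype=complex)
        theta = np.full((4, 4), 0.3)
        pos = forward_model(baseline, np.zeros(6), theta, 0, basis)
        neg = forward_model(baseline, np.zeros(6), theta, 1, basis)
        np.testing.assert_allclose(np.angle(pos * np.conj(neg)), 0.6)

    def test_constant_coefficient_rotates_to_i(self):
        basis = build_basis((3, 3), 2)
        c = np.zeros(6)
        c[0] = np.pi / 2
        pred = forward_model(
            np.ones((3, 3), dtype=complex), c, np.zeros((3, 3)), 0, basis
        )
        np.testing.assert_allclose(pred, 1j, atol=1e-15)

    def test_magnitude_preserved(self, small_series):
        basis = build_basis(small_series.grid_shape, 2)
        rng = np.random.default_rng(1)
        pred = forward_model(
            small_series.data[0], rng.normal(size=6),
            rng.normal(size=small_series.grid_shape), 1, basis,
        )
        np.testing.assert_allclose(
            np.abs(pred), np.abs(small_series.data[0]), rtol=1e-12
        )

    def test_shape_mismatch_rejected(self):
        basis = build_basis((4, 4), 2)
        with pytest.raises(ValidationError):
            forward_model(np.ones((3, 3), dtype=complex), np.zeros(6),
                          np.zeros((3, 3)), 0, basis)


class TestLoss:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_naive_double_loop(self, seed):
        series, basis, baseline, coeffs, theta = random_instance(seed)
        options = FitOptions(lambda_sparsity=1.3, auto_scale_lambda=False)
        got = loss(series, baseline, coeffs, theta, basis, options)
        want = naive_loss(series, baseline, coeffs, theta, basis, 1.3,
                          options.l1_smoothing_eps)
        assert got == pytest.approx(want, rel=1e-12)

    def test_exact_model_with_zero_theta_has_zero_loss(self, params):
        basis = build_basis((4, 4), 2)
        rng = np.random.default_rng(3)
        baseline = rng.normal(size=(4, 4)) + 1j * rng.normal(size=(4, 4))
        coeffs = 0.2 * rng.normal(size=(4, basis.n_terms))
        theta = np.zeros((4, 4))
        data = np.stack([
            forward_model(baseline, coeffs[n], theta, n % 2, basis)
            for n in range(4)
        ])
        series = ComplexImageSeries(data=data, grid=Grid(),
                                    schedule=TriggerSchedule((0, 1, 0, 1)),
                                    params=params)
        assert loss(series, baseline, coeffs, theta, basis,
                    FitOptions(lambda_sparsity=0, auto_scale_lambda=False)
                    ) == pytest.approx(0.0, abs=1e-20)

    def test_pure_penalty_when_data_fits_exactly(self, params):
        basis = build_basis((4, 4), 2)
        baseline = np.full((4, 4), 2.0 + 0j)
        theta = np.zeros((4, 4))
        theta[2, 2] = 0.05
        coeffs = np.zeros((4, basis.n_terms))
        data = np.stack([
            forward_model(baseline, coeffs[n], theta, n % 2, basis)
            for n in range(4)
        ])
        series = ComplexImageSeries(data=data, grid=Grid(),
                                    schedule=TriggerSchedule((0, 1, 0, 1)),
                                    params=params)
        options = FitOptions(lambda_sparsity=100.0, auto_scale_lambda=False)
        got = loss(series, baseline, coeffs, theta, basis, options)
        # λ·|t| up to the smoothing-ε anchoring
        assert got == pytest.approx(100.0 * 0.05, abs=0.02)

    def test_lambda_auto_scaling(self, small_series):
        # λ₀=0.2 at mean amplitude 1e4 reproduces λ=2000
        series = ComplexImageSeries(
            data=small_series.data / small_series.mean_magnitude * 1e4,
            grid=small_series.grid, schedule=small_series.schedule,
            params=small_series.params,
        )
        assert resolve_lambda(series, FitOptions()) == pytest.approx(2000.0)
        assert resolve_lambda(
            series, FitOptions(lambda_sparsity=7.0, auto_scale_lambda=False)
        ) == 7.0


class TestAnalyticBaseline:
    def test_identical_images_return_baseline(self, params):
        basis = build_basis((4, 4), 2)
        m0 = np.arange(16).reshape(4, 4) + 1j
        data = np.stack([m0] * 4)
        series = ComplexImageSeries(data=data, grid=Grid(),
                                    schedule=TriggerSchedule((0, 1, 0, 1)),
                                    params=params)
        got = analytic_baseline(series, np.zeros((4, 6)), np.zeros((4, 4)), basis)
        np.testing.assert_allclose(got, m0)

    def test_opposite_contrast_phases_removed(self, params):
        basis = build_basis((4, 4), 2)
        m0 = np.full((4, 4), 3.0 - 1.0j)
        theta = np.full((4, 4), 0.4)
        data = np.stack([m0 * np.exp(1j * theta), m0 * np.exp(-1j * theta)])
        series = ComplexImageSeries(data=data, grid=Grid(),
                                    schedule=TriggerSchedule((0, 1)),
                                    params=params)
        got = analytic_baseline(series, np.zeros((2, 6)), theta, basis)
        np.testing.assert_allclose(got, m0, rtol=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_minimizes_data_term_against_perturbations(self, seed):
        # optimality oracle: the closed form beats 100 random perturbations
        series, basis, _, coeffs, theta = random_instance(seed, nt=6,
                                                          shape=(5, 4))
        m_hat = analytic_baseline(series, coeffs, theta, basis)
        opts = FitOptions(lambda_sparsity=0, auto_scale_lambda=False)
        best = loss(series, m_hat, coeffs, theta, basis, opts)
        rng = np.random.default_rng(100 + seed)
        for _ in range(100):
            delta = 0.1 * (rng.normal(size=m_hat.shape)
                           + 1j * rng.normal(size=m_hat.shape))
            perturbed = loss(series, m_hat + delta, coeffs, theta, basis, opts)
            assert perturbed >= best * (1 - 1e-10)


class TestFit:
    def test_gradient_matches_finite_differences(self):
        from mrarfi.recon import _objective_factory

        rng = np.random.default_rng(5)
        nt, shape = 4, (3, 3)
        basis = build_basis(shape, 1)
        data = (rng.normal(size=(nt, 9)) + 1j * rng.normal(size=(nt, 9)))
        signs = np.array([1.0, -1.0, 1.0, -1.0])
        obj = _objective_factory(data, signs, basis.design, 0.7, 1e-8)
        x0 = 0.1 * rng.normal(size=9 + nt * basis.n_terms)
        f0, g0 = obj(x0)
        for i in range(0, len(x0), 3):
            h = 1e-6
            e = np.zeros_like(x0)
            e[i] = h
            fd = (obj(x0 + e)[0] - obj(x0 - e)[0]) / (2 * h)
            assert fd == pytest.approx(g0[i], rel=1e-4, abs=1e-8)

    def test_recovers_theta_without_drift_or_noise(self, clean_sim):
        series, truth, basis = clean_sim
        result = fit(series, basis,
                     FitOptions(lambda_sparsity=0, auto_scale_lambda=False))
        rmse = np.sqrt(np.mean((result.theta - truth.theta) ** 2))
        assert rmse < 1e-4

    def test_pure_polynomial_drift_yields_null_theta(self):
        config = SimulationConfig(seed=9, grid_shape=(16, 16), n_timepoints=10,
                                  displacement_nm=0.0, noise_std=0.0,
                                  drift_highorder_std=0.0, drift_poly_std=0.08)
        series, _ = simulate(config)
        basis = build_basis((16, 16), 2)
        result = fit(series, basis,
                     FitOptions(lambda_sparsity=0, auto_scale_lambda=False,
                                max_iterations=2000,
                                gradient_tolerance=1e-12))
        assert np.abs(result.theta).max() < 1e-3

    def test_indicator_complement_negates_theta(self, clean_sim):
        series, _, basis = clean_sim
        flipped = ComplexImageSeries(
            data=series.data, grid=series.grid,
            schedule=TriggerSchedule(
                tuple(1 - i for i in series.schedule.indicators)),
            params=series.params,
        )
        r1 = fit(series, basis)
        r2 = fit(flipped, basis)
        np.testing.assert_allclose(r2.theta, -r1.theta, atol=1e-6)

    def test_global_phase_invariance(self, clean_sim):
        series, truth, basis = clean_sim
        rotated = ComplexImageSeries(
            data=series.data * np.exp(1j * 0.7), grid=series.grid,
            schedule=series.schedule, params=series.params,
        )
        opts = FitOptions(lambda_sparsity=0, auto_scale_lambda=False,
                          max_iterations=2000, gradient_tolerance=1e-12)
        r1 = fit(series, basis, opts)
        r2 = fit(rotated, basis, opts)
        diff = np.abs(r2.theta - r1.theta)
        # strict agreement inside the object; air voxels carry almost no
        # data weight and converge correspondingly loosely
        assert diff[truth.brain_mask].max() < 1e-6
        assert diff.max() < 1e-4

    def test_loss_trace_monotone_nonincreasing(self, clean_sim):
        series, _, basis = clean_sim
        result = fit(series, basis)
        trace = np.array(result.loss_trace)
        tol = 1e-9 * np.maximum(np.abs(trace[:-1]), 1.0)
        assert np.all(np.diff(trace) <= tol)

    def test_shrinkage_monotone_in_lambda(self):
        # paper-scale amplitude; peak |θ̂| non-increasing over the λ grid
        config = SimulationConfig(seed=13, grid_shape=(16, 16), n_timepoints=8,
                                  noise_std=0.0, drift_highorder_std=0.0,
                                  drift_poly_std=0.02)
        series, _ = simulate(config)
        basis = build_basis((16, 16), 2)
        peaks = []
        for lam in (0.0, 10.0, 100.0, 1000.0, 10000.0):
            result = fit(series, basis,
                         FitOptions(lambda_sparsity=lam,
                                    auto_scale_lambda=False))
            peaks.append(np.abs(result.theta).max())
        for lo, hi in zip(peaks[1:], peaks[:-1]):
            assert lo <= hi + 1e-6

    def test_basis_grid_mismatch_rejected(self, clean_sim):
        series, _, _ = clean_sim
        with pytest.raises(ValidationError):
            fit(series, build_basis((8, 8), 2))

    def test_nonconvergence_reports_flag_not_exception(self, clean_sim):
        series, _, basis = clean_sim
        result = fit(series, basis, FitOptions(max_iterations=2))
        assert result.converged is False


class TestResultToMap:
    def _result_with_theta(self, theta, grid=None):
        from mrarfi import ModelFitResult

        return ModelFitResult(theta=theta, coeffs=np.zeros((2, 6)),
                              baseline=np.ones_like(theta, dtype=complex),
                              loss_trace=[0.0], converged=True,
                              lambda_resolved=0.0, grid=grid or Grid())

    def test_known_conversion(self, params):
        theta = np.full((2, 2), 0.015)
        dmap = result_to_map(self._result_with_theta(theta), params)
        np.testing.assert_allclose(dmap.values, 2.0e-7, rtol=0.01)

    def test_zero_theta_zero_map(self, params):
        dmap = result_to_map(self._result_with_theta(np.zeros((2, 2))), params)
        np.testing.assert_array_equal(dmap.values, 0.0)

    def test_doubling_gradient_halves_map(self, params):
        from mrarfi import AcquisitionParams

        theta = np.full((2, 2), 0.01)
        double_g = AcquisitionParams(meg_amplitude=80.0, meg_duration=7.0,
                                     us_frequency=0.65)
        d1 = result_to_map(self._result_with_theta(theta), params)
        d2 = result_to_map(self._result_with_theta(theta), double_g)
        np.testing.assert_allclose(d2.values, d1.values / 2)
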