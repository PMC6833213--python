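"""Offline stoichiometry identification: weights, criterion, closed form, search."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oursense import (
    DataQualityWarning,
    DegenerateFitError,
    InvalidInputError,
    InvalidModelError,
    OfflineDataset,
    OURSeries,
    compute_x_specific,
    discrete_stage_a_experiment,
    entropy_criterion,
    find_induction_time,
    fit_maintenance_polynomial,
    fit_strain,
    solve_stoichiometry,
    uncertainty_weight,
)
from oursense.model_core import discrete_cour_prediction


class TestUncertaintyWeight:
    @pytest.mark.parametrize(
        "k_exp, x, expected",
        [
            (1.0, 3.7, 1.0),  # plain least squares
            (0.0, 2.0, 0.25),  # variance proportional to X^2
            (0.4, 5.0, 0.424),  # Monod-form interpolation
        ],
    )
    def test_values(self, k_exp, x, expected):
        assert uncertainty_weight(x, k_exp) == pytest.approx(expected)

    def test_diverges_at_zero_biomass(self):
        with pytest.raises(InvalidInputError):
            uncertainty_weight(0.0, 0.4)
        assert uncertainty_weight(0.0, 1.0) == 1.0

    @given(x=st.floats(0.1, 50), k=st.floats(0, 1))
    def test_linear_interpolation_in_k_exp(self, x, k):
        """The weight interpolates linearly between the two limiting criteria."""
        w0 = uncertainty_weight(x, 0.0)
        w1 = uncertainty_weight(x, 1.0)
        assert uncertainty_weight(x, k) == pytest.approx(k * w1 + (1 - k) * w0, rel=1e-12)


class TestEntropyCriterion:
    def test_zero_for_exact_model_data(self, small_offline_dataset):
        ds = small_offline_dataset
        cour = discrete_cour_prediction(
            ds.sample_times, ds.biomass, ds.x0, alpha=1.7, k1=0.02, t_i=2.0
        )
        s = entropy_criterion(ds, cour, 1.7, 0.02, 2.0, 0.4).s_value
        assert s == pytest.approx(0.0, abs=1e-20)

    def test_hand_computed_three_sample_case(self, small_offline_dataset):
        # X=[1,2,4], X0=1, observations [0, 2.1, 6.3] vs alpha=2 growth model
        cour = np.array([0.0, 2.1, 6.3])
        s = entropy_criterion(
            small_offline_dataset, cour, alpha=2.0, k1=0.0, t_i=10.0, k_exp=1.0
        ).s_value
        assert s == pytest.approx(-0.10)

    def test_quadratic_scaling_of_residuals(self, small_offline_dataset):
        ds = small_offline_dataset
        pred = discrete_cour_prediction(ds.sample_times, ds.biomass, ds.x0, 2.0, 0.0, 10.0)
        resid = np.array([0.0, 0.1, 0.3])
        s1 = entropy_criterion(ds, pred + resid, 2.0, 0.0, 10.0, 1.0).s_value
        s2 = entropy_criterion(ds, pred + 2 * resid, 2.0, 0.0, 10.0, 1.0).s_value
        assert s2 == pytest.approx(4 * s1)
        assert s1 <= 0 and s2 <= 0

    def test_rejects_misaligned_observations(self, small_offline_dataset):
        with pytest.raises(InvalidInputError):
            entropy_criterion(small_offline_dataset, [0.0, 1.0], 1, 0, 1, 0.4)


class TestSolveStoichiometry:
    def test_single_phase_reduces_to_yield_ratio(self, small_offline_dataset):
        ds = small_offline_dataset
        cour = 1.5 * (ds.biomass - ds.x0)
        alpha, k1 = solve_stoichiometry(ds, cour, t_i=10.0, k_exp=0.4)
        assert alpha == pytest.approx(1.5)
        assert k1 == 0.0

    def test_exact_recovery_on_two_phase_data(self, exact_two_phase_experiment):
        ds, series = exact_two_phase_experiment
        cour = series.cour_at(ds.sample_times)
        alpha, k1 = solve_stoichiometry(ds, cour, t_i=10.0, k_exp=0.4)
        assert alpha == pytest.approx(1.01, rel=1e-9)
        assert k1 == pytest.approx(4e-3, rel=1e-9)

    def test_degenerate_when_biomass_never_grows(self):
        ds = OfflineDataset(
            sample_times=np.array([1.0, 2.0]), biomass=np.array([1.0, 1.0]), x0=1.0
        )
        with pytest.raises(DegenerateFitError):
            solve_stoichiometry(ds, np.array([0.1, 0.2]), t_i=0.5, k_exp=1.0)

    @pytest.mark.parametrize("k_exp", [0.0, 1.0])
    def test_limits_match_independent_least_squares(
        self, exact_two_phase_experiment, k_exp
    ):
        """k_exp=1 equals unweighted LSQ; k_exp=0 equals 1/X^2-weighted LSQ,
        both computed independently with numpy.linalg.lstsq."""
        ds, series = exact_two_phase_experiment
        cour = series.cour_at(ds.sample_times)
        rng = np.random.default_rng(7)
        cour = cour * (1 + 0.03 * rng.standard_normal(cour.size))
        t_i = 10.0
        from oursense.model_core import maintenance_riemann_terms

        design = np.column_stack(
            [ds.biomass - ds.x0, maintenance_riemann_terms(ds.sample_times, ds.biomass, t_i)]
        )
        w = 1.0 / ds.biomass**2 if k_exp == 0.0 else np.ones_like(ds.biomass)
        sw = np.sqrt(w)
        ref, *_ = np.linalg.lstsq(design * sw[:, None], cour * sw, rcond=None)
        alpha, k1 = solve_stoichiometry(ds, cour, t_i, k_exp)
        assert alpha == pytest.approx(ref[0], rel=1e-10)
        assert k1 == pytest.approx(ref[1], rel=1e-10)

    def test_closed_form_matches_brute_force_criterion_maximization(self):
        """On random small instances the closed form agrees with dense-grid +
        simplex maximization of the entropy criterion."""
        from scipy.optimize import minimize

        rng = np.random.default_rng(11)
        for _ in range(5):
            n = int(rng.integers(5, 13))
            t = np.sort(rng.uniform(0.5, 20, n)) + 0.01 * np.arange(n)
            x0 = float(rng.uniform(0.1, 0.5))
            x = np.sort(rng.uniform(x0 + 0.1, 30, n))
            t_i = float(t[rng.integers(0, n - 2)])
            k_exp = float(rng.uniform(0, 1))
            ds = OfflineDataset(sample_times=t, biomass=x, x0=x0)
            cour = discrete_cour_prediction(
                t, x, x0, float(rng.uniform(0.5, 2)), float(rng.uniform(1e-3, 2e-2)), t_i
            )
            cour = cour * (1 + 0.05 * rng.standard_normal(n))
            alpha_cf, k1_cf = solve_stoichiometry(ds, cour, t_i, k_exp)

            def neg_s(p):
                return -entropy_criterion(ds, cour, p[0], p[1], t_i, k_exp).s_value

            grid_a = np.linspace(0.2, 3.0, 21)
            grid_k = np.linspace(-0.05, 0.05, 21)
            vals = [[neg_s((a, k)) for k in grid_k] for a in grid_a]
            i, j = np.unravel_index(np.argmin(vals), (21, 21))
            res = minimize(
                neg_s,
                [grid_a[i], grid_k[j]],
                method="Nelder-Mead",
                options=dict(xatol=1e-12, fatol=1e-16, maxiter=5000),
            )
            assert res.x[0] == pytest.approx(alpha_cf, rel=1e-4)
            assert abs(res.x[1] - k1_cf) / max(abs(k1_cf), 1e-9) < 1e-4


class TestInductionTimeSearch:
    def test_recovers_true_activation_time(self):
        ds, series = discrete_stage_a_experiment(alpha=1.2, k1=6e-3, t_i=12.0)
        cour = series.cour_at(ds.sample_times)
        t_i, trace = find_induction_time(ds, cour, k_exp=0.4)
        assert t_i == 12.0
        assert trace == sorted(trace)
        # the criterion is exactly zero at the truth, negative elsewhere
        s_at_best = dict(trace)[12.0]
        assert s_at_best == pytest.approx(0.0, abs=1e-12)

    def test_flat_criterion_on_single_phase_data_warns(self, small_offline_dataset):
        ds = small_offline_dataset
        cour = 1.5 * (ds.biomass - ds.x0)
        with pytest.warns(DataQualityWarning):
            t_i, trace = find_induction_time(ds, cour, k_exp=1.0, candidates=[3.0])
        assert t_i == 3.0

    def test_ties_break_toward_earliest_candidate(self, small_offline_dataset):
        ds = small_offline_dataset
        cour = 1.5 * (ds.biomass - ds.x0)  # perfect single-phase fit: S=0 everywhere
        t_i, trace = find_induction_time(ds, cour, k_exp=1.0, candidates=[1.0, 2.0, 3.0])
        assert t_i == min(c for c, _ in trace)
        assert all(s == pytest.approx(0.0, abs=1e-24) for _, s in trace)

    def test_empty_candidates_rejected(self, small_offline_dataset):
        with pytest.raises(InvalidInputError):
            find_induction_time(
                small_offline_dataset, [0.0, 1.5, 4.5], k_exp=0.4, candidates=[]
            )


class TestMaintenanceRegression:
    def test_exact_line_recovery_with_published_yeast_coefficients(self):
        x = np.linspace(7, 25, 8)
        beta = 2.3851e-3 * x - 1.5014e-2
        model = fit_maintenance_polynomial(np.column_stack([x, beta]), degree=1)
        assert model.k_beta1 == pytest.approx(2.3851e-3, rel=1e-12)
        assert model.k_beta0 == pytest.approx(-1.5014e-2, rel=1e-12)
        assert model.x_specific == pytest.approx(6.29, abs=5e-3)

    def test_exact_parabola_recovery(self):
        x = np.linspace(21, 40, 9)
        beta = 7.2e-5 * x**2 - 2.9625e-3 * x + 4.27047e-2
        model = fit_maintenance_polynomial(np.column_stack([x, beta]), degree=2)
        assert model.k_beta2 == pytest.approx(7.2e-5, rel=1e-9)
        assert model.x_specific_from_stationary_point

    def test_matches_closed_form_simple_regression(self):
        x = np.array([1.0, 2.0, 4.0])
        b = np.array([0.1, 0.2, 0.45])
        model = fit_maintenance_polynomial(np.column_stack([x, b]), degree=1)
        # hand least squares: slope = cov/var, intercept = mean residual
        slope = np.sum((x - x.mean()) * (b - b.mean())) / np.sum((x - x.mean()) ** 2)
        intercept = b.mean() - slope * x.mean()
        assert model.k_beta1 == pytest.approx(slope, rel=1e-12)
        assert model.k_beta0 == pytest.approx(intercept, rel=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(InvalidInputError):
            fit_maintenance_polynomial(np.array([[1.0, 0.1], [1.0, 0.2]]), degree=1)


class TestXSpecific:
    def test_published_yeast_root(self):
        res = compute_x_specific(0.0, 2.3851e-3, -1.5014e-2, degree=1)
        assert res.value == pytest.approx(6.29, abs=5e-3)
        assert not res.from_stationary_point

    def test_published_ecoli_stationary_point_fallback(self):
        res = compute_x_specific(7.2e-5, -2.9625e-3, 4.27047e-2, degree=2)
        assert res.value == pytest.approx(20.6, abs=5e-2)
        assert res.from_stationary_point

    def test_unit_linear_root(self):
        assert compute_x_specific(0.0, 1.0, -10.0, degree=1).value == pytest.approx(10.0)

    def test_quadratic_with_real_roots_takes_largest(self):
        # beta = (X-2)(X-8) = X^2 - 10X + 16
        res = compute_x_specific(1.0, -10.0, 16.0, degree=2)
        assert res.value == pytest.approx(8.0)
        assert not res.from_stationary_point

    def test_invalid_models_rejected(self):
        with pytest.raises(InvalidModelError):
            compute_x_specific(0.0, 0.0, 1.0, degree=1)
        with pytest.raises(InvalidModelError):
            compute_x_specific(0.0, 1.0, 1.0, degree=1)  # negative root


class TestFitStrain:
    def test_noise_free_end_to_end_recovery(self, exact_two_phase_experiment):
        ds, series = exact_two_phase_experiment
        report = fit_strain([(ds, series)], k_exp=0.4)
        p = report.strain_parameters
        assert p.alpha == pytest.approx(1.01, rel=1e-6)
        assert p.k1 == pytest.approx(4e-3, rel=1e-6)
        assert p.t_i == pytest.approx(10.0, abs=1e-9)
        assert report.beta_samples.shape[0] > 0

    def test_pooling_replicates_is_idempotent(self, exact_two_phase_experiment):
        ds, series = exact_two_phase_experiment
        single = fit_strain([(ds, series)], k_exp=0.4).strain_parameters
        triple = fit_strain([(ds, series)] * 3, k_exp=0.4).strain_parameters
        assert triple.alpha == pytest.approx(single.alpha, rel=1e-12)
        assert triple.k1 == pytest.approx(single.k1, rel=1e-12)
        assert triple.t_i == single.t_i

    def test_known_induction_time_skips_search(self, exact_two_phase_experiment):
        ds, series = exact_two_phase_experiment
        report = fit_strain([(ds, series)], k_exp=0.4, induction_time=10.0)
        assert report.criterion_trace == []
        assert report.strain_parameters.alpha == pytest.approx(1.01, rel=1e-9)

    def test_median_alpha_error_under_multiplicative_noise(self):
        """5% multiplicative cOUR noise, seeds 0-19: median alpha error < 5%."""
        ds, series = discrete_stage_a_experiment(alpha=1.01, k1=4e-3, t_i=10.0)
        errors = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            cour = series.cour_values.copy()
            cour[1:] *= 1 + 0.05 * rng.standard_normal(cour.size - 1)
            noisy = OURSeries.from_cour(series.times, cour)
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")
                rep = fit_strain([(ds, noisy)], k_exp=0.4)
            errors.append(abs(rep.strain_parameters.alpha - 1.01) / 1.01)
        assert np.median(errors) < 0.05

    def test_errors_carry_experiment_label(self):
        ds = OfflineDataset(
            sample_times=np.array([1.0, 2.0]),
            biomass=np.array([1.0, 1.0]),
            x0=1.0,
            label="flat-run",
        )
        series = OURSeries.from_our([0.0, 1.0, 2.0], [0.1, 0.1, 0.1])
        with pytest.raises(DegenerateFitError, match="flat-run"):
            fit_strain([(ds, series)], k_exp=1.0, induction_time=1.5)
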