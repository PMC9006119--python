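"""Model simulation, predictive bands, and scoring metrics."""

import numpy as np
import pytest

import esindy as es
from esindy.library import ode_terms
from esindy.regression import SparseModel


def _linear_decay_model():
    terms = ode_terms(1, 1, names=["x"])  # [1, x]
    Xi = np.array([[0.0], [-1.0]])
    return SparseModel(Xi=Xi, terms=terms, state_names=["x"])


class TestSimulateModel:
    def test_exponential_decay_closed_form(self):
        traj = es.simulate_model(_linear_decay_model(), np.array([1.0]),
                                 np.linspace(0, 1, 11))
        assert abs(traj.y[-1, 0] - np.exp(-1)) < 1e-6
        assert not traj.diverged

    def test_empty_model_stays_constant(self):
        terms = ode_terms(1, 1, names=["x"])
        model = SparseModel(Xi=np.zeros((2, 1)), terms=terms,
                            state_names=["x"])
        traj = es.simulate_model(model, np.array([2.5]),
                                 np.linspace(0, 5, 6))
        np.testing.assert_allclose(traj.y, 2.5)

    def test_blow_up_flagged_not_raised(self):
        terms = ode_terms(1, 2, names=["x"])  # [1, x, x^2]
        Xi = np.array([[0.0], [0.0], [1.0]])  # x' = x^2 blows up at t = 1
        model = SparseModel(Xi=Xi, terms=terms, state_names=["x"])
        traj = es.simulate_model(model, np.array([1.0]),
                                 np.linspace(0, 2, 21))
        assert traj.diverged
        assert np.isnan(traj.y[-1, 0])

    def test_short_horizon_shadowing_of_recovered_lorenz(
            self, lorenz_library, lorenz_clean):
        model = es.stridge(lorenz_library, es.RegressionConfig(lambda1=0.1))
        t = np.linspace(0, 1.0, 101)
        traj = es.simulate_model(model, lorenz_clean.U[0], t)
        truth = lorenz_clean.U[:101]
        # chaotic error growth from the small differencing bias stays well
        # below the attractor scale over one time unit
        assert np.max(np.abs(traj.y - truth)) < 0.5


class TestEnsembleForecast:
    def test_identical_members_have_zero_width_band(self):
        model = _linear_decay_model()
        em = es.EnsembleModel(
            members=[model.Xi.copy() for _ in range(10)],
            availability=np.ones((10, 2), dtype=bool),
            inclusion=(model.Xi != 0).astype(float),
            aggregate=model)
        band = es.ensemble_forecast(em, np.array([1.0]),
                                    np.linspace(0, 1, 5),
                                    n_realizations=50, models_per_draw=5,
                                    rng=np.random.default_rng(1))
        np.testing.assert_allclose(band.upper, band.lower, atol=1e-12)

    def test_band_ordering_and_coverage_on_noisy_lotka_volterra(self):
        spec = es.SystemSpec("lotka_volterra", dt=0.02, m=500)
        clean = es.simulate_system(spec)
        noisy = es.add_noise(clean, es.NoiseSpec(level=0.05, seed=3))
        lib = es.build_ode_library(noisy, poly_order=2,
                                   diff_method="smoothed")
        em = es.fit_ensemble(lib, es.EnsembleConfig(q=50, mode="bagging",
                                                    seed=4),
                             es.RegressionConfig(lambda1=0.1,
                                                 normalize_columns=True))
        horizon = 60
        band = es.ensemble_forecast(
            em, clean.U[0], clean.t[:horizon], n_realizations=200,
            models_per_draw=5, level=0.95, rng=np.random.default_rng(5))
        assert np.all(band.lower <= band.median + 1e-12)
        assert np.all(band.median <= band.upper + 1e-12)
        inside = band.contains(clean.U[:horizon])
        assert inside.mean() >= 0.8

    def test_too_few_members_rejected(self):
        model = _linear_decay_model()
        em = es.EnsembleModel(
            members=[model.Xi], availability=np.ones((1, 2), dtype=bool),
            inclusion=(model.Xi != 0).astype(float), aggregate=model)
        with pytest.raises(ValueError, match="members"):
            es.ensemble_forecast(em, np.array([1.0]), np.linspace(0, 1, 3),
                                 models_per_draw=5)


class TestCoefficientError:
    @pytest.mark.parametrize("xi_hat, expected", [
        (np.array([3.0, 4.0]), 0.0),
        (np.array([0.0, 0.0]), 1.0),
        (np.array([3.0, 0.0]), 0.8),
    ])
    def test_hand_computed_values(self, xi_hat, expected):
        xi_true = np.array([3.0, 4.0])
        assert es.coefficient_error(xi_hat, xi_true) == \
            pytest.approx(expected)

    def test_scale_invariance(self, rng):
        a = rng.standard_normal((5, 2))
        b = rng.standard_normal((5, 2))
        assert es.coefficient_error(a, b) == \
            pytest.approx(es.coefficient_error(10 * a, 10 * b))

    def test_zero_truth_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            es.coefficient_error(np.ones(3), np.zeros(3))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            es.coefficient_error(np.ones(3), np.ones(4))


class TestSuccessRate:
    def _models(self, supports):
        terms = ode_terms(1, 3, names=["x"])  # 4 terms
        out = []
        for sup in supports:
            Xi = np.where(np.asarray(sup)[:, None], 1.0, 0.0)
            out.append(SparseModel(Xi=Xi, terms=terms, state_names=["x"]))
        return out

    def test_all_exact_matches(self):
        truth = np.array([[True], [False], [True], [False]])
        models = self._models([[1, 0, 1, 0]] * 3)
        assert es.success_rate(models, truth) == 1.0

    def test_one_spurious_term_in_one_of_four(self):
        truth = np.array([[True], [False], [True], [False]])
        models = self._models([[1, 0, 1, 0]] * 3 + [[1, 1, 1, 0]])
        assert es.success_rate(models, truth) == 0.75

    def test_per_term_mode_is_lenient(self):
        truth = np.array([[True], [False], [True], [False]])
        models = self._models([[1, 1, 1, 0]])
        assert es.success_rate(models, truth) == 0.0
        assert es.success_rate(models, truth, per_term=True) == 0.75

    def test_permutation_invariance(self):
        truth = np.array([[True], [False], [True], [False]])
        models = self._models([[1, 0, 1, 0], [1, 1, 1, 0], [0, 0, 0, 0]])
        assert es.success_rate(models, truth) == \
            es.success_rate(models[::-1], truth)
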