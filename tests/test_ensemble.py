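"""Bagging, bragging, library bagging, inclusion probabilities."""

import time

import numpy as np
import pytest

import esindy as es
from esindy.library import Library, ode_terms


def _identity_sampler(m, rng):
    return np.arange(m)


def _rigged_library(member_values=None, rng=None):
    """Tiny library whose single active column has coefficient 1."""
    rng = rng or np.random.default_rng(0)
    Theta = rng.standard_normal((30, 3))
    y = Theta[:, 1].copy()
    return Library(Theta=Theta, terms=ode_terms(2, 1)[:3],
                   target=y[:, None], state_names=["s"])


class TestBootstrapIndices:
    def test_single_row(self, rng):
        assert es.bootstrap_indices(1, rng).tolist() == [0]

    def test_deterministic_given_seed(self):
        a = es.bootstrap_indices(100, np.random.default_rng(9))
        b = es.bootstrap_indices(100, np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)

    def test_distinct_fraction_converges(self):
        # E[#distinct]/m -> 1 - 1/e for large m
        rng = np.random.default_rng(2024)
        fractions = [
            np.unique(es.bootstrap_indices(10_000, rng)).size / 10_000
            for _ in range(200)
        ]
        assert abs(np.mean(fractions) - (1 - np.exp(-1))) < 0.01


class TestFitEnsemble:
    def test_identity_resample_reproduces_plain_fit(self, lorenz_library):
        rconf = es.RegressionConfig(lambda1=0.1)
        plain = es.stridge(lorenz_library, rconf)
        em = es.fit_ensemble(
            lorenz_library, es.EnsembleConfig(q=1, mode="bagging", seed=0),
            rconf, index_sampler=_identity_sampler)
        np.testing.assert_array_equal(em.aggregate.Xi, plain.Xi)

    def test_clean_lorenz_true_terms_certain(self, lorenz_library,
                                             lorenz_truth):
        em = es.fit_ensemble(
            lorenz_library,
            es.EnsembleConfig(q=100, mode="bagging", seed=1),
            es.RegressionConfig(lambda1=0.1))
        assert np.all(em.inclusion[lorenz_truth != 0] == 1.0)

    def test_mean_vs_median_aggregation(self):
        lib = _rigged_library()
        rconf = es.RegressionConfig(lambda1=0.5)
        members = [np.array([[0.0], [1.0], [0.0]]),
                   np.array([[0.0], [1.0], [0.0]]),
                   np.array([[0.0], [100.0], [0.0]])]
        from esindy.ensemble import EnsembleModel, _aggregate
        inclusion = np.full((3, 1), 1.0)
        stack = np.stack(members)
        bag = _aggregate(stack, inclusion, "bagging", 0.65)
        brag = _aggregate(stack, inclusion, "bragging", 0.65)
        assert bag[1, 0] == pytest.approx(34.0)
        assert brag[1, 0] == pytest.approx(1.0)

    def test_bragging_breakdown_robustness(self, lorenz_library):
        # rigged fixture: identical members, a minority corrupted with
        # 100x outliers; the median aggregate is unchanged, the mean moves
        from esindy.ensemble import _aggregate

        rconf = es.RegressionConfig(lambda1=0.1)
        base = es.stridge(lorenz_library, rconf).Xi
        q = 11
        stack = np.tile(base, (q, 1, 1))
        stack[: q // 2] *= 100.0
        inclusion = (stack != 0).mean(axis=0)
        brag = _aggregate(stack, inclusion, "bragging", 0.65)
        bag = _aggregate(stack, inclusion, "bagging", 0.65)
        np.testing.assert_array_equal(brag, np.where(inclusion >= 0.65,
                                                     base, 0))
        assert np.max(np.abs(bag - base)) > 1.0

    def test_inclusion_permutation_invariance(self, lorenz_library):
        rconf = es.RegressionConfig(lambda1=0.1)
        em = es.fit_ensemble(
            lorenz_library, es.EnsembleConfig(q=20, mode="bagging", seed=4),
            rconf, index_sampler=_identity_sampler)
        perm = np.random.default_rng(0).permutation(lorenz_library.D)
        permuted = lorenz_library.subset(perm)
        em_p = es.fit_ensemble(
            permuted, es.EnsembleConfig(q=20, mode="bagging", seed=4),
            rconf, index_sampler=_identity_sampler)
        np.testing.assert_allclose(em_p.inclusion, em.inclusion[perm])


class TestLibraryEnsemble:
    def test_full_subsample_degenerates_to_plain_fit(self, lorenz_library):
        rconf = es.RegressionConfig(lambda1=0.1)
        plain = es.stridge(lorenz_library, rconf)
        em = es.fit_library_ensemble(
            lorenz_library,
            es.EnsembleConfig(q=5, mode="library-bagging",
                              l=lorenz_library.D, seed=5),
            rconf)
        assert set(np.unique(em.inclusion)) <= {0.0, 1.0}
        np.testing.assert_allclose(em.aggregate.Xi, plain.Xi, atol=1e-10)

    def test_offer_counts_match_hypergeometric_expectation(self,
                                                           lorenz_library):
        D, l, q = 20, 5, 400
        em = es.fit_library_ensemble(
            lorenz_library,
            es.EnsembleConfig(q=q, mode="library-bagging", l=l, seed=6),
            es.RegressionConfig(lambda1=0.1))
        offered = em.availability.sum(axis=0)
        expect = q * l / D
        assert np.all(np.abs(offered - expect) <= 3 * np.sqrt(expect))

    def test_clean_lorenz_inclusion_separates_truth(self, lorenz_library,
                                                    lorenz_truth):
        em = es.fit_library_ensemble(
            lorenz_library,
            es.EnsembleConfig(q=200, mode="library-bagging", l=14, seed=7),
            es.RegressionConfig(lambda1=0.1, normalize_columns=True))
        true_mask = lorenz_truth != 0
        assert np.all(em.inclusion[true_mask] >= 0.9)
        # members missing a governing column substitute correlated terms,
        # so spurious inclusion is nonzero but clearly separated
        assert np.all(em.inclusion[~true_mask] < 0.8)

    def test_oversized_subsample_rejected(self, lorenz_library):
        with pytest.raises(ValueError, match="exceeds"):
            es.fit_library_ensemble(
                lorenz_library,
                es.EnsembleConfig(q=2, mode="library-bagging",
                                  l=lorenz_library.D + 1, seed=0),
                es.RegressionConfig(lambda1=0.1))

    def test_member_cost_scales_with_subsample_size(self, rng):
        # least-squares member cost grows ~ l^2 at fixed rows: the largest
        # subsample must be measurably slower than the smallest
        M, D = 400, 128
        Theta = rng.standard_normal((M, D))
        y = Theta[:, 0] + 0.01 * rng.standard_normal(M)
        lib = Library(Theta=Theta, terms=ode_terms(1, D - 1),
                      target=y[:, None], state_names=["s"])
        rconf = es.RegressionConfig(lambda1=0.5)
        times = {}
        for l in (16, 64):
            t0 = time.perf_counter()
            es.fit_library_ensemble(
                lib, es.EnsembleConfig(q=30, mode="library-bagging", l=l,
                                       seed=1), rconf)
            times[l] = time.perf_counter() - t0
        assert times[64] > times[16]


class TestPrescreen:
    def test_zero_threshold_is_identity(self, lorenz_library):
        em = es.fit_library_ensemble(
            lorenz_library,
            es.EnsembleConfig(q=50, mode="library-bagging", l=10, seed=8),
            es.RegressionConfig(lambda1=0.1))
        sub = es.prescreen_library(lorenz_library, em, keep_tol=0.0)
        assert sub.D == lorenz_library.D

    def test_strict_threshold_keeps_only_truth(self, lorenz_library,
                                               lorenz_truth):
        # on clean data every bootstrap fit recovers the exact support, so
        # inclusion is exactly one on the true terms and zero elsewhere
        em = es.fit_ensemble(
            lorenz_library,
            es.EnsembleConfig(q=50, mode="bagging", seed=9),
            es.RegressionConfig(lambda1=0.1))
        sub = es.prescreen_library(lorenz_library, em, keep_tol=1.0)
        true_labels = {
            lorenz_library.terms[d].label
            for d in np.flatnonzero(np.any(lorenz_truth != 0, axis=1))
        }
        assert {t.label for t in sub.terms} == true_labels

    def test_impossible_threshold_raises(self, lorenz_library):
        em = es.fit_library_ensemble(
            lorenz_library,
            es.EnsembleConfig(q=20, mode="library-bagging", l=10, seed=10),
            es.RegressionConfig(lambda1=0.1))
        with pytest.raises(ValueError, match="lower threshold"):
            es.prescreen_library(lorenz_library, em, keep_tol=1.01)
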