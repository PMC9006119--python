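"""Weak-form assembly: geometry, manufactured solutions, convergence."""

import numpy as np
import pytest

import esindy as es
from esindy.library import TermSpec, pde_terms
from esindy.weak import TestFunctionSpec, assemble_weak_system, make_domains


def _plane_wave_field(n=256, m=256, L=2 * np.pi, T=2 * np.pi):
    x = np.linspace(0, L, n, endpoint=False)
    t = np.linspace(0, T, m)
    u = np.sin(x[:, None] - t[None, :])
    return es.Field(u=u, x=x, t=t)


class TestMakeDomains:
    def test_geometry(self):
        fld = es.Field(u=np.zeros((100, 100)),
                       x=np.linspace(0, 1, 100, endpoint=False),
                       t=np.linspace(0, 1, 100))
        dom = make_domains(fld, K=1, h_x=0.1, h_t=0.1, seed=0)
        assert dom.hw_x == 10 and dom.hw_t == 10
        assert dom.points_per_domain == 21 * 21
        ix, it = dom.centers[0]
        assert 10 <= ix <= 89 and 10 <= it <= 89

    def test_deterministic_given_seed(self):
        fld = es.Field(u=np.zeros((64, 64)),
                       x=np.linspace(0, 1, 64, endpoint=False),
                       t=np.linspace(0, 1, 64))
        a = make_domains(fld, 20, seed=3)
        b = make_domains(fld, 20, seed=3)
        np.testing.assert_array_equal(a.centers, b.centers)

    def test_capacity_exceeded(self):
        fld = es.Field(u=np.zeros((64, 64)),
                       x=np.linspace(0, 1, 64, endpoint=False),
                       t=np.linspace(0, 1, 64))
        with pytest.raises(ValueError, match="admissible"):
            make_domains(fld, K=10 ** 6)

    def test_too_small_domains_rejected(self):
        fld = es.Field(u=np.zeros((20, 20)),
                       x=np.linspace(0, 1, 20, endpoint=False),
                       t=np.linspace(0, 1, 20))
        with pytest.raises(ValueError, match="9x9"):
            make_domains(fld, K=1, h_x=0.05, h_t=0.05)


class TestAssembly:
    def test_constant_field_integrates_to_zero(self):
        x = np.linspace(0, 1, 64, endpoint=False)
        fld = es.Field(u=np.full((64, 64), 3.0), x=x,
                       t=np.linspace(0, 1, 64))
        ws = assemble_weak_system(fld, pde_terms(1, 2, 3), K=10, seed=1)
        np.testing.assert_allclose(ws.q0, 0.0, atol=1e-12)

    def test_insufficient_smoothness_rejected(self):
        fld = _plane_wave_field(64, 64)
        with pytest.raises(ValueError, match="boundary"):
            assemble_weak_system(fld, pde_terms(1, 1, 3),
                                 tf=TestFunctionSpec(p_x=2, p_t=3), K=10)

    def test_manufactured_advection_identity(self):
        # u = sin(x - t) satisfies u_t = -u_x: q0 must equal -Q[:, u_x]
        fld = _plane_wave_field()
        terms = [TermSpec("deriv-product", (0,), derivative_order=1,
                          label="u_x")]
        ws = assemble_weak_system(fld, terms, K=100, seed=2)
        np.testing.assert_allclose(ws.q0[:, 0], -ws.Q[:, 0],
                                   atol=1e-4 * np.abs(ws.q0).max())

    def test_quadrature_error_second_order(self):
        # doubling the grid shrinks the weak residual by >= 4x
        errs = []
        for n in (128, 256):
            fld = _plane_wave_field(n, n)
            terms = [TermSpec("deriv-product", (0,), derivative_order=1,
                              label="u_x")]
            ws = assemble_weak_system(fld, terms, K=50, seed=4)
            errs.append(np.linalg.norm(ws.q0[:, 0] + ws.Q[:, 0]))
        assert errs[0] / errs[1] >= 4.0

    def test_transfer_agrees_with_direct_derivative(self):
        # smooth field: integrating u_xx against w equals transferring both
        # derivatives onto w
        fld = _plane_wave_field()
        term = TermSpec("deriv-product", (0,), derivative_order=2,
                        label="u_xx")
        dom = make_domains(fld, 50, seed=5)
        tf = TestFunctionSpec(p_x=4, p_t=3)
        transferred = assemble_weak_system(fld, [term], tf=tf, domains=dom)
        direct = assemble_weak_system(fld, [TermSpec("monomial", (1,),
                                                     label="u")],
                                      tf=tf, domains=dom)
        # for u = sin(x - t), u_xx = -u
        np.testing.assert_allclose(transferred.Q[:, 0], -direct.Q[:, 0],
                                   atol=1e-4 * np.abs(direct.Q).max())

    def test_noise_variance_scales_inversely_with_points(self, rng):
        # pure-noise field: Var(q0) ~ 1 / points-per-domain
        variances = []
        for n in (64, 128):
            x = np.linspace(0, 1, n, endpoint=False)
            t = np.linspace(0, 1, n)
            u = rng.standard_normal((n, n))
            fld = es.Field(u=u, x=x, t=t)
            dom = make_domains(fld, 300, h_x=0.2, h_t=0.2, seed=6)
            ws = assemble_weak_system(fld, [TermSpec("monomial", (1,),
                                                     label="u")],
                                      domains=dom)
            variances.append(ws.q0[:, 0].var())
        ratio = variances[0] / variances[1]  # 4x fewer points -> 4x variance
        assert 2.0 < ratio < 8.0


class TestWeakFit:
    def test_clean_burgers_recovery(self, burgers_field, scalar_pde_terms):
        spec = es.SystemSpec("burgers_inviscid")
        xi_true = es.true_xi(spec, scalar_pde_terms)
        ws = assemble_weak_system(burgers_field, scalar_pde_terms, K=200,
                                  seed=1)
        model = es.weak_fit(ws, es.RegressionConfig(
            lambda1=0.1, lambda2=1e-6, normalize_columns=True))
        assert (model.support == (xi_true != 0)).all()
        labels = [t.label for t in scalar_pde_terms]
        coef = model.Xi[labels.index("u*u_x"), 0]
        assert abs(coef - (-1.0)) < 0.05

    def test_clean_kdv_recovery(self, kdv_field, scalar_pde_terms):
        from esindy.benchmark import weak_rconf

        spec = es.SystemSpec("kdv")
        xi_true = es.true_xi(spec, scalar_pde_terms)
        ws = assemble_weak_system(kdv_field, scalar_pde_terms, K=200, seed=1)
        model = es.weak_fit(ws, weak_rconf("kdv"))
        assert (model.support == (xi_true != 0)).all()
        labels = [t.label for t in scalar_pde_terms]
        assert abs(model.Xi[labels.index("u*u_x"), 0] + 6.0) < 0.3
        assert abs(model.Xi[labels.index("u_xxx"), 0] + 1.0) < 0.05

    def test_zero_target_gives_empty_model(self):
        x = np.linspace(0, 1, 64, endpoint=False)
        fld = es.Field(u=np.full((64, 64), 2.0), x=x,
                       t=np.linspace(0, 1, 64))
        ws = assemble_weak_system(fld, pde_terms(1, 1, 1), K=20, seed=2)
        with pytest.warns(UserWarning):
            model = es.weak_fit(ws, es.RegressionConfig(lambda1=0.1))
        assert model.n_active == 0

    def test_underdetermined_system_warns(self, burgers_field,
                                          scalar_pde_terms):
        ws = assemble_weak_system(burgers_field, scalar_pde_terms, K=10,
                                  seed=3)
        with pytest.warns(UserWarning, match="underdetermined"):
            es.weak_fit(ws, es.RegressionConfig(
                lambda1=0.1, normalize_columns=True))
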