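"""Weak (integral) formulation of PDE discovery.

Each candidate term is multiplied by a compactly supported separable test
function w(x,t) = (1-s^2)^p_x (1-r^2)^p_t on a rectangular subdomain and
integrated; integration by parts moves derivatives off the (noisy) data
and onto the smooth test function wherever algebraically possible.
Stacking K subdomains gives the linear system q0 = Q Xi, which replaces
the pointwise regression and averages measurement noise over each
subdomain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from numpy.polynomial import polynomial as npoly

from .core import Field
from .library import Library, TermSpec
from .regression import RegressionConfig, SparseModel, stridge


@dataclass
class TestFunctionSpec:
    """Smoothness exponents of the separable polynomial test function.

    ``p_x`` must exceed the highest spatial derivative order in the
    library so that every integration by parts leaves zero boundary
    terms; ``p_t`` >= 2 covers the single time-derivative transfer.
    """

    p_x: int = 5
    p_t: int = 3

    def __post_init__(self):
        if self.p_t < 2:
            raise ValueError("p_t must be >= 2")
        if self.p_x < 1:
            raise ValueError("p_x must be >= 1")

    def validate_for(self, max_deriv: int) -> None:
        if self.p_x < max_deriv + 1:
            raise ValueError(
                f"p_x={self.p_x} too small for derivative order "
                f"{max_deriv}: boundary terms would not vanish "
                f"(need p_x >= {max_deriv + 1})"
            )


@dataclass
class DomainSet:
    """K rectangular subdomains centred on interior grid points."""

    centers: np.ndarray   # (K, 2) int indices (ix, it)
    hw_x: int             # half-width in x grid points
    hw_t: int             # half-width in t grid points
    seed: int = 0

    @property
    def K(self) -> int:
        return self.centers.shape[0]

    @property
    def points_per_domain(self) -> int:
        return (2 * self.hw_x + 1) * (2 * self.hw_t + 1)


@dataclass
class WeakSystem:
    """Integrated linear system q0 = Q Xi over K test-function/domain pairs."""

    Q: np.ndarray         # (K, D)
    q0: np.ndarray        # (K, n_comp)
    terms: list[TermSpec]
    tf: TestFunctionSpec
    domains: DomainSet
    state_names: list[str]

    def __post_init__(self):
        if not np.all(np.isfinite(self.Q)) or not np.all(np.isfinite(self.q0)):
            raise ValueError("non-finite entries in weak system")
        if self.Q.shape[0] != self.domains.K:
            raise ValueError("rows of Q do not align with domains")


def make_domains(
    fld: Field, K: int, h_x: float = 0.1, h_t: float = 0.1, seed: int = 0,
) -> DomainSet:
    """Draw K interior subdomain centres uniformly without replacement.

    ``h_x`` and ``h_t`` are half-widths as fractions of the full spatial
    and temporal extent; every subdomain must contain at least 9 x 9 grid
    points and lie strictly inside the field.
    """
    if not (0 < h_x < 0.5 and 0 < h_t < 0.5):
        raise ValueError("h_x and h_t must lie in (0, 0.5)")
    hw_x = int(round(h_x * (fld.n_x - 1)))
    hw_t = int(round(h_t * (fld.m - 1)))
    if hw_x < 4 or hw_t < 4:
        raise ValueError(
            "subdomains must contain at least 9x9 grid points; increase "
            "h_x/h_t or refine the grid"
        )
    ix_lo, ix_hi = hw_x, fld.n_x - 1 - hw_x
    it_lo, it_hi = hw_t, fld.m - 1 - hw_t
    n_ix = ix_hi - ix_lo + 1
    n_it = it_hi - it_lo + 1
    admissible = n_ix * n_it
    if K > admissible:
        raise ValueError(
            f"K={K} exceeds the {admissible} admissible interior centres"
        )
    rng = np.random.default_rng(seed)
    flat = rng.choice(admissible, size=K, replace=False)
    centers = np.column_stack([ix_lo + flat // n_it, it_lo + flat % n_it])
    return DomainSet(centers=centers, hw_x=hw_x, hw_t=hw_t, seed=seed)


def _testfn_profiles(p: int, hw: int, scale: float, orders: Sequence[int]):
    """(1-s^2)^p and requested derivatives on the 2*hw+1 local points.

    ``scale`` converts d/ds to d/d(physical coordinate).
    """
    s = np.linspace(-1.0, 1.0, 2 * hw + 1)
    base = npoly.polypow([1.0, 0.0, -1.0], p)
    out = {}
    for j in sorted(set(orders)):
        coef = npoly.polyder(base, j) if j else base
        out[j] = npoly.polyval(s, coef) * scale ** j
    return out


def _trap_weights(n: int, h: float) -> np.ndarray:
    w = np.full(n, h)
    w[0] = w[-1] = h / 2.0
    return w


def assemble_weak_system(
    fld: Field, terms: Sequence[TermSpec],
    tf: Optional[TestFunctionSpec] = None,
    domains: Optional[DomainSet] = None,
    K: Optional[int] = None, seed: int = 0,
    lowpass_frac: float = 0.15,
) -> WeakSystem:
    """Integrate every library term against test functions on each domain.

    The time-derivative side is always transferred: q0_k = -int u w_t.
    Pure spatial derivatives are transferred entirely onto w; first-order
    derivatives of a pure power of the same component use the conservative
    form u^a u_x = (u^(a+1))_x / (a+1); remaining products are integrated
    directly, with the derivative factor evaluated spectrally once on the
    full grid.

    Differentiating raw data amplifies measurement noise by k^d, so the
    direct path differentiates a band-limited projection of the field:
    only the lowest ``lowpass_frac`` of spatial modes are retained
    (periodic fields; set to 1 to disable).  Transferred and conservative
    terms never differentiate the data and are unaffected.
    """
    terms = list(terms)
    max_d = max((tm.derivative_order for tm in terms), default=0)
    if tf is None:
        tf = TestFunctionSpec(p_x=max_d + 2, p_t=3)
    tf.validate_for(max_d)
    if domains is None:
        domains = make_domains(fld, K=K if K else 2 * len(terms), seed=seed)
    complex_field = np.iscomplexobj(fld.u)
    n_comp = fld.n_comp

    # global derivative fields needed by the "direct" path
    from .library import spatial_derivative

    if fld.periodic and lowpass_frac < 1.0:
        k = np.fft.fftfreq(fld.n_x)
        keep = np.abs(k) <= lowpass_frac * np.abs(k).max()
        u_hat = np.fft.fft(fld.u, axis=0)
        u_filt = np.fft.ifft(keep.reshape((-1,) + (1,) * (fld.u.ndim - 1))
                             * u_hat, axis=0)
        if not complex_field:
            u_filt = u_filt.real
        fld_smooth = Field(u=u_filt, x=fld.x, t=fld.t, periodic=True)
    else:
        fld_smooth = fld

    direct_derivs: dict[tuple[int, int], np.ndarray] = {}
    for tm in terms:
        d, c = tm.derivative_order, tm.derivative_component
        if d == 0:
            continue
        pure_power = (
            tm.kind == "deriv-product"
            and sum(tm.exponents) == tm.exponents[c]
        )
        transferable = tm.kind in ("deriv-product", "modulus-monomial") and \
            sum(tm.exponents) == 0
        conservative = tm.kind == "deriv-product" and d == 1 and \
            pure_power and tm.exponents[c] >= 1
        if not (transferable or conservative):
            direct_derivs[(c, d)] = spatial_derivative(fld_smooth, c, d)

    scale_x = 1.0 / (domains.hw_x * fld.dx)
    scale_t = 1.0 / (domains.hw_t * fld.dt)
    phi_x = _testfn_profiles(tf.p_x, domains.hw_x, scale_x,
                             orders=list(range(max_d + 1)))
    phi_t = _testfn_profiles(tf.p_t, domains.hw_t, scale_t, orders=[0, 1])
    qx = _trap_weights(2 * domains.hw_x + 1, fld.dx)
    qt = _trap_weights(2 * domains.hw_t + 1, fld.dt)
    # combined quadrature x test-function weights, shape (n_loc_x, n_loc_t)
    W = {j: np.outer(qx * phi_x[j], qt * phi_t[0]) for j in phi_x}
    W_t = np.outer(qx * phi_x[0], qt * phi_t[1])

    dtype = complex if complex_field else float
    Q = np.zeros((domains.K, len(terms)), dtype=dtype)
    q0 = np.zeros((domains.K, n_comp), dtype=dtype)

    for kdx, (ix, it) in enumerate(domains.centers):
        sx = slice(ix - domains.hw_x, ix + domains.hw_x + 1)
        st = slice(it - domains.hw_t, it + domains.hw_t + 1)
        local = [fld.component(c)[sx, st] for c in range(n_comp)]
        for c in range(n_comp):
            q0[kdx, c] = -np.sum(local[c] * W_t)
        for jdx, tm in enumerate(terms):
            d, c = tm.derivative_order, tm.derivative_component
            if tm.kind == "modulus-monomial":
                b = tm.exponents[0]
                if b == 0:
                    Q[kdx, jdx] = (-1) ** d * np.sum(local[0] * W[d])
                else:
                    f = np.abs(local[0]) ** (2 * b)
                    g = (local[0] if d == 0
                         else direct_derivs[(0, d)][sx, st])
                    Q[kdx, jdx] = np.sum(f * g * W[0])
                continue
            mono = None
            for cc, e in enumerate(tm.exponents):
                if e:
                    fac = local[cc] ** e
                    mono = fac if mono is None else mono * fac
            if d == 0:
                F = mono if mono is not None else 1.0
                Q[kdx, jdx] = np.sum(F * W[0]) if mono is not None \
                    else np.sum(W[0])
            elif mono is None:
                # pure derivative: transfer all d parts onto w
                Q[kdx, jdx] = (-1) ** d * np.sum(local[c] * W[d])
            elif d == 1 and sum(tm.exponents) == tm.exponents[c]:
                # conservative form: u^a u_x = (u^(a+1))_x / (a+1)
                a = tm.exponents[c]
                Q[kdx, jdx] = -np.sum(local[c] ** (a + 1) * W[1]) / (a + 1)
            else:
                F = mono * direct_derivs[(c, d)][sx, st]
                Q[kdx, jdx] = np.sum(F * W[0])

    names = ["u"] if n_comp == 1 else [chr(ord("u") + i) for i in range(n_comp)]
    return WeakSystem(Q=Q, q0=q0, terms=terms, tf=tf, domains=domains,
                      state_names=names)


def weak_fit(ws: WeakSystem, config: RegressionConfig) -> SparseModel:
    """Sparse fit of the integrated system (delegates to STRidge)."""
    if ws.domains.K < len(ws.terms):
        warnings.warn(
            f"K={ws.domains.K} subdomains for D={len(ws.terms)} terms; the "
            "least-squares problem is underdetermined",
            stacklevel=2,
        )
    lib = Library(Theta=ws.Q, terms=ws.terms, target=ws.q0,
                  state_names=ws.state_names)
    return stridge(lib, config)


def weak_library(ws: WeakSystem) -> Library:
    """The weak system viewed as a regression Library (for ensembling)."""
    return Library(Theta=ws.Q, terms=ws.terms, target=ws.q0,
                   state_names=ws.state_names)
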