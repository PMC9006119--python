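"""Candidate-function libraries for ODE and PDE discovery.

Builds the feature matrix Theta whose columns are candidate right-hand-side
terms (polynomials, optional trigonometric terms, and for PDEs products of
monomials with spatial derivatives), together with the matched regression
target (the numerically differentiated time derivative).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Optional, Sequence

import numpy as np
from scipy.signal import savgol_filter

from .core import Field, TimeSeries

VALID_KINDS = (
    "constant",
    "monomial",
    "sin",
    "cos",
    "deriv-product",
    "modulus-monomial",
)


@dataclass(frozen=True)
class TermSpec:
    """One library column.

    ``exponents`` are per-state monomial powers.  For ``deriv-product``
    terms the column is (monomial in the states) x (d-th spatial derivative
    of component ``derivative_component``); ``modulus-monomial`` terms are
    |u|^(2*exponents[0]) * d-th derivative of u, used for complex fields.
    """

    kind: str
    exponents: tuple[int, ...]
    derivative_order: int = 0
    derivative_component: int = 0
    label: str = ""

    def __post_init__(self):
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown term kind {self.kind!r}")
        if any(e < 0 for e in self.exponents):
            raise ValueError("exponents must be non-negative")
        if self.derivative_order < 0:
            raise ValueError("derivative order must be non-negative")

    @property
    def total_degree(self) -> int:
        return sum(self.exponents)


@dataclass
class Library:
    """Feature matrix with aligned term descriptors and regression target."""

    Theta: np.ndarray  # (M, D)
    terms: list[TermSpec]
    target: np.ndarray  # (M, n)
    state_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.Theta.shape[1] != len(self.terms):
            raise ValueError("Theta columns do not align with terms")
        if self.Theta.shape[0] != self.target.shape[0]:
            raise ValueError("target rows do not align with Theta rows")
        for arr, what in ((self.Theta, "Theta"), (self.target, "target")):
            if not np.all(np.isfinite(arr)):
                j = np.argwhere(~np.isfinite(arr))[0]
                name = (
                    self.terms[j[1]].label if what == "Theta" else f"state {j[1]}"
                )
                raise ValueError(f"non-finite value in {what} ({name})")

    @property
    def D(self) -> int:
        return len(self.terms)

    @property
    def n_targets(self) -> int:
        return self.target.shape[1]

    def subset(self, indices: Sequence[int]) -> "Library":
        """Sub-library restricted to the given term indices (order kept)."""
        idx = list(indices)
        return Library(
            Theta=self.Theta[:, idx],
            terms=[self.terms[i] for i in idx],
            target=self.target,
            state_names=list(self.state_names),
        )


# --------------------------------------------------------------------------
# term enumeration
# --------------------------------------------------------------------------

def monomial_exponents(n: int, poly_order: int) -> list[tuple[int, ...]]:
    """All exponent tuples of total degree <= poly_order, graded lexicographic.

    Within each total degree, terms are ordered so earlier states carry
    higher powers first (x^2, x*y, y^2 for n=2, degree 2).
    """
    out: list[tuple[int, ...]] = []
    for deg in range(poly_order + 1):
        for combo in combinations_with_replacement(range(n), deg):
            e = [0] * n
            for i in combo:
                e[i] += 1
            out.append(tuple(e))
    return out


def _monomial_label(exponents: tuple[int, ...], names: Sequence[str]) -> str:
    parts = []
    for e, name in zip(exponents, names):
        if e == 1:
            parts.append(name)
        elif e > 1:
            parts.append(f"{name}^{e}")
    return "*".join(parts) if parts else "1"


def ode_terms(
    n: int, poly_order: int, include_trig: bool = False,
    names: Optional[Sequence[str]] = None,
) -> list[TermSpec]:
    """Enumerate ODE library terms: monomials then optional sin/cos."""
    if poly_order < 1:
        raise ValueError("poly_order must be >= 1")
    names = list(names) if names else [f"x{i}" for i in range(n)]
    terms = []
    for e in monomial_exponents(n, poly_order):
        kind = "constant" if sum(e) == 0 else "monomial"
        terms.append(TermSpec(kind, e, label=_monomial_label(e, names)))
    if include_trig:
        for fn in ("sin", "cos"):
            for i in range(n):
                e = tuple(1 if j == i else 0 for j in range(n))
                terms.append(TermSpec(fn, e, label=f"{fn} {names[i]}"))
    return terms


def evaluate_ode_terms(terms: Sequence[TermSpec], X: np.ndarray) -> np.ndarray:
    """Evaluate ODE terms at states X (..., n) -> features (..., D)."""
    X = np.asarray(X, dtype=float)
    cols = []
    for term in terms:
        if term.kind in ("constant", "monomial"):
            col = np.ones(X.shape[:-1])
            for i, e in enumerate(term.exponents):
                if e:
                    col = col * X[..., i] ** e
        elif term.kind in ("sin", "cos"):
            i = term.exponents.index(1)
            col = getattr(np, term.kind)(X[..., i])
        else:
            raise ValueError(f"term {term.label!r} is not an ODE term")
        cols.append(col)
    return np.stack(cols, axis=-1)


def pde_terms(
    n_comp: int, poly_order: int, max_deriv: int,
    names: Optional[Sequence[str]] = None,
) -> list[TermSpec]:
    """PDE library terms: monomial x (optional spatial-derivative factor).

    D = C(n_comp + poly_order, poly_order) * (n_comp * max_deriv + 1).
    """
    names = list(names) if names else (
        ["u"] if n_comp == 1 else [chr(ord("u") + i) for i in range(n_comp)]
    )
    deriv_factors: list[Optional[tuple[int, int]]] = [None]
    for c in range(n_comp):
        for d in range(1, max_deriv + 1):
            deriv_factors.append((c, d))
    terms = []
    for e in monomial_exponents(n_comp, poly_order):
        for fac in deriv_factors:
            mono = _monomial_label(e, names)
            if fac is None:
                kind = "constant" if sum(e) == 0 else "monomial"
                terms.append(TermSpec(kind, e, label=mono))
            else:
                c, d = fac
                dlabel = f"{names[c]}_{'x' * d}"
                label = dlabel if mono == "1" else f"{mono}*{dlabel}"
                terms.append(
                    TermSpec("deriv-product", e, derivative_order=d,
                             derivative_component=c, label=label)
                )
    return terms


def complex_pde_terms(poly_order: int, max_deriv: int) -> list[TermSpec]:
    """Library for a complex scalar field: |u|^(2b) * d^d u / dx^d."""
    terms = []
    for b in range(poly_order + 1):
        for d in range(max_deriv + 1):
            mono = "|u|^2" if b == 1 else f"|u|^{2 * b}"
            dlabel = "u" if d == 0 else f"u_{'x' * d}"
            label = dlabel if b == 0 else f"{mono}*{dlabel}"
            terms.append(
                TermSpec("modulus-monomial", (b,), derivative_order=d,
                         label=label)
            )
    return terms


# --------------------------------------------------------------------------
# numerical differentiation in time
# --------------------------------------------------------------------------

def differentiate_time(
    series: TimeSeries, method: str = "centered",
    window: int = 7, polyorder: int = 3,
) -> np.ndarray:
    """Time derivative of the snapshot matrix, (m, n).

    ``centered`` uses second-order centered differences on the interior and
    second-order one-sided stencils at the two endpoints, so every sample
    stays usable.  ``smoothed`` first applies a fixed-window local-polynomial
    (Savitzky–Golay) filter to each state, then differences — useful for
    short noisy records.
    """
    if series.m < 3:
        raise ValueError("need at least 3 samples to differentiate")
    if method not in ("centered", "smoothed"):
        raise ValueError(f"unknown differentiation method {method!r}")
    if not series.is_uniform():
        raise ValueError(
            "time grid is not uniform; resample to a uniform grid before "
            "using the centered scheme"
        )
    U = series.U
    if method == "smoothed":
        w = min(window, series.m if series.m % 2 == 1 else series.m - 1)
        p = min(polyorder, w - 1)
        U = savgol_filter(U, window_length=w, polyorder=p, axis=0)
    return np.gradient(U, series.dt, axis=0, edge_order=2)


# --------------------------------------------------------------------------
# library builders
# --------------------------------------------------------------------------

def build_ode_library(
    series: TimeSeries, poly_order: int, include_trig: bool = False,
    diff_method: str = "centered", derivative: Optional[np.ndarray] = None,
) -> Library:
    """Candidate library Theta(U) and target dU/dt for an ODE fit.

    ``derivative`` overrides the numerically differentiated target (used
    when the caller has access to exact derivatives).
    """
    terms = ode_terms(series.n, poly_order, include_trig, series.names)
    Theta = evaluate_ode_terms(terms, series.U)
    if derivative is None:
        derivative = differentiate_time(series, method=diff_method)
    return Library(Theta=Theta, terms=terms, target=np.asarray(derivative),
                   state_names=list(series.names))


def spatial_derivative(fld: Field, component: int, order: int) -> np.ndarray:
    """d-th spatial derivative of one component, (n_x, m).

    Spectral differentiation for periodic fields, repeated second-order
    finite differences otherwise.
    """
    u = fld.component(component)
    if order == 0:
        return u
    if fld.periodic:
        k = 2.0 * np.pi * np.fft.fftfreq(fld.n_x, d=fld.dx)
        mult = (1j * k) ** order
        du = np.fft.ifft(mult[:, None] * np.fft.fft(u, axis=0), axis=0)
        return du if np.iscomplexobj(u) else du.real
    du = u
    for _ in range(order):
        du = np.gradient(du, fld.dx, axis=0, edge_order=2)
    return du


def time_derivative(fld: Field, component: int = 0) -> np.ndarray:
    """Centered-difference du/dt for one component, (n_x, m)."""
    return np.gradient(fld.component(component), fld.dt, axis=1, edge_order=2)


def evaluate_pde_term(fld: Field, term: TermSpec) -> np.ndarray:
    """Evaluate one PDE term on the full grid, (n_x, m)."""
    if term.kind == "modulus-monomial":
        u = fld.component(0)
        col = np.abs(u) ** (2 * term.exponents[0]) if term.exponents[0] else 1.0
        return col * spatial_derivative(fld, 0, term.derivative_order)
    col = np.ones((fld.n_x, fld.m))
    for c, e in enumerate(term.exponents):
        if e:
            col = col * fld.component(c) ** e
    if term.kind == "deriv-product":
        col = col * spatial_derivative(
            fld, term.derivative_component, term.derivative_order
        )
    return col


def build_pde_library(
    fld: Field, max_deriv: int, poly_order: int,
) -> Library:
    """Pointwise PDE library: rows are grid points, flattened time-major.

    Retained as a diagnostic baseline; the weak formulation supersedes it
    for noisy data.
    """
    if max_deriv > 4:
        raise ValueError("max_deriv above 4 is not supported")
    if fld.n_x < 2 * max_deriv + 1:
        raise ValueError(
            f"grid too coarse for derivative order {max_deriv}: need at "
            f"least {2 * max_deriv + 1} spatial points"
        )
    complex_field = np.iscomplexobj(fld.u)
    if complex_field:
        terms = complex_pde_terms(poly_order, max_deriv)
    else:
        terms = pde_terms(fld.n_comp, poly_order, max_deriv)

    def flat(a: np.ndarray) -> np.ndarray:
        return np.transpose(a).ravel()  # time-major: row = it * n_x + ix

    Theta = np.column_stack(
        [np.broadcast_to(evaluate_pde_term(fld, tm), (fld.n_x, fld.m)).T.ravel()
         for tm in terms]
    )
    target = np.column_stack(
        [flat(time_derivative(fld, c)) for c in range(fld.n_comp)]
    )
    names = ["u"] if fld.n_comp == 1 else [
        chr(ord("u") + i) for i in range(fld.n_comp)
    ]
    return Library(Theta=Theta, terms=terms, target=target, state_names=names)
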