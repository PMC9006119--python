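"""Synthetic benchmark systems with known governing equations.

Generators for the chaotic Lorenz system, Lotka-Volterra predator-prey
dynamics, and five canonical 1-D PDEs (inviscid Burgers, Korteweg-de Vries,
nonlinear Schrödinger, Kuramoto-Sivashinsky, and a lambda-omega
reaction-diffusion system), each with its ground-truth coefficient matrix
on a declared candidate library.  Measurement noise is additive i.i.d.
Gaussian with standard deviation expressed as a fraction of each signal's
root-mean-square amplitude.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import fsolve

from .core import ControlledTimeSeries, Field, TimeSeries
from .library import TermSpec

SYSTEM_NAMES = (
    "lorenz",
    "lotka_volterra",
    "burgers_inviscid",
    "kdv",
    "nls",
    "kuramoto_sivashinsky",
    "reaction_diffusion",
)

DEFAULT_PARAMS = {
    "lorenz": {"sigma": 10.0, "rho": 28.0, "beta": 8.0 / 3.0},
    "lotka_volterra": {"a": 1.0, "b": 0.1, "c": 1.5, "d": 0.075},
    "burgers_inviscid": {},
    "kdv": {},
    "nls": {},
    "kuramoto_sivashinsky": {},
    "reaction_diffusion": {"d": 0.1, "beta": 1.0},
}

LORENZ_IC_BOX = np.array([[-20.0, 20.0], [-20.0, 20.0], [0.0, 40.0]])


@dataclass
class SystemSpec:
    """Declaration of one benchmark system and its sampling grid."""

    name: str
    params: dict = field(default_factory=dict)
    dt: float = 0.01
    m: int = 1000
    x0: Optional[np.ndarray] = None      # ODE initial state
    n_x: int = 256                        # PDE spatial points
    L: Optional[float] = None             # PDE domain length
    transient: float = 0.0                # discarded spin-up time

    def __post_init__(self):
        if self.name not in SYSTEM_NAMES:
            raise ValueError(f"unknown system {self.name!r}")
        merged = dict(DEFAULT_PARAMS[self.name])
        merged.update(self.params)
        self.params = merged
        if self.dt <= 0 or self.m < 2:
            raise ValueError("grid must have positive dt and m >= 2")

    @property
    def is_pde(self) -> bool:
        return self.name not in ("lorenz", "lotka_volterra")


@dataclass
class NoiseSpec:
    """Additive Gaussian noise, std = level x RMS of the clean signal."""

    level: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.level < 0:
            raise ValueError("noise level must be non-negative")


# --------------------------------------------------------------------------
# ODE right-hand sides
# --------------------------------------------------------------------------

def lorenz_rhs(t, s, sigma, rho, beta):
    x, y, z = s
    return [sigma * (y - x), x * (rho - z) - y, x * y - beta * z]


def lotka_volterra_rhs(t, s, a, b, c, d):
    x, y = s
    return [a * x - b * x * y, -c * y + d * x * y]


def lorenz_fixed_points(sigma: float = 10.0, rho: float = 28.0,
                        beta: float = 8.0 / 3.0) -> np.ndarray:
    """Non-origin equilibria of the Lorenz system, by root solve.

    Returns a (2, 3) array; for the classical parameters these are
    (+-sqrt(72), +-sqrt(72), 27).
    """
    def f(s):
        return lorenz_rhs(0.0, s, sigma, rho, beta)

    guess = np.sqrt(beta * (rho - 1))
    pts = []
    for sign in (+1.0, -1.0):
        sol = fsolve(f, [sign * guess * 1.1, sign * guess * 0.9, rho],
                     xtol=1e-14, full_output=False)
        pts.append(sol)
    return np.array(pts)


# --------------------------------------------------------------------------
# spectral time steppers
# --------------------------------------------------------------------------

def _etdrk4_coeffs(L: np.ndarray, h: float, n_contour: int = 32):
    """Kassam-Trefethen contour-integral evaluation of the ETDRK4 phi
    weights, stable for small |h L|."""
    E = np.exp(h * L)
    E2 = np.exp(h * L / 2.0)
    r = np.exp(1j * np.pi * (np.arange(1, n_contour + 1) - 0.5) / n_contour)
    LR = h * L[..., None] + r
    Q = h * np.mean((np.exp(LR / 2.0) - 1.0) / LR, axis=-1)
    f1 = h * np.mean(
        (-4.0 - LR + np.exp(LR) * (4.0 - 3.0 * LR + LR ** 2)) / LR ** 3, axis=-1)
    f2 = h * np.mean(
        (2.0 + LR + np.exp(LR) * (-2.0 + LR)) / LR ** 3, axis=-1)
    f3 = h * np.mean(
        (-4.0 - 3.0 * LR - LR ** 2 + np.exp(LR) * (4.0 - LR)) / LR ** 3, axis=-1)
    if np.isrealobj(L):
        Q, f1, f2, f3 = (np.real(a) for a in (Q, f1, f2, f3))
    return E, E2, Q, f1, f2, f3


def _etdrk4_run(v0: np.ndarray, L: np.ndarray, nonlinear: Callable,
                h: float, n_steps: int, store_every: int) -> np.ndarray:
    """Integrate v' = L v + N(v) in Fourier space; returns stored states."""
    E, E2, Q, f1, f2, f3 = _etdrk4_coeffs(L, h)
    v = v0.copy()
    out = [v.copy()]
    for step in range(1, n_steps + 1):
        Nv = nonlinear(v)
        a = E2 * v + Q * Nv
        Na = nonlinear(a)
        b = E2 * v + Q * Na
        Nb = nonlinear(b)
        c = E2 * a + Q * (2.0 * Nb - Nv)
        Nc = nonlinear(c)
        v = E * v + f1 * Nv + 2.0 * f2 * (Na + Nb) + f3 * Nc
        if step % store_every == 0:
            out.append(v.copy())
    return np.array(out)


def _wavenumbers(n_x: int, L: float) -> np.ndarray:
    return 2.0 * np.pi * np.fft.fftfreq(n_x, d=L / n_x)


# --------------------------------------------------------------------------
# simulators
# --------------------------------------------------------------------------

def _simulate_ode(spec: SystemSpec) -> TimeSeries:
    if spec.name == "lorenz":
        rhs, names = lorenz_rhs, ["x", "y", "z"]
        x0 = spec.x0 if spec.x0 is not None else np.array([-8.0, 8.0, 27.0])
        args = tuple(spec.params[k] for k in ("sigma", "rho", "beta"))
    else:
        rhs, names = lotka_volterra_rhs, ["x", "y"]
        x0 = spec.x0 if spec.x0 is not None else np.array([20.0, 5.0])
        args = tuple(spec.params[k] for k in ("a", "b", "c", "d"))
    t0 = spec.transient
    t = t0 + spec.dt * np.arange(spec.m)
    sol = solve_ivp(rhs, (0.0, t[-1]), np.asarray(x0, dtype=float),
                    t_eval=t, args=args, method="RK45",
                    rtol=1e-10, atol=1e-12)
    if not sol.success:
        raise RuntimeError(f"integration of {spec.name} failed: {sol.message}")
    return TimeSeries(U=sol.y.T, t=t - t0, names=names)


def _simulate_burgers(spec: SystemSpec) -> Field:
    L = spec.L or 2.0 * np.pi
    x = L * np.arange(spec.n_x) / spec.n_x
    u0 = np.sin(2.0 * np.pi * x / L)
    k = _wavenumbers(spec.n_x, L)
    u0x = np.real(np.fft.ifft(1j * k * np.fft.fft(u0)))
    t_shock = -1.0 / u0x.min()
    horizon = spec.dt * (spec.m - 1)
    if horizon >= 0.95 * t_shock:
        raise ValueError(
            f"requested horizon {horizon:.3g} reaches the shock; latest "
            f"safe horizon is {0.95 * t_shock:.3g}"
        )
    dealias = np.abs(k) < (2.0 / 3.0) * np.abs(k).max()

    def rhs(t, u):
        u_hat = np.fft.fft(u)
        ux = np.real(np.fft.ifft(1j * k * u_hat * dealias))
        return -u * ux

    t = spec.dt * np.arange(spec.m)
    sol = solve_ivp(rhs, (0.0, t[-1]), u0, t_eval=t, method="RK45",
                    rtol=1e-10, atol=1e-12)
    if not sol.success:
        raise RuntimeError(f"Burgers integration failed: {sol.message}")
    return Field(u=sol.y, x=x, t=t, periodic=True)


def _simulate_kdv(spec: SystemSpec) -> Field:
    # classical interacting-soliton benchmark on a periodic interval
    L = spec.L or 2.0 * np.pi
    x = -L / 2.0 + L * np.arange(spec.n_x) / spec.n_x
    A, B = 25.0, 16.0
    u0 = (3.0 * A ** 2 / np.cosh(0.5 * A * (x + 2.0)) ** 2
          + 3.0 * B ** 2 / np.cosh(0.5 * B * (x + 1.0)) ** 2)
    k = _wavenumbers(spec.n_x, L)
    Lop = 1j * k ** 3  # from -u_xxx
    dealias = np.abs(k) < (2.0 / 3.0) * np.abs(k).max()
    g = -3j * k * dealias

    def nonlinear(v):
        u = np.real(np.fft.ifft(v))
        return g * np.fft.fft(u ** 2)  # -6 u u_x = -3 (u^2)_x

    h, store = _substeps(spec.dt, 2.5e-6)
    v = _etdrk4_run(np.fft.fft(u0), Lop, nonlinear, h, (spec.m - 1) * store,
                    store)
    u = np.real(np.fft.ifft(v, axis=1)).T
    return Field(u=u, x=x, t=spec.dt * np.arange(spec.m), periodic=True)


def _simulate_ks(spec: SystemSpec) -> Field:
    L = spec.L or 32.0 * np.pi
    x = L * np.arange(spec.n_x) / spec.n_x
    u0 = np.cos(2.0 * np.pi * x / L) * (1.0 + np.sin(2.0 * np.pi * x / L))
    k = _wavenumbers(spec.n_x, L)
    Lop = k ** 2 - k ** 4
    dealias = np.abs(k) < (2.0 / 3.0) * np.abs(k).max()
    g = -0.5j * k * dealias

    def nonlinear(v):
        u = np.real(np.fft.ifft(v))
        return g * np.fft.fft(u ** 2)

    h, store = _substeps(spec.dt, 0.05)
    v0 = np.fft.fft(u0)
    n_trans = int(round(spec.transient / h))
    if n_trans:
        v0 = _etdrk4_run(v0, Lop, nonlinear, h, n_trans, n_trans)[-1]
    v = _etdrk4_run(v0, Lop, nonlinear, h, (spec.m - 1) * store, store)
    u = np.real(np.fft.ifft(v, axis=1)).T
    return Field(u=u, x=x, t=spec.dt * np.arange(spec.m), periodic=True)


def _simulate_nls(spec: SystemSpec) -> Field:
    # focusing NLS: u_t = (i/2) u_xx + i |u|^2 u, split-step Fourier
    L = spec.L or 20.0 * np.pi
    x = -L / 2.0 + L * np.arange(spec.n_x) / spec.n_x
    u0 = 2.0 / np.cosh(x)
    k = _wavenumbers(spec.n_x, L)
    h, store = _substeps(spec.dt, 1e-3)
    u = u0.astype(complex)
    half_linear = np.exp(0.25j * (-k ** 2) * h)  # i/2 u_xx for half a step
    out = [u.copy()]
    for step in range(1, (spec.m - 1) * store + 1):
        u = np.fft.ifft(half_linear * np.fft.fft(u))
        u = u * np.exp(1j * np.abs(u) ** 2 * h)
        u = np.fft.ifft(half_linear * np.fft.fft(u))
        if step % store == 0:
            out.append(u.copy())
    return Field(u=np.array(out).T, x=x, t=spec.dt * np.arange(spec.m),
                 periodic=True)


def _simulate_reaction_diffusion(spec: SystemSpec) -> Field:
    # lambda-omega system on a periodic 1-D grid: spiral-wave kinetics
    d = spec.params["d"]
    beta = spec.params["beta"]
    L = spec.L or 20.0
    x = -L / 2.0 + L * np.arange(spec.n_x) / spec.n_x
    u0 = np.tanh(np.sqrt(x ** 2)) * np.cos(2.0 * np.pi * x / L * 2.0)
    v0 = np.tanh(np.sqrt(x ** 2)) * np.sin(2.0 * np.pi * x / L * 2.0)
    k = _wavenumbers(spec.n_x, L)
    Lop = np.stack([1.0 - d * k ** 2, 1.0 - d * k ** 2])
    dealias = np.abs(k) < (2.0 / 3.0) * np.abs(k).max()

    def nonlinear(v_hat):
        u = np.real(np.fft.ifft(v_hat[0]))
        v = np.real(np.fft.ifft(v_hat[1]))
        a2 = u ** 2 + v ** 2
        nu = -a2 * u + beta * a2 * v
        nv = -beta * a2 * u - a2 * v
        return np.stack([np.fft.fft(nu) * dealias, np.fft.fft(nv) * dealias])

    h, store = _substeps(spec.dt, 0.02)
    v0_hat = np.stack([np.fft.fft(u0), np.fft.fft(v0)])
    traj = _etdrk4_run(v0_hat, Lop, nonlinear, h, (spec.m - 1) * store, store)
    uv = np.real(np.fft.ifft(traj, axis=2))  # (m, 2, n_x)
    u = np.transpose(uv, (2, 0, 1))          # (n_x, m, 2)
    return Field(u=u, x=x, t=spec.dt * np.arange(spec.m), periodic=True)


def _substeps(dt_sample: float, dt_max: float) -> tuple[float, int]:
    """Integrator step h and store interval so samples land on the grid."""
    store = max(1, int(np.ceil(dt_sample / dt_max)))
    return dt_sample / store, store


_PDE_DEFAULTS = {
    "burgers_inviscid": dict(dt=0.004, m=101, n_x=256, L=2 * np.pi),
    "kdv": dict(dt=2e-5, m=151, n_x=256, L=2 * np.pi),
    "nls": dict(dt=0.01, m=251, n_x=256, L=20 * np.pi),
    "kuramoto_sivashinsky": dict(dt=0.4, m=251, n_x=256, L=32 * np.pi,
                                 transient=50.0),
    "reaction_diffusion": dict(dt=0.05, m=201, n_x=128, L=20.0),
}


def default_spec(name: str, **overrides) -> SystemSpec:
    """SystemSpec with the packaged desk-scale defaults for ``name``."""
    kw = dict(_PDE_DEFAULTS.get(name, {}))
    kw.update(overrides)
    return SystemSpec(name=name, **kw)


def simulate_system(spec: SystemSpec) -> Union[TimeSeries, Field]:
    """Clean simulation of the declared system on its sampling grid."""
    if spec.name in ("lorenz", "lotka_volterra"):
        return _simulate_ode(spec)
    return {
        "burgers_inviscid": _simulate_burgers,
        "kdv": _simulate_kdv,
        "nls": _simulate_nls,
        "kuramoto_sivashinsky": _simulate_ks,
        "reaction_diffusion": _simulate_reaction_diffusion,
    }[spec.name](spec)


# --------------------------------------------------------------------------
# ground-truth coefficients
# --------------------------------------------------------------------------

def _truth_table(name: str, params: dict) -> list[dict[str, float]]:
    """Per-state {term label: coefficient} for the governing equations."""
    p = dict(DEFAULT_PARAMS[name])
    p.update(params)
    if name == "lorenz":
        return [
            {"x": -p["sigma"], "y": p["sigma"]},
            {"x": p["rho"], "y": -1.0, "x*z": -1.0},
            {"x*y": 1.0, "z": -p["beta"]},
        ]
    if name == "lotka_volterra":
        return [
            {"x": p["a"], "x*y": -p["b"]},
            {"y": -p["c"], "x*y": p["d"]},
        ]
    if name == "burgers_inviscid":
        return [{"u*u_x": -1.0}]
    if name == "kdv":
        return [{"u*u_x": -6.0, "u_xxx": -1.0}]
    if name == "kuramoto_sivashinsky":
        return [{"u*u_x": -1.0, "u_xx": -1.0, "u_xxxx": -1.0}]
    if name == "nls":
        return [{"u_xx": 0.5j, "|u|^2*u": 1j}]
    if name == "reaction_diffusion":
        b, d = p["beta"], p["d"]
        return [
            {"u": 1.0, "u^3": -1.0, "u*v^2": -1.0, "u^2*v": b, "v^3": b,
             "u_xx": d},
            {"v": 1.0, "v^3": -1.0, "u^2*v": -1.0, "u^3": -b, "u*v^2": -b,
             "v_xx": d},
        ]
    raise ValueError(f"unknown system {name!r}")


def true_xi(spec: SystemSpec, terms: Sequence[TermSpec]) -> np.ndarray:
    """Ground-truth coefficient matrix of ``spec`` on the given library.

    Raises if a governing term is missing from the library (the truth must
    lie in the candidate span for recovery experiments to be meaningful).
    """
    table = _truth_table(spec.name, spec.params)
    labels = [tm.label for tm in terms]
    dtype = complex if spec.name == "nls" else float
    Xi = np.zeros((len(terms), len(table)), dtype=dtype)
    for i, row in enumerate(table):
        for label, coeff in row.items():
            if label not in labels:
                raise ValueError(
                    f"library is missing governing term {label!r} of "
                    f"{spec.name}"
                )
            Xi[labels.index(label), i] = coeff
    return Xi


def true_support(spec: SystemSpec, terms: Sequence[TermSpec]) -> np.ndarray:
    """Boolean (D, n) ground-truth support mask."""
    return true_xi(spec, terms) != 0


# --------------------------------------------------------------------------
# noise and initial conditions
# --------------------------------------------------------------------------

def add_noise(data: Union[TimeSeries, Field], noise: NoiseSpec):
    """Additive Gaussian noise, per-component std = level x clean RMS."""
    if noise.level == 0:
        return data
    rng = np.random.default_rng(noise.seed)
    if isinstance(data, TimeSeries):
        rms = np.sqrt(np.mean(data.U ** 2, axis=0))
        noisy = data.U + noise.level * rms * rng.standard_normal(data.U.shape)
        out = dataclasses.replace(data, U=noisy)
        return out
    u = data.u
    axes = (0, 1)
    rms = np.sqrt(np.mean(np.abs(u) ** 2, axis=axes))
    if np.iscomplexobj(u):
        eps = (rng.standard_normal(u.shape) + 1j * rng.standard_normal(u.shape))
        eps /= np.sqrt(2.0)
    else:
        eps = rng.standard_normal(u.shape)
    return dataclasses.replace(data, u=u + noise.level * rms * eps)


def sample_initial_condition(
    region: np.ndarray, rng: np.random.Generator,
) -> np.ndarray:
    """Uniform draw from an (n, 2) bounding box of [low, high] rows."""
    region = np.asarray(region, dtype=float)
    if region.ndim != 2 or region.shape[1] != 2:
        raise ValueError("region must be an (n, 2) array of [low, high]")
    return rng.uniform(region[:, 0], region[:, 1])
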