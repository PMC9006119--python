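"""Model simulation, probabilistic ensemble forecasts and scoring.

Identified sparse models are integrated with an adaptive Runge-Kutta
scheme; ensembles yield empirical predictive bands by repeatedly drawing
a few members, averaging their coefficients, and simulating.  Scoring
uses the relative coefficient error and the exact-support success rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .ensemble import EnsembleModel
from .regression import SparseModel
from .library import evaluate_ode_terms

logger = logging.getLogger("esindy")

DIVERGENCE_BOUND = 1e6


@dataclass
class Trajectory:
    t: np.ndarray
    y: np.ndarray          # (len(t), n); NaN rows after a divergence
    diverged: bool = False


@dataclass
class ForecastBand:
    """Pointwise median and empirical quantile band of an ensemble forecast."""

    t: np.ndarray
    median: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float
    n_realizations: int
    models_per_draw: int
    n_divergent: int = 0

    def __post_init__(self):
        ok = np.isfinite(self.lower) & np.isfinite(self.upper)
        if not np.all(self.lower[ok] <= self.median[ok] + 1e-12):
            raise ValueError("band ordering violated: lower > median")
        if not np.all(self.median[ok] <= self.upper[ok] + 1e-12):
            raise ValueError("band ordering violated: median > upper")

    def contains(self, y: np.ndarray) -> np.ndarray:
        """Boolean (len(t), n): does the band bracket these values?"""
        return (y >= self.lower) & (y <= self.upper)


@dataclass
class EvalReport:
    """Per-realization support successes and coefficient errors."""

    success: np.ndarray
    Ec: np.ndarray

    @property
    def success_rate(self) -> float:
        return float(np.mean(self.success))

    @property
    def median_Ec(self) -> float:
        return float(np.median(self.Ec))


def _make_rhs(model: SparseModel):
    active = np.flatnonzero(np.any(model.Xi != 0, axis=1))
    terms = [model.terms[d] for d in active]
    Xi = np.real(model.Xi[active])

    def rhs(t, x):
        if not terms:
            return np.zeros_like(x)
        return evaluate_ode_terms(terms, x) @ Xi

    return rhs


def simulate_model(
    model: SparseModel, x0: np.ndarray, t_grid: np.ndarray,
    rtol: float = 1e-8, atol: float = 1e-10,
) -> Trajectory:
    """Integrate dx/dt = Theta(x) Xi on ``t_grid`` (adaptive RK45).

    A state excursion beyond |x| = 1e6 truncates the trajectory, which is
    returned flagged as divergent rather than raising.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    rhs = _make_rhs(model)

    def blow_up(t, x):
        return np.max(np.abs(x)) - DIVERGENCE_BOUND

    blow_up.terminal = True
    sol = solve_ivp(rhs, (t_grid[0], t_grid[-1]), x0, t_eval=t_grid,
                    method="RK45", rtol=rtol, atol=atol, events=blow_up)
    y = np.full((t_grid.size, x0.size), np.nan)
    got = sol.y.shape[1]
    y[:got] = sol.y.T
    diverged = bool(sol.status == 1) or (not sol.success) or got < t_grid.size
    return Trajectory(t=t_grid, y=y, diverged=diverged)


def ensemble_forecast(
    em: EnsembleModel, x0: np.ndarray, t_grid: np.ndarray,
    n_realizations: int = 1000, models_per_draw: int = 5,
    level: float = 0.95, rng: Optional[np.random.Generator] = None,
) -> ForecastBand:
    """Predictive band: draw ``models_per_draw`` members with replacement,
    average their coefficients, simulate, and take pointwise quantiles
    over realizations.  Divergent realizations are excluded (counted)."""
    if rng is None:
        rng = np.random.default_rng(0)
    if em.q < models_per_draw:
        raise ValueError(
            f"ensemble has {em.q} members, fewer than models_per_draw="
            f"{models_per_draw}"
        )
    stack = em.member_stack()
    trajs, n_div = [], 0
    for _ in range(n_realizations):
        draw = rng.integers(0, em.q, size=models_per_draw)
        Xi = stack[draw].mean(axis=0)
        model = SparseModel(Xi=Xi, terms=em.aggregate.terms,
                            state_names=em.aggregate.state_names)
        traj = simulate_model(model, x0, t_grid)
        if traj.diverged:
            n_div += 1
            continue
        trajs.append(traj.y)
    if n_div:
        logger.info("ensemble_forecast: excluded %d divergent realizations",
                    n_div)
    if not trajs:
        raise RuntimeError("every forecast realization diverged")
    Y = np.stack(trajs, axis=0)
    alpha = (1.0 - level) / 2.0
    return ForecastBand(
        t=np.asarray(t_grid, dtype=float),
        median=np.quantile(Y, 0.5, axis=0),
        lower=np.quantile(Y, alpha, axis=0),
        upper=np.quantile(Y, 1.0 - alpha, axis=0),
        level=level, n_realizations=n_realizations,
        models_per_draw=models_per_draw, n_divergent=n_div,
    )


def coefficient_error(Xi_hat: np.ndarray, Xi_true: np.ndarray) -> float:
    """Relative coefficient error ||Xi_true - Xi_hat|| / ||Xi_true||,
    entrywise (Frobenius) 2-norm over the vectorized matrices."""
    Xi_hat = np.asarray(Xi_hat)
    Xi_true = np.asarray(Xi_true)
    if Xi_hat.shape != Xi_true.shape:
        raise ValueError(
            f"shape mismatch: {Xi_hat.shape} vs {Xi_true.shape}")
    denom = np.linalg.norm(Xi_true)
    if denom == 0:
        raise ValueError("true coefficient matrix is identically zero")
    return float(np.linalg.norm(Xi_true - Xi_hat) / denom)


def success_rate(
    models: Sequence[SparseModel], true_support: np.ndarray,
    per_term: bool = False,
) -> float:
    """Fraction of fits recovering the correct support.

    Strict (default): a fit succeeds only when its nonzero/zero pattern
    matches ``true_support`` exactly.  ``per_term=True`` instead averages
    per-term correctness within each fit before averaging over fits.
    """
    true_support = np.asarray(true_support, dtype=bool)
    scores = []
    for model in models:
        match = model.support == true_support
        scores.append(match.mean() if per_term else float(match.all()))
    return float(np.mean(scores))
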