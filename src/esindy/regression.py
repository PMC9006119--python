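"""Sequentially thresholded least squares and ridge regression.

The sparsity-promoting solver at the heart of model discovery: iterate
{ ridge fit on the active columns; drop coefficients below the threshold
lambda1; refit } until the support stabilizes, then refit the surviving
terms without regularization.  With lambda2 = 0 the scheme is plain
sequentially thresholded least squares (STLS); lambda2 > 0 gives STRidge,
which copes better with the highly correlated columns of PDE libraries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .library import Library, TermSpec


@dataclass
class RegressionConfig:
    lambda1: float = 0.1          # hard threshold on coefficient magnitude
    lambda2: float = 0.0          # ridge weight; 0 reduces STRidge to STLS
    max_iter: int = 10
    normalize_columns: bool = False

    def __post_init__(self):
        if self.lambda1 <= 0:
            raise ValueError("lambda1 must be positive")
        if self.lambda2 < 0:
            raise ValueError("lambda2 must be non-negative")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class SparseModel:
    """Coefficient matrix Xi (D x n) over a fixed term ordering."""

    Xi: np.ndarray
    terms: list[TermSpec]
    state_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.Xi = np.atleast_2d(np.asarray(self.Xi))
        if self.Xi.shape[0] != len(self.terms):
            raise ValueError("Xi rows do not align with terms")
        if not self.state_names:
            self.state_names = [f"x{i}" for i in range(self.Xi.shape[1])]

    @property
    def support(self) -> np.ndarray:
        """Boolean (D, n) mask of nonzero coefficients."""
        return self.Xi != 0

    @property
    def n_active(self) -> int:
        return int(np.count_nonzero(self.Xi))

    def equation_strings(self) -> list[str]:
        """Human-readable right-hand sides, one per state."""
        out = []
        for i, name in enumerate(self.state_names):
            parts = [
                f"{self.Xi[d, i]:+.4g} {tm.label}"
                for d, tm in enumerate(self.terms)
                if self.Xi[d, i] != 0
            ]
            rhs = " ".join(parts) if parts else "0"
            out.append(f"d{name}/dt = {rhs}")
        return out


def ridge_solve(Theta: np.ndarray, y: np.ndarray, lambda2: float = 0.0) -> np.ndarray:
    """Minimize ||y - Theta xi||^2 + lambda2 ||xi||^2.

    lambda2 = 0 returns the minimum-norm least-squares solution via a
    rank-revealing solver; lambda2 > 0 solves the equivalent augmented
    least-squares system, which is always well posed.
    """
    Theta = np.asarray(Theta)
    y = np.asarray(y)
    if Theta.ndim != 2:
        raise ValueError("Theta must be 2-D")
    squeeze = y.ndim == 1
    Y = y.reshape(-1, 1) if squeeze else y
    if lambda2 == 0.0:
        xi, *_ = np.linalg.lstsq(Theta, Y, rcond=None)
    else:
        D = Theta.shape[1]
        aug_T = np.vstack([Theta, np.sqrt(lambda2) * np.eye(D, dtype=Theta.dtype)])
        aug_y = np.vstack([Y, np.zeros((D, Y.shape[1]), dtype=Y.dtype)])
        xi, *_ = np.linalg.lstsq(aug_T, aug_y, rcond=None)
    return xi[:, 0] if squeeze else xi


def stridge(library: Library, config: RegressionConfig) -> SparseModel:
    """Sequentially thresholded ridge regression over all target states.

    Per state: iterate ridge fits, removing (strictly) sub-threshold
    coefficients, until the support is unchanged or ``max_iter`` is
    reached; then refit the final support by unregularized least squares.
    Column normalization (unit l2, with the target normalized likewise
    during thresholding) makes ``lambda1`` a dimensionless contribution
    threshold, comparable across columns and targets of very different
    scales; coefficients are reported on the original scale.
    """
    Theta = library.Theta
    M, D = Theta.shape
    if config.normalize_columns:
        norms = np.linalg.norm(Theta, axis=0)
        norms = np.where(norms == 0, 1.0, norms)
        Theta_n = Theta / norms
    else:
        norms = np.ones(D)
        Theta_n = Theta
    dtype = np.result_type(Theta, library.target)
    Xi = np.zeros((D, library.n_targets), dtype=dtype)
    any_empty = False
    for i in range(library.n_targets):
        y = library.target[:, i]
        if config.normalize_columns:
            ynorm = np.linalg.norm(y)
            y_n = y / ynorm if ynorm > 0 else y
        else:
            y_n = y
        active = np.ones(D, dtype=bool)
        xi_n = ridge_solve(Theta_n, y_n, config.lambda2)
        for _ in range(config.max_iter):
            keep = np.abs(xi_n) >= config.lambda1  # ties at lambda1 kept
            new_active = active & keep
            if new_active.sum() == 0:
                active = new_active
                break
            if np.array_equal(new_active, active):
                break
            active = new_active
            xi_n = np.zeros(D, dtype=dtype)
            xi_n[active] = ridge_solve(Theta_n[:, active], y_n, config.lambda2)
        if active.sum() == 0:
            any_empty = True
            continue
        # final unregularized refit on the surviving support, original scale
        xi = np.zeros(D, dtype=dtype)
        xi[active] = ridge_solve(Theta[:, active], y, 0.0)
        Xi[:, i] = xi
    if any_empty:
        warnings.warn(
            "all coefficients thresholded for at least one state; "
            "returning empty support (lower lambda1 to keep terms)",
            stacklevel=2,
        )
    return SparseModel(Xi=Xi, terms=list(library.terms),
                       state_names=list(library.state_names))
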