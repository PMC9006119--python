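"""Ensemble sparse model discovery: bagging, bragging and library bagging.

An ensemble of sparse fits on bootstrapped regression rows (bagging), with
median aggregation (bragging), or on random subsets of library columns
(library bagging).  The fraction of members in which each term is active
gives its inclusion probability, which is used both to threshold the
aggregate model and to prescreen large libraries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .library import Library
from .regression import RegressionConfig, SparseModel, stridge

MODES = ("bagging", "bragging", "library-bagging")


@dataclass
class EnsembleConfig:
    q: int = 100                  # ensemble size
    mode: str = "bagging"
    l: int = 0                    # library subsample size (library mode); 0 = ceil(D/2)
    inclusion_tol: float = 0.65   # inclusion-probability threshold
    seed: int = 0
    bootstrap_rows: bool = False  # library mode: additionally bootstrap rows
    refit_aggregate: bool = False  # refit selected support on the full data

    def __post_init__(self):
        if self.q < 1:
            raise ValueError("ensemble size q must be >= 1")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if not 0.0 <= self.inclusion_tol <= 1.0:
            raise ValueError("inclusion_tol must lie in [0, 1]")


@dataclass
class EnsembleModel:
    """q member coefficient matrices with inclusion probabilities.

    Members are zero-padded to the full library in library-bagging mode;
    ``availability[j, d]`` records whether term d was offered to member j.
    """

    members: list[np.ndarray]          # q arrays, each (D, n)
    availability: np.ndarray           # (q, D) bool
    inclusion: np.ndarray              # (D, n) in [0, 1]
    aggregate: SparseModel

    def __post_init__(self):
        if np.any(self.inclusion < 0) or np.any(self.inclusion > 1):
            raise ValueError("inclusion probabilities must lie in [0, 1]")

    @property
    def q(self) -> int:
        return len(self.members)

    def member_stack(self) -> np.ndarray:
        """(q, D, n) array of member coefficients."""
        return np.stack(self.members, axis=0)

    def coefficient_std(self) -> np.ndarray:
        """(D, n) member standard deviation of each coefficient."""
        return self.member_stack().std(axis=0)


def bootstrap_indices(m: int, rng: np.random.Generator) -> np.ndarray:
    """m i.i.d. uniform draws on {0..m-1}, with replacement."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return rng.integers(0, m, size=m)


def _fit_member(lib: Library, rconf: RegressionConfig) -> np.ndarray:
    """One sparse fit; failures yield an empty member with a warning."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return stridge(lib, rconf).Xi
    except np.linalg.LinAlgError as exc:  # pragma: no cover - rare
        warnings.warn(f"member fit failed ({exc}); recording empty model",
                      stacklevel=3)
        return np.zeros((lib.D, lib.n_targets))


def _aggregate(
    stack: np.ndarray, inclusion: np.ndarray, mode: str,
    inclusion_tol: float, weights: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Mean/median over members, then zero low-inclusion entries."""
    if mode == "bragging":
        agg = np.median(stack, axis=0)
    elif weights is not None:
        denom = np.maximum(weights.sum(axis=0), 1)[:, None]
        agg = (stack * weights[:, :, None]).sum(axis=0) / denom
    else:
        agg = stack.mean(axis=0)
    agg = np.where(inclusion >= inclusion_tol, agg, 0)
    return agg


def fit_ensemble(
    library: Library, econf: EnsembleConfig, rconf: RegressionConfig,
    index_sampler: Optional[Callable[[int, np.random.Generator], np.ndarray]] = None,
    rng: Optional[np.random.Generator] = None,
) -> EnsembleModel:
    """B(r)agging: bootstrap regression rows jointly in (Theta, target).

    ``index_sampler`` overrides the bootstrap (e.g. an identity resample
    in tests); rows of the feature matrix and target are resampled as
    pairs so derivative stencils are never broken.
    """
    if rng is None:
        rng = np.random.default_rng(econf.seed)
    if index_sampler is None:
        index_sampler = bootstrap_indices
    M = library.Theta.shape[0]
    members = []
    for _ in range(econf.q):
        idx = index_sampler(M, rng)
        boot = Library(
            Theta=library.Theta[idx], terms=library.terms,
            target=library.target[idx], state_names=library.state_names,
        )
        members.append(_fit_member(boot, rconf))
    stack = np.stack(members, axis=0)
    inclusion = (stack != 0).mean(axis=0)
    mode = econf.mode if econf.mode in ("bagging", "bragging") else "bagging"
    agg = _aggregate(stack, inclusion, mode, econf.inclusion_tol)
    aggregate = SparseModel(Xi=agg, terms=list(library.terms),
                            state_names=list(library.state_names))
    availability = np.ones((econf.q, library.D), dtype=bool)
    return EnsembleModel(members=members, availability=availability,
                         inclusion=inclusion, aggregate=aggregate)


def fit_library_ensemble(
    library: Library, econf: EnsembleConfig, rconf: RegressionConfig,
    rng: Optional[np.random.Generator] = None,
) -> EnsembleModel:
    """Library bagging: each member sees l of D columns, drawn without
    replacement; inclusion is normalized by how often a term was offered."""
    if rng is None:
        rng = np.random.default_rng(econf.seed)
    D = library.D
    l = econf.l if econf.l > 0 else int(np.ceil(D / 2))
    if l > D:
        raise ValueError(f"library subsample size l={l} exceeds D={D}")
    members, availability = [], np.zeros((econf.q, D), dtype=bool)
    M = library.Theta.shape[0]
    for j in range(econf.q):
        cols = np.sort(rng.choice(D, size=l, replace=False))
        availability[j, cols] = True
        sub = library.subset(cols)
        if econf.bootstrap_rows:
            idx = bootstrap_indices(M, rng)
            sub = Library(Theta=sub.Theta[idx], terms=sub.terms,
                          target=sub.target[idx],
                          state_names=sub.state_names)
        xi_sub = _fit_member(sub, rconf)
        xi = np.zeros((D, library.n_targets), dtype=xi_sub.dtype)
        xi[cols] = xi_sub
        members.append(xi)
    stack = np.stack(members, axis=0)
    offered = availability.sum(axis=0)  # (D,)
    never = offered == 0
    if np.any(never):
        warnings.warn(
            f"{int(never.sum())} library terms were never offered to any "
            "member (increase q or l); their inclusion is set to 0",
            stacklevel=2,
        )
    denom = np.maximum(offered, 1)[:, None]
    inclusion = (stack != 0).sum(axis=0) / denom
    agg = _aggregate(stack, inclusion, "bagging", econf.inclusion_tol,
                     weights=availability)
    if econf.refit_aggregate:
        # availability-weighted means are biased by members that were
        # offered a term without its governing partners; a least-squares
        # refit of the selected support on the full data removes that
        from .regression import ridge_solve

        agg = np.zeros_like(agg)
        keep = inclusion >= econf.inclusion_tol
        for i in range(library.n_targets):
            cols = np.flatnonzero(keep[:, i])
            if cols.size:
                agg[cols, i] = ridge_solve(
                    library.Theta[:, cols], library.target[:, i], 0.0)
    aggregate = SparseModel(Xi=agg, terms=list(library.terms),
                            state_names=list(library.state_names))
    return EnsembleModel(members=members, availability=availability,
                         inclusion=inclusion, aggregate=aggregate)


def prescreen_library(
    library: Library, em: EnsembleModel, keep_tol: float,
) -> Library:
    """Drop terms whose max-over-states inclusion falls below ``keep_tol``.

    The threshold needs care: too high and genuinely relevant terms are
    discarded before the final fit ever sees them.
    """
    if len(em.aggregate.terms) != library.D:
        raise ValueError("ensemble was not built on this library")
    score = em.inclusion.max(axis=1)
    keep = np.flatnonzero(score >= keep_tol)
    if keep.size == 0:
        raise ValueError(
            f"keep_tol={keep_tol} removed every term (max inclusion "
            f"{score.max():.3f}); choose a lower threshold"
        )
    return library.subset(keep)
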