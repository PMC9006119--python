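"""Core containers and file I/O.

Shared data types (snapshot time series, spatio-temporal fields, run
configuration), delimited-text and HDF5 readers/writers, the bundled
lynx–hare fixture, and JSON (de)serialization of sparse and ensemble
models.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import h5py
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("esindy")

MODEL_SCHEMA_VERSION = 1


class FormatError(ValueError):
    """Raised for malformed or version-incompatible files."""


@dataclass
class TimeSeries:
    """Multivariate snapshot matrix with sample times.

    Attributes
    ----------
    U : (m, n) ndarray
        State snapshots, one row per sample time.
    t : (m,) ndarray
        Strictly increasing sample times.
    names : list of str
        State-variable labels, length n.
    """

    U: np.ndarray
    t: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.U = np.atleast_2d(np.asarray(self.U, dtype=float))
        self.t = np.asarray(self.t, dtype=float).ravel()
        if self.U.shape[0] != self.t.size:
            raise ValueError(
                f"U has {self.U.shape[0]} rows but t has {self.t.size} entries"
            )
        if self.t.size < 2:
            raise ValueError("need at least two samples")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            row = int(np.argmax(dt <= 0)) + 1
            raise ValueError(f"non-monotone time at row {row}")
        if not np.all(np.isfinite(self.U)):
            raise ValueError("missing or non-finite values in state matrix")
        if not self.names:
            self.names = [f"x{i}" for i in range(self.U.shape[1])]
        if len(self.names) != self.U.shape[1]:
            raise ValueError("names length does not match state dimension")

    @property
    def m(self) -> int:
        return self.U.shape[0]

    @property
    def n(self) -> int:
        return self.U.shape[1]

    @property
    def dt(self) -> float:
        """Uniform sample spacing; raises if sampling is non-uniform."""
        d = np.diff(self.t)
        if not np.allclose(d, d[0], rtol=1e-8, atol=1e-12):
            raise ValueError("time grid is not uniform; resample first")
        return float(d[0])

    def is_uniform(self, rtol: float = 1e-8) -> bool:
        d = np.diff(self.t)
        return bool(np.allclose(d, d[0], rtol=rtol, atol=1e-12))


@dataclass
class ControlledTimeSeries(TimeSeries):
    """Time series with a scalar actuation signal on the same time base."""

    u_ctrl: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        super().__post_init__()
        self.u_ctrl = np.asarray(self.u_ctrl, dtype=float).ravel()
        if self.u_ctrl.size != self.m:
            raise ValueError(
                f"actuation has {self.u_ctrl.size} samples, state has {self.m}"
            )


@dataclass
class Field:
    """Scalar or multi-component field u(x, t) on a uniform space-time grid.

    ``u`` has shape (n_x, m) for a single component or (n_x, m, n_comp) for
    coupled components sharing one grid.  Complex values are allowed (e.g.
    for Schrödinger-type dynamics).
    """

    u: np.ndarray
    x: np.ndarray
    t: np.ndarray
    periodic: bool = True

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u)
        self.x = np.asarray(self.x, dtype=float).ravel()
        self.t = np.asarray(self.t, dtype=float).ravel()
        if self.u.ndim == 2:
            pass
        elif self.u.ndim != 3:
            raise ValueError("u must have shape (n_x, m) or (n_x, m, n_comp)")
        if self.u.shape[0] != self.x.size or self.u.shape[1] != self.t.size:
            raise ValueError(
                f"field shape {self.u.shape} inconsistent with grid "
                f"({self.x.size} x {self.t.size})"
            )
        for name, g in (("x", self.x), ("t", self.t)):
            d = np.diff(g)
            if g.size < 2 or not np.allclose(d, d[0], rtol=1e-10):
                raise ValueError(f"{name} grid must be uniform")

    @property
    def n_x(self) -> int:
        return self.x.size

    @property
    def m(self) -> int:
        return self.t.size

    @property
    def n_comp(self) -> int:
        return 1 if self.u.ndim == 2 else self.u.shape[2]

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0])

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def component(self, c: int) -> np.ndarray:
        """(n_x, m) view of component c."""
        return self.u if self.u.ndim == 2 else self.u[:, :, c]


# --------------------------------------------------------------------------
# Run configuration
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Seeded configuration for a full pipeline run.

    Parameter groups are plain dicts so that YAML round-trips losslessly;
    module-level config dataclasses validate them on use.
    """

    seed: int = 0
    regression: dict = field(default_factory=dict)
    ensemble: dict = field(default_factory=dict)
    weak: dict = field(default_factory=dict)
    noise: dict = field(default_factory=dict)
    library: dict = field(default_factory=dict)
    forecast: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


# --------------------------------------------------------------------------
# Delimited-text time series
# --------------------------------------------------------------------------

def read_timeseries(
    path: Union[str, Path], time_column: str = "t", sep: str = ","
) -> TimeSeries:
    """Read a delimited text file with a header row into a TimeSeries.

    The ``time_column`` is removed from the state matrix; all remaining
    columns become state variables in file order.
    """
    df = pd.read_csv(path, sep=sep)
    if time_column not in df.columns:
        raise ValueError(f"time column {time_column!r} not found in {path}")
    if df.isna().any().any():
        raise ValueError(f"missing values in {path}")
    t = df[time_column].to_numpy(dtype=float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        row = int(np.argmax(dt <= 0)) + 1
        raise ValueError(f"non-monotone time at row {row} of {path}")
    state = df.drop(columns=[time_column])
    return TimeSeries(U=state.to_numpy(dtype=float), t=t, names=list(state.columns))


def write_timeseries(series: TimeSeries, path: Union[str, Path],
                     time_column: str = "t", sep: str = ",") -> None:
    df = pd.DataFrame(series.U, columns=series.names)
    df.insert(0, time_column, series.t)
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def load_lynx_hare_fixture() -> TimeSeries:
    """Bundled yearly lynx–hare pelt counts, 1900–1920, in thousands.

    These are the commonly tabulated Hudson Bay Company pelt counts used
    throughout the predator–prey modelling literature; the exact provenance
    file varies between sources, so the bundled table is a documented
    stand-in at the standard published values.
    """
    ref = importlib.resources.files("esindy.data").joinpath("lynx_hare.csv")
    with importlib.resources.as_file(ref) as p:
        return read_timeseries(p, time_column="year")


# --------------------------------------------------------------------------
# HDF5 fields
# --------------------------------------------------------------------------

def write_field(fld: Field, path: Union[str, Path]) -> None:
    """Write a Field to HDF5 with datasets /u, /x, /t."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("u", data=fld.u)
        fh.create_dataset("x", data=fld.x)
        fh.create_dataset("t", data=fld.t)
        fh.attrs["periodic"] = bool(fld.periodic)


def read_field(path: Union[str, Path]) -> Field:
    with h5py.File(path, "r") as fh:
        return Field(
            u=fh["u"][()],
            x=fh["x"][()],
            t=fh["t"][()],
            periodic=bool(fh.attrs.get("periodic", True)),
        )


# --------------------------------------------------------------------------
# Model serialization (JSON, schema-versioned)
# --------------------------------------------------------------------------

def _term_to_dict(term) -> dict:
    return {
        "kind": term.kind,
        "exponents": list(term.exponents),
        "derivative_order": term.derivative_order,
        "derivative_component": term.derivative_component,
        "label": term.label,
    }


def _term_from_dict(d: dict):
    from .library import TermSpec

    return TermSpec(
        kind=d["kind"],
        exponents=tuple(d["exponents"]),
        derivative_order=d["derivative_order"],
        derivative_component=d.get("derivative_component", 0),
        label=d["label"],
    )


def save_model(model, path: Union[str, Path]) -> None:
    """Serialize a SparseModel or EnsembleModel to inspectable JSON."""
    from .ensemble import EnsembleModel
    from .regression import SparseModel

    if isinstance(model, SparseModel):
        payload = {
            "schema_version": MODEL_SCHEMA_VERSION,
            "kind": "sparse",
            "terms": [_term_to_dict(tm) for tm in model.terms],
            "Xi": model.Xi.tolist(),
            "state_names": list(model.state_names),
        }
    elif isinstance(model, EnsembleModel):
        payload = {
            "schema_version": MODEL_SCHEMA_VERSION,
            "kind": "ensemble",
            "terms": [_term_to_dict(tm) for tm in model.aggregate.terms],
            "members": [mm.tolist() for mm in model.members],
            "availability": model.availability.astype(int).tolist(),
            "inclusion": model.inclusion.tolist(),
            "aggregate_Xi": model.aggregate.Xi.tolist(),
            "state_names": list(model.aggregate.state_names),
        }
    else:  # pragma: no cover - defensive
        raise TypeError(f"cannot serialize {type(model).__name__}")
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def load_model(path: Union[str, Path]):
    """Inverse of :func:`save_model`."""
    from .ensemble import EnsembleModel
    from .regression import SparseModel

    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"corrupt model file {path}: {exc}") from exc
    version = payload.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise FormatError(
            f"model schema version {version!r} unsupported "
            f"(expected {MODEL_SCHEMA_VERSION})"
        )
    terms = [_term_from_dict(d) for d in payload["terms"]]
    if payload["kind"] == "sparse":
        return SparseModel(
            Xi=np.asarray(payload["Xi"], dtype=float),
            terms=terms,
            state_names=list(payload["state_names"]),
        )
    if payload["kind"] == "ensemble":
        members = [np.asarray(mm, dtype=float) for mm in payload["members"]]
        aggregate = SparseModel(
            Xi=np.asarray(payload["aggregate_Xi"], dtype=float),
            terms=terms,
            state_names=list(payload["state_names"]),
        )
        return EnsembleModel(
            members=members,
            availability=np.asarray(payload["availability"], dtype=bool),
            inclusion=np.asarray(payload["inclusion"], dtype=float),
            aggregate=aggregate,
        )
    raise FormatError(f"unknown model kind {payload['kind']!r}")
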