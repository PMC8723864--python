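"""Fixed-step integration front end and the Trace container.

The integrators are deterministic classical RK4 at ``dt_integrate``
(default 0.02 ms), sampling the state every ``dt_sample`` (default 1 ms).
Delay-coupled runs use the method of steps with a ring history buffer and
cubic Hermite interpolation (see :mod:`pbcsync._kernels`).  With zero
delays the DDE path degenerates exactly (bit for bit) to the plain ODE
integrator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

from . import _kernels
from .model import STATE5, STATE8, default_initial_state, default_pair_state
from .params import ModelParams, NetworkConfig

__all__ = [
    "Trace", "IntegrationDiverged",
    "integrate_ode", "integrate_dde",
    "run_single", "run_pair",
    "DEFAULT_DT", "DEFAULT_DT_SAMPLE", "DEFAULT_DURATION",
]

DEFAULT_DT = 0.02          # ms, integration step
DEFAULT_DT_SAMPLE = 1.0    # ms, sampling interval for metrics
DEFAULT_DURATION = 2e5     # ms, long enough for >= 20 burst cycles


class IntegrationDiverged(RuntimeError):
    """Raised when a non-finite state is encountered; carries the time."""

    def __init__(self, t_fail: float):
        super().__init__(f"integration diverged at t = {t_fail:g} ms")
        self.t_fail = t_fail


@dataclass
class Trace:
    """Uniformly sampled time series of the full model state.

    ``states`` is (n_samples, n_components) with columns labelled by
    ``columns``; ``meta`` records the run configuration.
    """

    t0: float
    dt_sample: float
    states: np.ndarray
    columns: tuple
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=float)
        self.columns = tuple(self.columns)
        if self.states.ndim != 2 or self.states.shape[0] < 2:
            raise ValueError("Trace needs at least 2 samples")
        if self.states.shape[1] != len(self.columns):
            raise ValueError("column labels do not match state width")

    @property
    def t(self) -> np.ndarray:
        return self.t0 + self.dt_sample * np.arange(self.states.shape[0])

    @property
    def duration(self) -> float:
        return self.dt_sample * (self.states.shape[0] - 1)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[:, self.columns.index(name)]

    def window(self, t_start: float, t_stop: float | None = None) -> "Trace":
        """Sub-trace restricted to [t_start, t_stop]."""
        t = self.t
        mask = t >= t_start if t_stop is None else (t >= t_start) & (t <= t_stop)
        i0 = int(np.argmax(mask))
        states = self.states[mask]
        return Trace(float(t[i0]), self.dt_sample, states, self.columns,
                     dict(self.meta))

    def discard_transient(self, fraction: float = 0.5) -> "Trace":
        """Drop the leading ``fraction`` of the run (metric convention)."""
        if not 0.0 <= fraction < 1.0:
            raise ValueError("fraction must be in [0, 1)")
        return self.window(self.t0 + fraction * self.duration)

    # -- I/O ---------------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(self.columns))
        df.insert(0, "t", self.t)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Trace":
        df = pd.read_csv(path)
        t = df["t"].to_numpy()
        return cls(float(t[0]), float(t[1] - t[0]),
                   df.drop(columns="t").to_numpy(), tuple(df.columns[1:]))

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("states", data=self.states)
            ds.attrs["t0"] = self.t0
            ds.attrs["dt_sample"] = self.dt_sample
            ds.attrs["columns"] = list(self.columns)
            ds.attrs["meta"] = yaml.safe_dump(_plain(self.meta))

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "Trace":
        with h5py.File(path, "r") as f:
            ds = f["states"]
            meta = yaml.safe_load(ds.attrs["meta"]) or {}
            return cls(float(ds.attrs["t0"]), float(ds.attrs["dt_sample"]),
                       ds[...], tuple(str(c) for c in ds.attrs["columns"]),
                       meta)


def _plain(obj):
    """Recursively convert numpy scalars for YAML serialization."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _steps(t_span: float, dt_integrate: float, dt_sample: float):
    if t_span <= 0:
        raise ValueError("t_span must be positive")
    ratio = dt_sample / dt_integrate
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("dt_sample must be an integer multiple of dt_integrate")
    sample_every = int(round(ratio))
    n_steps = int(round(t_span / dt_integrate))
    if n_steps < sample_every:
        raise ValueError("t_span shorter than one sampling interval")
    n_steps -= n_steps % sample_every
    return n_steps, sample_every


def integrate_ode(rhs: Callable, y0: Sequence[float], t_span: float,
                  dt_integrate: float = DEFAULT_DT,
                  dt_sample: float = DEFAULT_DT_SAMPLE,
                  columns: tuple | None = None) -> Trace:
    """Generic fixed-step RK4 for an arbitrary Python RHS ``f(t, y)``.

    Used for small oracle problems and cross-checks; the neuron runs go
    through the compiled drivers :func:`run_single` / :func:`run_pair`.
    """
    y = np.asarray(y0, dtype=float).copy()
    n_steps, sample_every = _steps(t_span, dt_integrate, dt_sample)
    out = np.empty((n_steps // sample_every + 1, y.size))
    out[0] = y
    t = 0.0
    idx = 1
    for step in range(n_steps):
        k1 = np.asarray(rhs(t, y))
        k2 = np.asarray(rhs(t + dt_integrate / 2, y + dt_integrate / 2 * k1))
        k3 = np.asarray(rhs(t + dt_integrate / 2, y + dt_integrate / 2 * k2))
        k4 = np.asarray(rhs(t + dt_integrate, y + dt_integrate * k3))
        y = y + dt_integrate / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += dt_integrate
        if (step + 1) % sample_every == 0:
            if not np.all(np.isfinite(y)):
                raise IntegrationDiverged(t)
            out[idx] = y
            idx += 1
    cols = columns or tuple(f"y{i}" for i in range(y.size))
    return Trace(0.0, dt_sample, out, cols,
                 {"dt_integrate": dt_integrate})


def run_single(p: ModelParams, I_exc: float, t_span: float = DEFAULT_DURATION,
               y0: Sequence[float] | None = None,
               dt_integrate: float = DEFAULT_DT,
               dt_sample: float = DEFAULT_DT_SAMPLE) -> Trace:
    """Integrate the 5-D single neuron with the compiled RK4 driver."""
    if y0 is None:
        y0 = default_initial_state(p)
    y0 = np.asarray(y0, dtype=float)
    n_steps, sample_every = _steps(t_span, dt_integrate, dt_sample)
    out, status, fail = _kernels.integrate5(y0, float(I_exc), p.to_array(),
                                            dt_integrate, n_steps, sample_every)
    if status != _kernels.OK:
        raise IntegrationDiverged(fail * dt_integrate)
    return Trace(0.0, dt_sample, out, STATE5,
                 {"I_exc": float(I_exc), "dt_integrate": dt_integrate})


def run_pair(p: ModelParams, net: NetworkConfig,
             t_span: float = DEFAULT_DURATION,
             y0: Sequence[float] | None = None,
             dt_integrate: float = DEFAULT_DT,
             dt_sample: float = DEFAULT_DT_SAMPLE) -> Trace:
    """Integrate the 8-D coupled pair; delays use the method of steps.

    The initial history is constant, equal to the initial state.  With
    ``tau1 == tau2 == 0`` the plain ODE driver is used, so the zero-delay
    DDE is exactly the no-delay system.
    """
    if y0 is None:
        y0 = default_pair_state(p)
    y0 = np.asarray(y0, dtype=float)
    n_steps, sample_every = _steps(t_span, dt_integrate, dt_sample)
    P = p.to_array()
    if net.tau1 == 0.0 and net.tau2 == 0.0:
        out, status, fail = _kernels.integrate8_nodelay(
            y0, net.g_c, net.I_exc1, net.I_exc2, P,
            dt_integrate, n_steps, sample_every)
    else:
        L = int(math.ceil(max(net.tau1, net.tau2) / dt_integrate)) + 4
        rings = [np.empty(L) for _ in range(4)]
        out, status, fail = _kernels.integrate8_dde(
            y0, net.g_c, net.tau1, net.tau2, net.I_exc1, net.I_exc2, P,
            dt_integrate, n_steps, sample_every, *rings)
    if status != _kernels.OK:
        raise IntegrationDiverged(fail * dt_integrate)
    return Trace(0.0, dt_sample, out, STATE8,
                 {"g_c": net.g_c, "tau1": net.tau1, "tau2": net.tau2,
                  "I_exc1": net.I_exc1, "I_exc2": net.I_exc2,
                  "dt_integrate": dt_integrate})


def integrate_dde(p: ModelParams, net: NetworkConfig, **kwargs) -> Trace:
    """Alias of :func:`run_pair` emphasizing the delayed path."""
    return run_pair(p, net, **kwargs)
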