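"""Pairwise synchronization measures for sampled voltage traces.

Implemented measures:

* Pearson correlation coefficient R of the two membrane potentials;
* maximum synchronization difference ``max(e) = max_k |V1_k - V2_k|``;
* Poincare phase from event (burst-onset) crossing times,
  ``phi(t) = 2 pi (t - t_n)/(t_{n+1} - t_n) + 2 pi n``, and the
  phase-synchronization criterion ``max |phi1 - phi2| < 2 pi``;
* similarity function
  ``S^2(tau) = <(x(t+tau) - y(t))^2> / sqrt(<x^2><y^2>)`` on
  mean-subtracted signals (Rosenblum-style lag-synchronization
  diagnostic; S(lag) = 0 for a pure time shift), with lag recovery by
  grid minimization;
* a categorical synchronization class combining all of the above.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SyncReport", "correlation_coefficient", "max_sync_difference",
    "poincare_phase", "phase_sync_test", "similarity", "similarity_curve",
    "lag_recover", "classify_sync", "PHASE_BOUND",
    "phase_difference_to_csv",
]

PHASE_BOUND = 2.0 * np.pi  # phase-locking criterion max|dphi| < 2*pi

# classification thresholds (package conventions; see docs/methods.md)
R_COMPLETE = 0.999
MAXE_COMPLETE = 1.0   # mV
R_APPROX = 0.95
S_LAG = 0.05


@dataclass
class SyncReport:
    """Synchronization measures for one pair run."""

    R: float
    max_e: float
    S0: float
    best_lag: float = 0.0
    S_min: float = np.nan
    dphi_max: float = np.nan
    N: int = 0
    sync_class: str = ""
    out_of_phase: bool = False
    S_tau: dict = field(default_factory=dict)   # lag -> S

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["S_tau"] = {str(k): float(v) for k, v in self.S_tau.items()}
        Path(path).write_text(json.dumps(d, indent=2, default=float))

    def similarity_to_csv(self, path: str | Path) -> None:
        """Write the S(tau) curve as a tidy (lag, S) table."""
        pd.DataFrame(sorted(self.S_tau.items()),
                     columns=["lag", "S"]).to_csv(path, index=False)


def phase_difference_to_csv(t, phi1, phi2, path: str | Path) -> None:
    """Write a phase-difference series (t, phi1, phi2, dphi) as CSV."""
    pd.DataFrame({"t": np.asarray(t), "phi1": np.asarray(phi1),
                  "phi2": np.asarray(phi2),
                  "dphi": np.abs(np.asarray(phi1) - np.asarray(phi2))}
                 ).to_csv(path, index=False)


def _pair(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    return x, y


def correlation_coefficient(x, y) -> float:
    """Centered Pearson correlation of two equally sampled series."""
    x, y = _pair(x, y)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if denom == 0:
        raise ValueError("correlation undefined for zero-variance series")
    return float((xc * yc).sum() / denom)


def max_sync_difference(x, y) -> float:
    """Infinity norm of the sample-wise difference."""
    x, y = _pair(x, y)
    return float(np.max(np.abs(x - y)))


def poincare_phase(events, t) -> np.ndarray:
    """Piecewise-linear phase from section-crossing times.

    ``phi(t_n) = 2 pi n`` and phi interpolates linearly in between; every
    query time must lie within the event span.
    """
    events = np.asarray(events, dtype=float)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if events.size < 2:
        raise ValueError("need at least 2 events to define a phase")
    if np.any(np.diff(events) <= 0):
        raise ValueError("event times must be strictly increasing")
    if t.min() < events[0] or t.max() > events[-1]:
        raise ValueError("query time outside the event span")
    n = np.clip(np.searchsorted(events, t, side="right") - 1, 0, events.size - 2)
    frac = (t - events[n]) / (events[n + 1] - events[n])
    return 2.0 * np.pi * (n + frac)


def phase_sync_test(phi1, phi2, bound: float = PHASE_BOUND) -> tuple[float, bool]:
    """Maximum absolute phase difference on a common grid; locked iff < bound."""
    phi1 = np.asarray(phi1, dtype=float)
    phi2 = np.asarray(phi2, dtype=float)
    if phi1.shape != phi2.shape:
        raise ValueError("phases must share a common time grid")
    dphi_max = float(np.max(np.abs(phi1 - phi2)))
    return dphi_max, dphi_max < bound


def similarity(x, y, lag: float, dt_sample: float, squared: bool = False) -> float:
    """Similarity function at one lag (x advanced by ``lag``).

    ``S^2 = mean[(x(t+lag) - y(t))^2] / sqrt(mean[x^2] * mean[y^2])`` on
    the overlapping window of the mean-subtracted signals; returns S
    (or S^2 with ``squared=True``).  The lag must be a multiple of the
    sampling interval.
    """
    x, y = _pair(x, y)
    k = lag / dt_sample
    if abs(k - round(k)) > 1e-9:
        raise ValueError("lag must be a multiple of dt_sample")
    k = int(round(k))
    if k >= 0:
        xs, ys = x[k:], y[:x.size - k] if k else y
    else:
        xs, ys = x[:k], y[-k:]
    if xs.size < 2:
        raise ValueError("overlap shorter than 2 samples")
    xs = xs - xs.mean()
    ys = ys - ys.mean()
    px = np.mean(xs ** 2)
    py = np.mean(ys ** 2)
    if px == 0 or py == 0:
        raise ValueError("similarity undefined for zero-power signal")
    s2 = np.mean((xs - ys) ** 2) / np.sqrt(px * py)
    return float(s2) if squared else float(np.sqrt(s2))


def similarity_curve(x, y, lag_grid, dt_sample: float) -> dict:
    """S over a grid of lags (ms -> S)."""
    return {float(lag): similarity(x, y, lag, dt_sample) for lag in lag_grid}


def lag_recover(x, y, lag_grid, dt_sample: float) -> float:
    """Lag minimizing S; ties broken toward the smallest absolute lag."""
    curve = similarity_curve(x, y, lag_grid, dt_sample)
    best = min(curve.items(), key=lambda kv: (round(kv[1], 12), abs(kv[0])))
    return best[0]


def classify_sync(R: float, max_e: float, dphi_max: float = np.nan,
                  S_tau: dict | None = None, burst_period: float = np.nan
                  ) -> tuple[str, bool]:
    """Categorical synchronization class.

    Returns ``(sync_class, out_of_phase)``.  Order of tests: complete
    (R > 0.999 and max_e < 1 mV), approximate (R > 0.95), phase
    (max|dphi| < 2 pi), lag (min S < 0.05 at a nonzero lag), otherwise
    asynchronous.  ``out_of_phase`` flags best alignment near half the
    burst period.
    """
    S_tau = S_tau or {}
    out_of_phase = False
    if S_tau and np.isfinite(burst_period) and burst_period > 0:
        best_lag = min(S_tau.items(), key=lambda kv: kv[1])[0]
        half = burst_period / 2.0
        out_of_phase = abs(abs(best_lag) - half) < 0.2 * burst_period
    if R > R_COMPLETE and max_e < MAXE_COMPLETE:
        return "complete", False
    if R > R_APPROX:
        return "approximate", out_of_phase
    if np.isfinite(dphi_max) and dphi_max < PHASE_BOUND:
        return "phase", out_of_phase
    nz = {lag: s for lag, s in S_tau.items() if lag != 0}
    if nz and min(nz.values()) < S_LAG:
        return "lag", out_of_phase
    return "asynchronous", out_of_phase
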