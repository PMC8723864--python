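"""Spike detection, interspike intervals, burst segmentation, ISI scans.

Spikes are upward crossings of a voltage threshold with hysteresis: after
a crossing of ``threshold_up`` the detector only re-arms once V falls
below ``threshold_rearm``, so subthreshold wiggles near the threshold do
not double-count.  Crossing times are linearly interpolated between the
bracketing samples.

Bursts are runs of spikes separated by interspike intervals below a gap
threshold; ``gap_threshold="auto"`` places the split at the largest
multiplicative gap in the sorted ISIs (the bimodal intra-burst /
inter-burst structure of bursting traces), and flags tonic spiking when
no such gap exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .integrate import Trace, run_single, run_pair, DEFAULT_DURATION
from .params import ModelParams, NetworkConfig

__all__ = [
    "SpikeTrain", "BurstSummary",
    "detect_spikes", "isi_sequence", "detect_bursts", "isi_scan",
    "DEFAULT_THRESHOLD_UP", "DEFAULT_THRESHOLD_REARM",
]

DEFAULT_THRESHOLD_UP = -30.0     # mV; burst spikes overshoot this comfortably
DEFAULT_THRESHOLD_REARM = -40.0  # mV


@dataclass
class SpikeTrain:
    spike_times: np.ndarray      # ms, strictly increasing
    threshold_up: float
    source: str = ""

    def __post_init__(self):
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size > 1 and np.any(np.diff(self.spike_times) <= 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self):
        return self.spike_times.size


@dataclass
class BurstSummary:
    burst_onsets: np.ndarray         # ms, first spike of each burst
    spikes_per_burst: np.ndarray     # int per burst
    interburst_intervals: np.ndarray  # ms, onset-to-onset gaps
    period: float                    # ms, mean burst cycle length
    frequency: float                 # 1/ms
    tonic: bool = False              # no bimodal ISI split found
    gap_threshold: float = field(default=np.nan)

    @property
    def n_bursts(self) -> int:
        return len(self.burst_onsets)


def detect_spikes(trace: Trace | np.ndarray, channel: str = "V",
                  threshold_up: float = DEFAULT_THRESHOLD_UP,
                  threshold_rearm: float = DEFAULT_THRESHOLD_REARM,
                  t: np.ndarray | None = None) -> SpikeTrain:
    """Hysteresis threshold-crossing spike detector.

    Accepts a :class:`Trace` (with ``channel`` naming the voltage column)
    or a bare voltage array with matching time array ``t``.
    """
    if threshold_rearm >= threshold_up:
        raise ValueError("threshold_rearm must be below threshold_up")
    if isinstance(trace, Trace):
        V = trace[channel]
        tv = trace.t
        source = channel
    else:
        V = np.asarray(trace, dtype=float)
        if t is None:
            raise ValueError("time array required for bare voltage input")
        tv = np.asarray(t, dtype=float)
        source = channel
    if V.size == 0:
        raise ValueError("empty trace")
    times = []
    armed = V[0] < threshold_up
    for i in range(1, V.size):
        if armed and V[i - 1] < threshold_up <= V[i]:
            frac = (threshold_up - V[i - 1]) / (V[i] - V[i - 1])
            times.append(tv[i - 1] + frac * (tv[i] - tv[i - 1]))
            armed = False
        elif not armed and V[i] < threshold_rearm:
            armed = True
    return SpikeTrain(np.asarray(times), threshold_up, source)


def isi_sequence(s: SpikeTrain) -> np.ndarray:
    """Successive spike-time differences (empty for < 2 spikes)."""
    if len(s) < 2:
        return np.empty(0)
    return np.diff(s.spike_times)


def _auto_gap(isis: np.ndarray) -> float | None:
    """Largest multiplicative gap in sorted ISIs; None when unimodal.

    The split is accepted only when the ratio across the gap exceeds 4,
    otherwise the train is treated as tonic.
    """
    if isis.size < 2:
        return None
    s = np.sort(isis)
    ratios = s[1:] / s[:-1]
    k = int(np.argmax(ratios))
    if ratios[k] < 4.0:
        return None
    return float(np.sqrt(s[k] * s[k + 1]))  # geometric midpoint


def detect_bursts(s: SpikeTrain, gap_threshold: float | str = "auto") -> BurstSummary:
    """Segment a spike train into bursts at ISIs exceeding the gap threshold."""
    if len(s) == 0:
        raise ValueError("cannot segment an empty spike train")
    isis = isi_sequence(s)
    tonic = False
    if gap_threshold == "auto":
        gap = _auto_gap(isis)
        if gap is None:
            tonic = True
            gap = np.inf
    else:
        gap = float(gap_threshold)
    breaks = np.flatnonzero(isis > gap) if isis.size else np.empty(0, int)
    onsets_idx = np.concatenate(([0], breaks + 1))
    counts = np.diff(np.concatenate((onsets_idx, [len(s)])))
    onsets = s.spike_times[onsets_idx]
    ibis = np.diff(onsets)
    period = float(np.mean(ibis)) if ibis.size else np.nan
    freq = 1.0 / period if ibis.size else np.nan
    return BurstSummary(onsets, counts.astype(int), ibis, period, freq,
                        tonic=tonic, gap_threshold=gap if np.isfinite(gap) else np.nan)


def isi_scan(param_name: str, grid, p: ModelParams | None = None,
             net: NetworkConfig | None = None,
             t_span: float = DEFAULT_DURATION,
             transient_fraction: float = 0.5,
             channel: str = "V",
             **integrate_kwargs) -> pd.DataFrame:
    """One simulation per grid value; post-transient ISIs in long format.

    ``param_name`` may be a single-neuron stimulus (``"I_exc"``) or any
    :class:`NetworkConfig` field for coupled scans (then ``channel``
    selects the neuron, e.g. ``"V1"``).  Returns a tidy DataFrame with
    columns ``(param_value, isi)``; quiescent cells (no spikes) appear as
    a single row with ``isi = NaN``, and integration failures are tagged
    in the ``error`` column.
    """
    if p is None:
        p = ModelParams.table1()
    rows = []
    for value in np.asarray(grid, dtype=float):
        try:
            if param_name == "I_exc" and net is None:
                tr = run_single(p, value, t_span, **integrate_kwargs)
                ch = "V"
            else:
                if net is None:
                    net = NetworkConfig()
                tr = run_pair(p, net.replace(**{param_name: float(value)}),
                              t_span, **integrate_kwargs)
                ch = channel if channel != "V" else "V1"
            st = detect_spikes(tr.discard_transient(transient_fraction), ch)
            isis = isi_sequence(st)
            if isis.size == 0:
                rows.append({"param_value": value, "isi": np.nan,
                             "n_spikes": len(st), "error": ""})
            else:
                rows.extend({"param_value": value, "isi": float(x),
                             "n_spikes": len(st), "error": ""}
                            for x in isis)
        except Exception as exc:  # record and continue the scan
            rows.append({"param_value": value, "isi": np.nan,
                         "n_spikes": 0, "error": str(exc)})
    return pd.DataFrame(rows, columns=["param_value", "isi", "n_spikes", "error"])


def quiescence_onset(scan: pd.DataFrame) -> float | None:
    """Smallest scanned value with zero post-transient spikes."""
    for value, group in scan.groupby("param_value", sort=True):
        if (group["n_spikes"] == 0).all() and (group["error"] == "").all():
            return float(value)
    return None


def write_scan(scan: pd.DataFrame, path: str | Path) -> None:
    scan.to_csv(path, index=False)
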