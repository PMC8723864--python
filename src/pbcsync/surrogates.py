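"""Synthetic voltage-like trace pairs with known synchronization structure.

The generator emulates the gross features the synchronization metrics
care about — a slow burst envelope carrying clusters of fast stereotyped
spikes — without running the neuron model, so every metric and the
classifier can be tested against construction-time ground truth:
controllable lag, phase shift, anti-phase alignment, noise correlation.
Spike pulses are raised cosines of 2 ms width (smooth, so interpolating
detectors are exercised); noise is Gaussian white at the sampling
resolution, deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .integrate import Trace

__all__ = ["SurrogateSpec", "gen_burst_trace", "gen_pair"]

KINDS = ("identical", "lagged", "phase_shifted", "noisy_correlated",
         "independent", "anti_phase")


@dataclass(frozen=True)
class SurrogateSpec:
    kind: str = "identical"
    burst_period: float = 500.0    # ms
    spikes_per_burst: int = 3
    intra_isi: float = 10.0        # ms
    spike_amp: float = 80.0        # mV above baseline
    baseline: float = -60.0        # mV
    lag: float = 0.0               # ms (lagged / phase_shifted kinds)
    target_R: float = 0.8          # noisy_correlated only
    noise_sd: float = 0.0          # mV additive white noise
    seed: int = 0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        if self.burst_period <= self.spikes_per_burst * self.intra_isi:
            raise ValueError("burst_period must exceed the burst envelope")
        if not 0.0 <= self.target_R <= 1.0:
            raise ValueError("target_R must be in [0, 1]")


_PULSE_WIDTH = 2.0  # ms


def _burst_signal(t: np.ndarray, spec: SurrogateSpec, shift: float) -> np.ndarray:
    """Deterministic burst waveform evaluated at times t (shifted)."""
    v = np.full(t.shape, spec.baseline)
    tt = np.mod(t - shift, spec.burst_period)
    for k in range(spec.spikes_per_burst):
        center = 50.0 + k * spec.intra_isi  # bursts start 50 ms into the cycle
        x = (tt - center) / (_PULSE_WIDTH / 2.0)
        mask = np.abs(x) < 1.0
        v[mask] += spec.spike_amp * 0.5 * (1.0 + np.cos(np.pi * x[mask]))
    return v


def gen_burst_trace(spec: SurrogateSpec, duration: float,
                    dt_sample: float = 1.0) -> Trace:
    """One bursty surrogate trace (baseline + stereotyped spike clusters)."""
    n = int(round(duration / dt_sample)) + 1
    t = dt_sample * np.arange(n)
    v = _burst_signal(t, spec, 0.0)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        v = v + spec.noise_sd * rng.standard_normal(n)
    return Trace(0.0, dt_sample, v[:, None], ("V",), {"spec": asdict(spec)})


def gen_pair(spec: SurrogateSpec, duration: float = 1e4,
             dt_sample: float = 1.0) -> tuple[Trace, Trace, dict]:
    """A trace pair plus the ground-truth record of its construction.

    Kinds: ``identical`` (R=1, max_e=0, S(0)=0); ``lagged`` (y delayed by
    ``spec.lag``, so S is minimized there); ``phase_shifted`` (same, with
    the phase offset 2*pi*lag/burst_period recorded); ``anti_phase``
    (lag = half the burst period); ``noisy_correlated`` (correlated
    Gaussian noise pair, y = rho*x + sqrt(1-rho^2)*eps with
    rho = target_R); ``independent`` (independent noise streams).
    """
    n = int(round(duration / dt_sample)) + 1
    t = dt_sample * np.arange(n)
    rng = np.random.default_rng(spec.seed)
    truth: dict = {"kind": spec.kind, "lag": 0.0, "phase_offset": 0.0,
                   "target_R": None,
                   "spikes_per_burst": spec.spikes_per_burst,
                   "burst_period": spec.burst_period}

    if spec.kind in ("identical", "lagged", "phase_shifted", "anti_phase"):
        lag = {"identical": 0.0, "lagged": spec.lag,
               "phase_shifted": spec.lag,
               "anti_phase": spec.burst_period / 2.0}[spec.kind]
        x = _burst_signal(t, spec, 0.0)
        y = _burst_signal(t, spec, lag)   # y lags x by `lag`
        truth["lag"] = lag
        truth["phase_offset"] = 2.0 * np.pi * lag / spec.burst_period
        if spec.noise_sd > 0:
            x = x + spec.noise_sd * rng.standard_normal(n)
            y = y + spec.noise_sd * rng.standard_normal(n)
    elif spec.kind == "noisy_correlated":
        rho = spec.target_R
        sd = spec.noise_sd if spec.noise_sd > 0 else 1.0
        base = rng.standard_normal(n)
        eps = rng.standard_normal(n)
        x = spec.baseline + sd * base
        y = spec.baseline + sd * (rho * base + np.sqrt(1 - rho ** 2) * eps)
        truth["target_R"] = rho
    else:  # independent
        sd = spec.noise_sd if spec.noise_sd > 0 else 1.0
        x = spec.baseline + sd * rng.standard_normal(n)
        y = spec.baseline + sd * rng.standard_normal(n)
        truth["target_R"] = 0.0

    meta = {"spec": asdict(spec)}
    return (Trace(0.0, dt_sample, x[:, None], ("V",), meta),
            Trace(0.0, dt_sample, y[:, None], ("V",), dict(meta)),
            truth)
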