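"""Single-neuron and coupled two-neuron right-hand sides.

The somatic subsystem is

    C_m dV/dt = -I_Na - I_NaP - I_CAN - I_K - I_L - I_exc  [ - I_c ]
    dn/dt     = (n_inf(V) - n) / tau_n(V)
    dh/dt     = (h_inf(V) - h) / tau_h(V)

with the calcium drive tracing an ellipse around (Ca_c, l_c):

    d[Ca]/dt = -eps * d * (l - l_c)
    dl/dt    =  eps / d * ([Ca] - Ca_c)

Current and gating kinetics follow the standard Butera / Park-Rubin forms:
Boltzmann steady states, cosh-shaped time constants, a Hill-type CAN
activation by intracellular calcium.  Every functional form is a plain
overridable function so variants can be swapped in.

Two electrically coupled neurons share one calcium subsystem; neuron *i*
receives the coupling current ``I_ci = g_c * (V_j(t - tau_i) - V_i(t))``,
subtracted on the right-hand side like the other currents.

State layouts used throughout the package::

    single neuron (5-D):  [V, n, h, Ca, l]
    coupled pair  (8-D):  [V1, n1, h1, V2, n2, h2, Ca, l]
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .params import ModelParams, NetworkConfig

__all__ = [
    "gate_inf", "gate_tau", "can_activation", "ionic_currents",
    "rhs_single", "rhs_coupled", "IonicCurrents",
    "STATE5", "STATE8", "default_initial_state", "default_pair_state",
]

#: Column labels of the single-neuron and pair state vectors.
STATE5 = ("V", "n", "h", "Ca", "l")
STATE8 = ("V1", "n1", "h1", "V2", "n2", "h2", "Ca", "l")


def gate_inf(V, V_half, slope):
    """Boltzmann steady-state activation ``1 / (1 + exp((V - V_half)/slope))``.

    Negative ``slope`` gives a gate that opens with depolarization.
    """
    if slope == 0:
        raise ValueError("gating slope must be nonzero")
    return 1.0 / (1.0 + np.exp((V - V_half) / slope))


def gate_tau(V, tau_bar, V_half, slope):
    """Voltage-dependent time constant ``tau_bar / cosh((V - V_half)/(2 slope))``.

    Peaks at ``tau_bar`` for ``V == V_half`` and decays symmetrically.
    """
    if slope == 0:
        raise ValueError("gating slope must be nonzero")
    if tau_bar <= 0:
        raise ValueError("tau_bar must be positive")
    return tau_bar / np.cosh((V - V_half) / (2.0 * slope))


def can_activation(Ca, K_CAN, n_CAN):
    """Hill-type CAN-current calcium activation ``1 / (1 + (K_CAN/Ca)^n_CAN)``."""
    Ca = np.asarray(Ca, dtype=float)
    if np.any(Ca <= 0):
        raise ValueError("calcium concentration must be positive")
    return 1.0 / (1.0 + (K_CAN / Ca) ** n_CAN)


class IonicCurrents(NamedTuple):
    I_Na: float
    I_NaP: float
    I_CAN: float
    I_K: float
    I_L: float


def ionic_currents(V, n, h, Ca, p: ModelParams) -> IonicCurrents:
    """All five somatic membrane currents at the given state."""
    m = gate_inf(V, p.V_m, p.s_m)
    mp = gate_inf(V, p.V_p, p.s_mp)
    I_Na = p.g_Na * m ** 3 * (1.0 - n) * (V - p.V_Na)
    I_NaP = p.g_NaP * mp * h * (V - p.V_Na)
    I_CAN = p.g_CAN * can_activation(Ca, p.K_CAN, p.n_CAN) * (V - p.V_Na)
    I_K = p.g_K * n ** 4 * (V - p.V_K)
    I_L = p.g_L * (V - p.V_L)
    return IonicCurrents(I_Na, I_NaP, I_CAN, I_K, I_L)


def rhs_single(state5, I_exc, p: ModelParams) -> np.ndarray:
    """Time derivative of the 5-D single-neuron state ``[V, n, h, Ca, l]``."""
    V, n, h, Ca, l = state5
    cur = ionic_currents(V, n, h, Ca, p)
    dV = (-cur.I_Na - cur.I_NaP - cur.I_CAN - cur.I_K - cur.I_L - I_exc) / p.C_m
    dn = (gate_inf(V, p.V_n, p.s_n) - n) / gate_tau(V, p.tau_n_bar, p.V_n, p.s_n)
    dh = (gate_inf(V, p.V_h, p.s_h) - h) / gate_tau(V, p.tau_h_bar, p.V_h, p.s_h)
    dCa = -p.eps * p.d * (l - p.l_c)
    dl = p.eps / p.d * (Ca - p.Ca_c)
    return np.array([dV, dn, dh, dCa, dl])


def rhs_coupled(state8, delayed_V, net: NetworkConfig, p: ModelParams) -> np.ndarray:
    """Time derivative of the 8-D coupled state ``[V1,n1,h1,V2,n2,h2,Ca,l]``.

    ``delayed_V = (V2(t - tau1), V1(t - tau2))`` must be resolved by the
    caller (history lookup); both neurons share the calcium subsystem.
    """
    V1, n1, h1, V2, n2, h2, Ca, l = state8
    V2_d, V1_d = delayed_V
    out = np.empty(8)
    for k, (V, n, h, Vd, I_exc) in enumerate(
        ((V1, n1, h1, V2_d, net.I_exc1), (V2, n2, h2, V1_d, net.I_exc2))
    ):
        cur = ionic_currents(V, n, h, Ca, p)
        I_c = net.g_c * (Vd - V)
        out[3 * k] = (
            -cur.I_Na - cur.I_NaP - cur.I_CAN - cur.I_K - cur.I_L - I_exc - I_c
        ) / p.C_m
        out[3 * k + 1] = (gate_inf(V, p.V_n, p.s_n) - n) / gate_tau(
            V, p.tau_n_bar, p.V_n, p.s_n
        )
        out[3 * k + 2] = (gate_inf(V, p.V_h, p.s_h) - h) / gate_tau(
            V, p.tau_h_bar, p.V_h, p.s_h
        )
    out[6] = -p.eps * p.d * (l - p.l_c)
    out[7] = p.eps / p.d * (Ca - p.Ca_c)
    return out


def default_initial_state(p: ModelParams, ellipse_energy: float = 0.0) -> np.ndarray:
    """Default single-neuron initial condition ``(-50, 0, 0.5, Ca0, l_c)``.

    The calcium subsystem starts on the ellipse
    ``E = (Ca - Ca_c)^2 / d + d (l - l_c)^2 = ellipse_energy``; the default
    ``E=0`` pins calcium at the center so the CAN drive is constant, which
    is the configuration used for all bursting and synchronization runs.
    """
    Ca0 = p.Ca_c + np.sqrt(ellipse_energy * p.d)
    return np.array([-50.0, 0.0, 0.5, Ca0, p.l_c])


def default_pair_state(p: ModelParams, dV2: float = 0.01,
                       ellipse_energy: float = 0.0) -> np.ndarray:
    """Default pair initial condition; neuron 2's V offset by ``dV2`` mV.

    The small offset makes complete synchronization a statement about
    convergence of the transverse dynamics rather than a trivial identity.
    """
    s = default_initial_state(p, ellipse_energy)
    return np.array([s[0], s[1], s[2], s[0] + dV2, s[1], s[2], s[3], s[4]])
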