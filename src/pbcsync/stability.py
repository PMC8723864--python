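"""Linear stability, Hopf normal form, and maximal Lyapunov exponents.

The calcium subsystem is an autonomous center (a pure rotation), so
equilibrium analysis fixes [Ca] at the ellipse center and works with the
three-variable somatic subsystem (V, n, h).  Symbolic differentiation
(sympy) supplies the exact Jacobian and the second/third multilinear
forms B(x, y) and C(x, y, z) needed for the Hopf normal form; finite
differences are used only as a cross-check in the tests.

The first Lyapunov coefficient is computed two ways:

* ``l1`` (default reported value): the invariant Kuznetsov expression
  with center-manifold correction,
  ``l1 = Re[<p,C(q,q,qb)> - 2<p,B(q,A^-1 B(q,qb))>
          + <p,B(qb,(2 i w I - A)^-1 B(q,q))>] / (2 w)``,
  with ``A q = i w q``, ``A^T p = -i w p``, ``<p,q> = sum conj(p) q = 1``.
* ``l1_plain``: the bare combination
  ``Re(i g20 g11 + w g21) / (2 w^2)`` with ``g20 = <p,B(q,q)>``,
  ``g11 = <p,B(q,qb)>``, ``g21 = <p,C(q,q,qb)>`` and a selectable
  p-normalization (``"pairing"`` for <p,q>=1, ``"last"`` for p3 = 1).
  This combination omits the cubic center-manifold correction and is not
  invariant under p-scaling unless the pairing normalization is used; it
  is provided for comparison with literature values computed that way.

Negative l1 means the bifurcating limit cycle is stable (supercritical).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import sympy as sp
from scipy.optimize import brentq

from . import _kernels
from .model import default_pair_state
from .params import ModelParams, NetworkConfig, PARAM_ORDER

__all__ = [
    "HopfResult", "LyapunovEstimate", "somatic_symbols",
    "find_equilibria", "find_equilibrium", "jacobian3",
    "locate_hopf", "normal_form_coeffs", "max_lyapunov",
    "first_lyapunov_from_forms", "somatic_multilinear_forms",
]


@dataclass
class HopfResult:
    I_exc_star: float
    eq3: np.ndarray                  # (V, n, h)
    A: np.ndarray                    # 3x3 Jacobian
    omega: float                     # 1/ms, imaginary part of critical pair
    lambda_real: float               # 1/ms, remaining real eigenvalue
    q: np.ndarray | None = None      # right eigenvector, first component 1
    p: np.ndarray | None = None      # left vector, A^T p = -i w p, <p,q>=1
    g20: complex | None = None
    g11: complex | None = None
    g21: complex | None = None
    l1: float | None = None          # invariant first Lyapunov coefficient
    l1_plain: float | None = None    # bare Eq-combination (see module doc)
    direction: str | None = None     # "supercritical" iff l1 < 0

    def to_dict(self) -> dict:
        def c(z):
            return None if z is None else [float(np.real(z)), float(np.imag(z))]
        return {
            "I_exc_star": self.I_exc_star,
            "eq3": [float(v) for v in self.eq3],
            "A": self.A.tolist(),
            "omega": self.omega,
            "lambda_real": self.lambda_real,
            "q": None if self.q is None else [c(z) for z in self.q],
            "p": None if self.p is None else [c(z) for z in self.p],
            "g20": c(self.g20), "g11": c(self.g11), "g21": c(self.g21),
            "l1": self.l1, "l1_plain": self.l1_plain,
            "direction": self.direction,
        }


@dataclass
class LyapunovEstimate:
    lambda_max: float                  # 1/ms
    convergence_series: np.ndarray     # running estimate per renormalization
    renorm_interval: float             # ms
    converged: bool = True


# --------------------------------------------------------------------------
# symbolic somatic subsystem
# --------------------------------------------------------------------------

@lru_cache(maxsize=8)
def somatic_symbols(param_key: tuple):
    """Lambdified RHS, Jacobian, Hessians and third-derivative tensors.

    ``param_key`` is the packed parameter tuple (hashable); all callables
    take (V, n, h, I_exc).
    """
    P = dict(zip(PARAM_ORDER, param_key))
    V, n, h, I = sp.symbols("V n h I_exc")
    minf = 1 / (1 + sp.exp((V - P["V_m"]) / P["s_m"]))
    mpinf = 1 / (1 + sp.exp((V - P["V_p"]) / P["s_mp"]))
    ninf = 1 / (1 + sp.exp((V - P["V_n"]) / P["s_n"]))
    hinf = 1 / (1 + sp.exp((V - P["V_h"]) / P["s_h"]))
    taun = P["tau_n_bar"] / sp.cosh((V - P["V_n"]) / (2 * P["s_n"]))
    tauh = P["tau_h_bar"] / sp.cosh((V - P["V_h"]) / (2 * P["s_h"]))
    fca = 1 / (1 + (P["K_CAN"] / P["Ca_c"]) ** P["n_CAN"])
    I_Na = P["g_Na"] * minf ** 3 * (1 - n) * (V - P["V_Na"])
    I_NaP = P["g_NaP"] * mpinf * h * (V - P["V_Na"])
    I_CAN = P["g_CAN"] * fca * (V - P["V_Na"])
    I_K = P["g_K"] * n ** 4 * (V - P["V_K"])
    I_L = P["g_L"] * (V - P["V_L"])
    f1 = (-I_Na - I_NaP - I_CAN - I_K - I_L - I) / P["C_m"]
    f2 = (ninf - n) / taun
    f3 = (hinf - h) / tauh
    F = sp.Matrix([f1, f2, f3])
    X = sp.Matrix([V, n, h])
    args = (V, n, h, I)
    J = F.jacobian(X)
    rhs_f = sp.lambdify(args, F, "numpy")
    jac_f = sp.lambdify(args, J, "numpy")
    hess_f = [sp.lambdify(args, sp.hessian(F[i], X), "numpy") for i in range(3)]
    third_f = [[[[sp.lambdify(args, sp.diff(F[i], X[j], X[k], X[m]), "numpy")
                  for m in range(3)] for k in range(3)] for j in range(3)]
               for i in range(3)]
    ninf_f = sp.lambdify(V, ninf, "numpy")
    hinf_f = sp.lambdify(V, hinf, "numpy")
    return rhs_f, jac_f, hess_f, third_f, ninf_f, hinf_f


def _sym(p: ModelParams):
    return somatic_symbols(tuple(p.to_array()))


# --------------------------------------------------------------------------
# equilibria and Jacobian
# --------------------------------------------------------------------------

def find_equilibria(p: ModelParams, I_exc: float,
                    v_range: tuple = (-80.0, 20.0),
                    n_grid: int = 2001) -> list[np.ndarray]:
    """All somatic equilibria (V, n, h) at fixed calcium (ellipse center).

    At equilibrium n = n_inf(V) and h = h_inf(V), so roots are found on
    the scalar voltage balance by a dense sign-change sweep plus Brent
    refinement.  Returns equilibria sorted by V (the cubic branch yields
    up to three).
    """
    rhs_f, _, _, _, ninf_f, hinf_f = _sym(p)

    def g(V):
        return float(rhs_f(V, ninf_f(V), hinf_f(V), I_exc)[0, 0])

    Vs = np.linspace(v_range[0], v_range[1], n_grid)
    vals = np.array([g(v) for v in Vs])
    roots = []
    for i in range(len(Vs) - 1):
        if vals[i] == 0.0:
            roots.append(Vs[i])
        elif vals[i] * vals[i + 1] < 0:
            roots.append(brentq(g, Vs[i], Vs[i + 1], xtol=1e-13))
    out = [np.array([V, ninf_f(V), hinf_f(V)]) for V in sorted(roots)]
    if not out:
        raise ValueError(f"no equilibrium found in V range {v_range}")
    return out


def find_equilibrium(p: ModelParams, I_exc: float, branch: str = "lower",
                     **kwargs) -> np.ndarray:
    """One equilibrium on the requested branch (lower/middle/upper by V)."""
    eqs = find_equilibria(p, I_exc, **kwargs)
    idx = {"lower": 0, "upper": -1}.get(branch)
    if idx is None:
        if len(eqs) < 3:
            raise ValueError("middle branch requires three equilibria")
        idx = 1
    return eqs[idx]


def jacobian3(p: ModelParams, I_exc: float, eq3) -> np.ndarray:
    """Analytic 3x3 Jacobian of the somatic RHS at an equilibrium."""
    _, jac_f, _, _, _, _ = _sym(p)
    V, n, h = eq3
    return np.array(jac_f(V, n, h, I_exc), dtype=float)


def _pair_real(p: ModelParams, I_exc: float, branch: str):
    eq = find_equilibrium(p, I_exc, branch)
    A = jacobian3(p, I_exc, eq)
    ev = np.linalg.eigvals(A)
    order = np.argsort(np.abs(ev.imag))
    # eigenvalue with smallest |Im| is the "real" one; the other two the pair
    lam_r = ev[order[0]]
    pair = ev[order[1:]]
    return float(pair.real.max()), eq, A


# --------------------------------------------------------------------------
# Hopf location and normal form
# --------------------------------------------------------------------------

def locate_hopf(p: ModelParams, I_range: tuple = (8.0, 13.0),
                branch: str = "lower", tol: float = 1e-10,
                max_iter: int = 200) -> HopfResult:
    """Bisection on the real part of the complex pair along a branch.

    Returns the eigen-data at the crossing (normal-form coefficients are
    added by :func:`normal_form_coeffs`).
    """
    lo, hi = I_range
    f_lo, _, _ = _pair_real(p, lo, branch)
    f_hi, _, _ = _pair_real(p, hi, branch)
    if f_lo * f_hi > 0:
        raise ValueError(
            f"complex pair real part does not change sign over {I_range}")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid, _, _ = _pair_real(p, mid, branch)
        if abs(f_mid) < tol or hi - lo < 1e-14:
            break
        if f_mid * f_lo > 0:
            lo, f_lo = mid, f_mid
        else:
            hi = mid
    I_star = 0.5 * (lo + hi)
    _, eq, A = _pair_real(p, I_star, branch)
    ev = np.linalg.eigvals(A)
    order = np.argsort(np.abs(ev.imag))
    lam_real = float(ev[order[0]].real)
    omega = float(np.abs(ev[order[-1]].imag))
    return HopfResult(I_star, eq, A, omega, lam_real)


def first_lyapunov_from_forms(A: np.ndarray, B, C,
                              p_normalization: str = "pairing") -> dict:
    """First Lyapunov coefficient of a Hopf point from A, B(x,y), C(x,y,z).

    ``A`` must have a (near-)purely-imaginary eigenvalue pair; ``B`` and
    ``C`` are the second/third multilinear forms of the vector field at
    the equilibrium.  Returns a dict with q, p, g20, g11, g21, the
    invariant ``l1`` and the bare combination ``l1_plain`` (see module
    docstring).  This is the generic machinery; tests exercise it on
    analytic normal-form oracles.
    """
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    ev, vec = np.linalg.eig(A)
    iq = int(np.argmax(ev.imag))
    omega = float(ev[iq].imag)
    if omega <= 0:
        raise ValueError("defective or real eigenpair at the Hopf point")
    q = vec[:, iq]
    q = q / q[0]                          # first component 1
    evT, vecT = np.linalg.eig(A.T)
    ip_ = int(np.argmin(np.abs(evT - (-1j * omega))))
    p_raw = vecT[:, ip_]
    pairing = np.vdot(p_raw, q)
    if abs(pairing) < 1e-14:
        raise ValueError("degenerate eigenvector pairing")
    p_vec = p_raw / np.conj(pairing)      # <p,q> = sum conj(p) q = 1

    qb = np.conj(q)
    g20 = complex(np.vdot(p_vec, B(q, q)))
    g11 = complex(np.vdot(p_vec, B(q, qb)))
    g21 = complex(np.vdot(p_vec, C(q, q, qb)))

    # invariant l1 with center-manifold correction
    s1 = np.linalg.solve(A, B(q, qb))
    s2 = np.linalg.solve(2j * omega * np.eye(n) - A, B(q, q))
    G21 = (g21 - 2.0 * np.vdot(p_vec, B(q, s1))
           + np.vdot(p_vec, B(qb, s2)))
    l1 = float(np.real(G21) / (2.0 * omega))

    if p_normalization == "pairing":
        p_plain = p_vec
    elif p_normalization == "last":
        p_plain = p_raw / p_raw[-1]
    else:
        raise ValueError("p_normalization must be 'pairing' or 'last'")
    g20p = complex(np.vdot(p_plain, B(q, q)))
    g11p = complex(np.vdot(p_plain, B(q, qb)))
    g21p = complex(np.vdot(p_plain, C(q, q, qb)))
    l1_plain = float(np.real(1j * g20p * g11p + omega * g21p)
                     / (2.0 * omega ** 2))
    return {"omega": omega, "q": q, "p": p_vec, "g20": g20, "g11": g11,
            "g21": g21, "l1": l1, "l1_plain": l1_plain}


def somatic_multilinear_forms(p: ModelParams, eq3, I_exc: float):
    """B(x,y) and C(x,y,z) of the somatic RHS at an equilibrium (symbolic)."""
    _, _, hess_f, third_f, _, _ = _sym(p)
    V0, n0, h0 = eq3
    args = (V0, n0, h0, I_exc)
    H = [np.array(hess_f[i](*args), dtype=float) for i in range(3)]
    CT = np.empty((3, 3, 3, 3))
    for i in range(3):
        for j in range(3):
            for k in range(3):
                for m in range(3):
                    CT[i, j, k, m] = float(third_f[i][j][k][m](*args))

    def B(x, y):
        return np.array([x @ H[i] @ y for i in range(3)])

    def C(x, y, z):
        return np.einsum("ijkm,j,k,m->i", CT, x, y, z)

    return B, C


def normal_form_coeffs(hopf: HopfResult, p: ModelParams,
                       p_normalization: str = "pairing") -> HopfResult:
    """Complete a located Hopf point with g20, g11, g21 and l1.

    ``p_normalization`` affects only ``l1_plain`` (see module docstring);
    the invariant ``l1`` always uses the unit-pairing left vector.
    """
    B, C = somatic_multilinear_forms(p, hopf.eq3, hopf.I_exc_star)
    nf = first_lyapunov_from_forms(hopf.A, B, C, p_normalization)
    hopf.q, hopf.p = nf["q"], nf["p"]
    hopf.g20, hopf.g11, hopf.g21 = nf["g20"], nf["g11"], nf["g21"]
    hopf.l1, hopf.l1_plain = nf["l1"], nf["l1_plain"]
    hopf.direction = "supercritical" if nf["l1"] < 0 else "subcritical"
    return hopf


# --------------------------------------------------------------------------
# maximal Lyapunov exponent (Benettin two-trajectory method)
# --------------------------------------------------------------------------

def max_lyapunov(p: ModelParams, system: str = "pair",
                 net: NetworkConfig | None = None,
                 I_exc: float = 8.5, Ca_fixed: float | None = None,
                 y0=None, perturb_index: int = 0,
                 renorm_interval: float = 50.0,
                 duration: float = 4e5, d0: float = 1e-6,
                 dt_integrate: float = 0.02,
                 discard_fraction: float = 0.25,
                 convergence_tol: float | None = None) -> LyapunovEstimate:
    """Largest Lyapunov exponent by two-trajectory renormalization.

    ``system`` selects the flow: ``"somatic"`` (3-D, calcium fixed),
    ``"single"`` (5-D neuron; the neutral calcium rotation bounds the
    exponent below by 0), or ``"pair"`` (8-D delay-coupled network; the
    perturbation is applied uniformly to the V1 history, and the
    separation norm runs over state plus history rings).
    """
    P = p.to_array()
    renorm_steps = max(1, int(round(renorm_interval / dt_integrate)))
    n_renorms = max(4, int(duration / (renorm_steps * dt_integrate)))
    discard = int(discard_fraction * n_renorms)
    if system in ("somatic", "single"):
        ndim = 3 if system == "somatic" else 5
        if y0 is None:
            y0 = np.array([-50.0, 0.0, 0.5, p.Ca_c, p.l_c])
        y0 = np.asarray(y0, dtype=float)
        if y0.size < 5:
            y0 = np.concatenate([y0, [p.Ca_c, p.l_c][: 5 - y0.size]])
        series = _kernels.benettin_ode(
            y0, float(I_exc), float(Ca_fixed if Ca_fixed is not None else p.Ca_c),
            ndim, P, dt_integrate, renorm_steps, n_renorms, d0, discard,
            perturb_index)
    elif system == "pair":
        if net is None:
            net = NetworkConfig()
        if y0 is None:
            y0 = default_pair_state(p)
        L = int(math.ceil(max(net.tau1, net.tau2, dt_integrate) / dt_integrate)) + 4
        series = _kernels.benettin_dde(
            np.asarray(y0, dtype=float), net.g_c, net.tau1, net.tau2,
            net.I_exc1, net.I_exc2, P, dt_integrate, renorm_steps,
            n_renorms, d0, discard, L)
    else:
        raise ValueError("system must be 'somatic', 'single' or 'pair'")
    tail = series[~np.isnan(series)]
    lam = float(tail[-1]) if tail.size else np.nan
    converged = True
    if convergence_tol is not None and tail.size >= 10:
        span = tail[-tail.size // 5:]
        converged = float(np.ptp(span)) < convergence_tol
    return LyapunovEstimate(lam, series, renorm_interval, converged)
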