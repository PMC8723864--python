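import numpy as np
import pytest

import pbcsync as pb
from pbcsync.stability import (find_equilibria, first_lyapunov_from_forms,
                               jacobian3, locate_hopf, max_lyapunov)


def somatic_rhs(params, y, I_exc, Ca):
    return pb.rhs_single(np.array([y[0], y[1], y[2], Ca, params.l_c]),
                         I_exc, params)[:3]


class TestEquilibria:
    def test_residual_is_tiny(self, params):
        for I in (9.0, 11.0, 12.5):
            for eq in find_equilibria(params, I):
                res = somatic_rhs(params, eq, I, params.Ca_c)
                assert np.linalg.norm(res) < 1e-10

    def test_cubic_branch_has_three_roots(self, params):
        eqs = find_equilibria(params, 9.0)
        assert len(eqs) == 3
        V = [e[0] for e in eqs]
        assert V[0] < V[1] < V[2]

    def test_branch_selection(self, params):
        lo = pb.find_equilibrium(params, 9.0, "lower")
        up = pb.find_equilibrium(params, 9.0, "upper")
        assert lo[0] < up[0]

    def test_gates_at_steady_state(self, params):
        eq = pb.find_equilibrium(params, 10.0)
        assert eq[1] == pytest.approx(pb.gate_inf(eq[0], params.V_n, params.s_n))
        assert eq[2] == pytest.approx(pb.gate_inf(eq[0], params.V_h, params.s_h))

    def test_sweep_traces_s_shaped_branch(self, params):
        """Lower-branch V decreases monotonically with stimulus current."""
        Vs = [pb.find_equilibrium(params, I)[0] for I in np.linspace(8, 12, 9)]
        assert np.all(np.diff(Vs) < 0)


class TestJacobian:
    def test_structural_zeros(self, params):
        eq = pb.find_equilibrium(params, 10.0)
        A = jacobian3(params, 10.0, eq)
        assert A[1, 2] == 0.0
        assert A[2, 1] == 0.0

    def test_matches_finite_differences(self, params):
        I = 10.0
        eq = pb.find_equilibrium(params, I)
        A = jacobian3(params, I, eq)
        eps = 1e-6
        for j in range(3):
            dy = np.zeros(3)
            dy[j] = eps
            col = (somatic_rhs(params, eq + dy, I, params.Ca_c)
                   - somatic_rhs(params, eq - dy, I, params.Ca_c)) / (2 * eps)
            assert col == pytest.approx(A[:, j], rel=1e-6, abs=1e-9)


class TestHopf:
    def test_pure_imaginary_pair_at_crossing(self, hopf_point):
        ev = np.linalg.eigvals(hopf_point.A)
        pair = sorted(ev, key=lambda z: -abs(z.imag))[:2]
        assert all(abs(z.real) < 1e-8 for z in pair)
        real_ev = min(ev, key=lambda z: abs(z.imag))
        assert abs(real_ev.imag) < 1e-12
        assert real_ev.real < 0

    def test_eigen_data_consistency(self, hopf_point):
        h = hopf_point
        assert np.linalg.norm(h.A @ h.q - 1j * h.omega * h.q) < 1e-8
        assert abs(np.vdot(h.p, h.q) - 1.0) < 1e-10

    def test_bisection_tolerance_convergence(self, params):
        h1 = locate_hopf(params, (10.0, 12.5), tol=1e-6)
        h2 = locate_hopf(params, (10.0, 12.5), tol=1e-8)
        assert abs(h1.I_exc_star - h2.I_exc_star) < 1e-4

    def test_no_sign_change_rejected(self, params):
        with pytest.raises(ValueError):
            locate_hopf(params, (12.0, 12.5))


def embed_normal_form(sigma, om=2.0):
    """3-D embedding of z' = i*om*z + sigma*z|z|^2 plus a stable w' = -w."""
    A = np.array([[0.0, -om, 0.0], [om, 0.0, 0.0], [0.0, 0.0, -1.0]])

    def B(x, y):
        return np.zeros(3, dtype=complex)

    def C(x, y, z):
        c1 = sigma * (6 * x[0] * y[0] * z[0]
                      + 2 * (x[0] * y[1] * z[1] + x[1] * y[0] * z[1]
                             + x[1] * y[1] * z[0]))
        c2 = sigma * (6 * x[1] * y[1] * z[1]
                      + 2 * (x[1] * y[0] * z[0] + x[0] * y[1] * z[0]
                             + x[0] * y[0] * z[1]))
        return np.array([c1, c2, 0.0], dtype=complex)

    return A, B, C


class TestFirstLyapunov:
    def test_supercritical_oracle(self):
        A, B, C = embed_normal_form(-1.0)
        nf = first_lyapunov_from_forms(A, B, C)
        assert nf["l1"] < 0
        assert nf["l1"] == pytest.approx(-2.0)

    def test_subcritical_oracle(self):
        A, B, C = embed_normal_form(+1.0)
        nf = first_lyapunov_from_forms(A, B, C)
        assert nf["l1"] > 0

    @pytest.mark.parametrize("sigma", [-1.0, 1.0])
    def test_sign_invariant_under_coordinate_change(self, sigma):
        """The Hopf direction (sign of l1) survives any linear change of
        coordinates; the magnitude is pinned by the q-normalization and is
        exactly preserved by transforms fixing the first coordinate."""
        rng = np.random.default_rng(4)
        A, B, C = embed_normal_form(sigma)
        l1_ref = first_lyapunov_from_forms(A, B, C)["l1"]
        # general similarity: sign preserved
        T = rng.normal(size=(3, 3)) + np.eye(3) * 2.0
        Ti = np.linalg.inv(T)
        l1_tr = first_lyapunov_from_forms(
            T @ A @ Ti,
            lambda x, y: T @ B(Ti @ x, Ti @ y),
            lambda x, y, z: T @ C(Ti @ x, Ti @ y, Ti @ z))["l1"]
        assert np.sign(l1_tr) == np.sign(l1_ref)
        # first-coordinate-fixing transform: value preserved exactly
        th = 0.7
        T2 = np.array([[1.0, 0.0, 0.0],
                       [0.0, np.cos(th), -np.sin(th)],
                       [0.0, np.sin(th), np.cos(th)]])
        T2i = np.linalg.inv(T2)
        l1_rot = first_lyapunov_from_forms(
            T2 @ A @ T2i,
            lambda x, y: T2 @ B(T2i @ x, T2i @ y),
            lambda x, y, z: T2 @ C(T2i @ x, T2i @ y, T2i @ z))["l1"]
        assert l1_rot == pytest.approx(l1_ref, rel=1e-9)

    def test_neuron_hopf_coefficients_finite(self, hopf_point):
        h = hopf_point
        assert np.isfinite(h.l1) and np.isfinite(h.l1_plain)
        assert h.direction in ("supercritical", "subcritical")
        assert h.direction == ("supercritical" if h.l1 < 0 else "subcritical")


class TestMaxLyapunov:
    def test_quiescent_somatic_is_stable(self, params):
        est = max_lyapunov(params, system="somatic", I_exc=12.0,
                           duration=6e4)
        assert est.lambda_max < -1e-4

    def test_calcium_rotation_is_neutral(self, params):
        y0 = np.array([-51.5, 0.003, 0.67, 0.15, 0.9])
        est = max_lyapunov(params, system="single", I_exc=12.0, y0=y0,
                           perturb_index=3, duration=6e4)
        assert abs(est.lambda_max) < 1e-4

    def test_delay_coupled_chaos_is_positive(self, params):
        net = pb.NetworkConfig(g_c=0.4, tau1=10.0, tau2=10.0,
                               I_exc1=8.5, I_exc2=8.5)
        est = max_lyapunov(params, system="pair", net=net, duration=1.5e5)
        assert est.lambda_max > 1e-4
        # robustness: halving d0 and renorm interval keeps the estimate
        est2 = max_lyapunov(params, system="pair", net=net, duration=1.5e5,
                            d0=5e-7, renorm_interval=25.0)
        assert est2.lambda_max > 1e-4
        assert est2.lambda_max == pytest.approx(est.lambda_max, rel=0.35)
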