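import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pbcsync.syncmetrics import (classify_sync, correlation_coefficient,
                                 lag_recover, max_sync_difference,
                                 phase_sync_test, poincare_phase, similarity,
                                 similarity_curve)


def brute_R(x, y):
    """Direct evaluation of the centered correlation sum formula."""
    xb, yb = np.mean(x), np.mean(y)
    num = sum((xi - xb) * (yi - yb) for xi, yi in zip(x, y))
    den = np.sqrt(sum((xi - xb) ** 2 for xi in x)
                  * sum((yi - yb) ** 2 for yi in y))
    return num / den


class TestCorrelation:
    def test_self_correlation(self):
        x = np.array([1.0, 5.0, 2.0, 8.0])
        assert correlation_coefficient(x, x) == pytest.approx(1.0)

    def test_anti_correlation(self):
        x = np.array([1.0, 5.0, 2.0, 8.0])
        assert correlation_coefficient(x, 3.0 - x) == pytest.approx(-1.0)

    def test_against_direct_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 3.0, 5.0])
        assert correlation_coefficient(x, y) == pytest.approx(brute_R(x, y))
        rng = np.random.default_rng(7)
        a, b = rng.normal(size=50), rng.normal(size=50)
        assert correlation_coefficient(a, b) == pytest.approx(brute_R(a, b))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlation_coefficient(np.ones(5), np.arange(5.0))

    @settings(max_examples=40, deadline=None)
    @given(st.floats(0.1, 10.0), st.floats(-5.0, 5.0))
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=30), rng.normal(size=30)
        r = correlation_coefficient(x, y)
        assert correlation_coefficient(a * x + b, y) == pytest.approx(r)
        assert correlation_coefficient(-a * x + b, y) == pytest.approx(-r)


class TestMaxDifference:
    def test_identical_and_offset(self):
        x = np.array([1.0, -2.0, 3.0])
        assert max_sync_difference(x, x) == 0.0
        assert max_sync_difference(x, x + 2.5) == pytest.approx(2.5)

    def test_against_brute_force(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(size=100), rng.normal(size=100)
        assert max_sync_difference(x, y) == pytest.approx(
            max(abs(a - b) for a, b in zip(x, y)))

    def test_metric_symmetry(self):
        rng = np.random.default_rng(12)
        x, y = rng.normal(size=50), rng.normal(size=50)
        assert max_sync_difference(x, y) == max_sync_difference(y, x)


class TestPoincarePhase:
    def test_uniform_events_give_linear_phase(self):
        events = np.arange(0.0, 1001.0, 100.0)
        t = np.array([50.0, 250.0, 730.0])
        assert poincare_phase(events, t) == pytest.approx(2 * np.pi * t / 100.0)

    def test_midpoint_and_knots(self):
        events = np.array([0.0, 80.0, 250.0, 300.0])  # jittered
        for n, tn in enumerate(events[:-1]):
            assert poincare_phase(events, tn)[0] == pytest.approx(2 * np.pi * n)
        mid = 0.5 * (events[1] + events[2])
        assert poincare_phase(events, mid)[0] == pytest.approx(2 * np.pi + np.pi)

    def test_monotone_and_continuous(self):
        events = np.array([0.0, 130.0, 190.0, 410.0, 500.0])
        t = np.linspace(0.0, 500.0, 1001)
        phi = poincare_phase(events, t)
        assert np.all(np.diff(phi) > 0)
        assert np.max(np.abs(np.diff(phi))) < 0.2  # no jumps

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            poincare_phase(np.array([0.0, 100.0]), [150.0])


class TestPhaseSync:
    def test_identical_trains_locked(self):
        events = np.array([0.0, 100.0, 200.0, 300.0])
        t = np.linspace(0, 300, 100)
        phi = poincare_phase(events, t)
        dphi, locked = phase_sync_test(phi, phi)
        assert dphi == 0.0 and locked

    def test_frequency_mismatch_unbounded(self):
        t = np.linspace(0.0, 5000.0, 2000)
        e1 = np.arange(0.0, 5001.0, 100.0)
        e2 = np.arange(0.0, 5001.0, 200.0)
        phi1 = poincare_phase(e1, t)
        phi2 = poincare_phase(e2, t)
        dphi, locked = phase_sync_test(phi1, phi2)
        assert not locked
        assert dphi == pytest.approx(np.pi * 5000.0 / 100.0, rel=0.05)

    def test_constant_offset_locked(self):
        T, off = 100.0, 30.0
        t = np.linspace(off, 1000.0, 500)
        phi1 = poincare_phase(np.arange(0.0, 1101.0, T), t)
        phi2 = poincare_phase(np.arange(off, 1101.0, T), t)
        dphi, locked = phase_sync_test(phi1, phi2)
        assert locked
        assert dphi == pytest.approx(2 * np.pi * off / T, rel=1e-6)


class TestSimilarity:
    def test_identical_signals_zero(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=200)
        assert similarity(x, x, 0.0, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_pure_lag_zero_at_true_lag(self):
        rng = np.random.default_rng(6)
        base = np.cumsum(rng.normal(size=400))  # smooth-ish signal
        L = 35
        x, y = base[L:], base[:-L]  # x(t) = base(t+L), y(t) = base(t)
        assert similarity(x, y, -float(L), 1.0) < 1e-10 or \
            similarity(x, y, float(L), 1.0) < 1e-10

    def test_independent_signals_approach_s2_of_two(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=200_000)
        y = rng.normal(size=200_000)
        s2 = similarity(x, y, 0.0, 1.0, squared=True)
        assert s2 == pytest.approx(2.0, rel=0.02)

    def test_lag_must_be_grid_multiple(self):
        with pytest.raises(ValueError):
            similarity(np.arange(10.0), np.arange(10.0), 0.5, 1.0)

    def test_zero_power_rejected(self):
        with pytest.raises(ValueError):
            similarity(np.ones(10), np.arange(10.0), 0.0, 1.0)

    def test_lag_recover_identical_and_sine(self):
        t = np.arange(0.0, 2000.0, 1.0)
        x = np.sin(2 * np.pi * t / 200.0)
        grid = np.arange(-150.0, 151.0, 1.0)
        assert lag_recover(x, x, grid, 1.0) == 0.0
        # anti-phase sine: best alignment at half the period
        y = -x
        assert abs(lag_recover(x, y, grid, 1.0)) == pytest.approx(100.0)


class TestClassification:
    def test_identical_is_complete(self):
        cls, _ = classify_sync(1.0, 0.0)
        assert cls == "complete"

    def test_high_correlation_is_approximate(self):
        cls, _ = classify_sync(0.98, 12.0)
        assert cls == "approximate"

    def test_phase_class(self):
        cls, _ = classify_sync(0.4, 50.0, dphi_max=3.0)
        assert cls == "phase"

    def test_lag_class(self):
        cls, _ = classify_sync(0.4, 50.0, dphi_max=100.0,
                               S_tau={0.0: 0.8, 35.0: 0.01})
        assert cls == "lag"

    def test_asynchronous_fallback(self):
        cls, _ = classify_sync(0.1, 70.0, dphi_max=100.0,
                               S_tau={0.0: 0.9, 35.0: 0.8})
        assert cls == "asynchronous"

    def test_out_of_phase_flag(self):
        _, oop = classify_sync(0.97, 30.0, S_tau={0.0: 0.5, 250.0: 0.02},
                               burst_period=500.0)
        assert oop


class TestSerialization:
    def test_similarity_curve_csv(self, tmp_path):
        from pbcsync.syncmetrics import SyncReport
        rep = SyncReport(R=0.5, max_e=10.0, S0=0.4,
                         S_tau={0.0: 0.4, 10.0: 0.1, -10.0: 0.6})
        rep.similarity_to_csv(tmp_path / "s.csv")
        import pandas as pd
        df = pd.read_csv(tmp_path / "s.csv")
        assert list(df.columns) == ["lag", "S"]
        assert df["lag"].is_monotonic_increasing
        assert len(df) == 3

    def test_phase_difference_csv(self, tmp_path):
        import pandas as pd
        from pbcsync.syncmetrics import phase_difference_to_csv
        t = np.linspace(0, 10, 5)
        phase_difference_to_csv(t, t, 0.5 * t, tmp_path / "p.csv")
        df = pd.read_csv(tmp_path / "p.csv")
        assert df["dphi"].to_numpy() == pytest.approx(0.5 * t)
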