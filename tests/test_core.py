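"""Unit and property tests for the slow-state integrator and binding solver."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adenosim import (ModelParameters, SystemState, atot_exact,
                      binding_equilibrium, integrate_segment, kinetic_oracle,
                      receptor_rate)
from adenosim.core import WAKE, _advance


class TestAtotExact:
    def test_at_asymptote_stays(self):
        assert atot_exact(869.5, 869.5, 18.18, 5.0) == pytest.approx(869.5)

    def test_saturation_limit(self):
        assert atot_exact(0.0, 869.5, 18.18, 1e6) == pytest.approx(
            869.5, abs=1e-6)

    def test_identity_at_zero_duration(self):
        assert atot_exact(596.4, 869.5, 18.18, 0.0) == 596.4

    def test_matches_rk4_integration_of_the_ode(self):
        # independent oracle: fixed-step RK4 on chi dA/dt = mu - A
        A, mu, chi, h = 596.4, 869.5, 18.18, 1e-4
        for _ in range(int(round(18.18 / h))):
            k1 = (mu - A) / chi
            k2 = (mu - (A + 0.5 * h * k1)) / chi
            k3 = (mu - (A + 0.5 * h * k2)) / chi
            k4 = (mu - (A + h * k3)) / chi
            A += h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        closed = atot_exact(596.4, 869.5, 18.18, 18.18)
        assert closed == pytest.approx(869.5 - 273.1 * math.exp(-1.0))
        assert closed == pytest.approx(A, rel=1e-10)

    @pytest.mark.parametrize("chi,dt", [(0.0, 1.0), (-1.0, 1.0), (1.0, -0.5)])
    def test_invalid_arguments(self, chi, dt):
        with pytest.raises(ValueError):
            atot_exact(100.0, 200.0, chi, dt)

    @given(A0=st.floats(0, 2000), mu=st.floats(1, 2000),
           dt1=st.floats(0, 50), dt2=st.floats(0, 50))
    @settings(max_examples=50, deadline=None)
    def test_monotone_toward_asymptote(self, A0, mu, dt1, dt2):
        lo, hi = sorted([dt1, dt2])
        d_lo = abs(atot_exact(A0, mu, 18.18, lo) - mu)
        d_hi = abs(atot_exact(A0, mu, 18.18, hi) - mu)
        assert d_hi <= d_lo + 1e-9


class TestBindingEquilibrium:
    def test_no_ligand_gives_empty_pools(self, full_fit):
        eq = binding_equilibrium(0.0, 600.0, full_fit)
        assert eq.A_u == eq.A1_b == eq.A2_b == 0.0
        assert eq.R1_u == 600.0

    def test_beta_direct_evaluation(self, full_fit):
        assert full_fit.beta == pytest.approx(300.0 / (300.0 + 100.0))

    def test_matches_mass_action_steady_state(self, full_fit):
        eq = binding_equilibrium(700.0, 600.0, full_fit)
        oracle = kinetic_oracle(700.0, 600.0, full_fit)
        assert eq.A1_b == pytest.approx(oracle.A1_b, rel=1e-6)
        assert eq.A1_b == pytest.approx(580.6, abs=0.05)

    def test_invalid_inputs(self, full_fit):
        with pytest.raises(ValueError):
            binding_equilibrium(-1.0, 600.0, full_fit)
        with pytest.raises(ValueError):
            binding_equilibrium(100.0, 0.0, full_fit)

    @given(A=st.floats(0, 2000), R=st.floats(1, 2000))
    @settings(max_examples=100, deadline=None)
    def test_conservation_and_dissociation(self, A, R):
        p = ModelParameters()
        eq = binding_equilibrium(A, R, p)
        # pool invariants
        assert eq.A_u + eq.A1_b + eq.A2_b == pytest.approx(
            A, rel=1e-9, abs=1e-12)
        assert eq.R1_u + eq.R1_b == pytest.approx(R, rel=1e-9)
        assert 0.0 <= eq.A1_b <= min(A, R) + 1e-9
        assert eq.R1_b == eq.A1_b and eq.R2_b == eq.A2_b
        if eq.R1_b > 1e-12:
            assert eq.A_u * eq.R1_u / eq.R1_b == pytest.approx(
                p.Kd1, rel=1e-9)

    @given(A=st.floats(1, 2000), R=st.floats(1, 2000),
           dA=st.floats(0.1, 100), dR=st.floats(0.1, 100))
    @settings(max_examples=60, deadline=None)
    def test_bound_pool_monotone_in_both_arguments(self, A, R, dA, dR):
        p = ModelParameters()
        base = binding_equilibrium(A, R, p).A1_b
        assert binding_equilibrium(A + dA, R, p).A1_b > base
        assert binding_equilibrium(A, R + dR, p).A1_b > base

    def test_vectorized_matches_scalar(self, full_fit):
        A = np.array([0.0, 100.0, 700.0, 1500.0])
        R = np.array([600.0, 600.0, 600.0, 900.0])
        eq = binding_equilibrium(A, R, full_fit)
        for i in range(A.size):
            s = binding_equilibrium(float(A[i]), float(R[i]), full_fit)
            assert eq.A1_b[i] == pytest.approx(s.A1_b, rel=1e-14, abs=1e-14)
            assert eq.A_u[i] == pytest.approx(s.A_u, rel=1e-14, abs=1e-14)


class TestKineticOracle:
    def test_equilibrium_satisfies_dissociation_relations(self, full_fit):
        eq = kinetic_oracle(500.0, 700.0, full_fit)
        assert eq.A_u * eq.R1_u / eq.R1_b == pytest.approx(
            full_fit.Kd1, rel=1e-8)
        assert eq.A_u * eq.R2_u / eq.R2_b == pytest.approx(
            full_fit.Kd2, rel=1e-8)

    def test_result_independent_of_rate_magnitudes(self, full_fit):
        slow = kinetic_oracle(700.0, 600.0, full_fit, k1b=1.0, k2b=1.0)
        fast = kinetic_oracle(700.0, 600.0, full_fit, k1b=100.0, k2b=100.0)
        assert slow.A1_b == pytest.approx(fast.A1_b, rel=1e-6)
        assert slow.A_u == pytest.approx(fast.A_u, rel=1e-6)

    def test_invalid_rates(self, full_fit):
        with pytest.raises(ValueError):
            kinetic_oracle(100.0, 600.0, full_fit, k1b=0.0)


class TestReceptorRate:
    def test_zero_at_target_occupancy(self, full_fit):
        assert receptor_rate(0.9677 * 600.0, 600.0, full_fit) == 0.0

    def test_full_occupancy_upregulates(self, full_fit):
        rate = receptor_rate(600.0, 600.0, full_fit)
        assert rate == pytest.approx((1 - 0.9677) * 600.0 / 291.0)
        assert rate > 0.0

    def test_low_occupancy_downregulates(self, full_fit):
        assert receptor_rate(0.5 * 600.0, 600.0, full_fit) < 0.0


class TestIntegrateSegment:
    def test_zero_duration_keeps_state(self, full_fit):
        s = SystemState(0.0, 700.0, 600.0, WAKE)
        out = integrate_segment(s, WAKE, 0.0, full_fit)
        assert out[-1].A_tot == s.A_tot
        assert out[-1].R1_tot == s.R1_tot
        assert out[-1].t == s.t

    def test_final_timestamp_exact_with_truncated_step(self, full_fit):
        s = SystemState(0.0, 700.0, 600.0, WAKE)
        out = integrate_segment(s, WAKE, 1.2345, full_fit, dt=0.01)
        assert out[-1].t == pytest.approx(1.2345, abs=1e-12)
        # dt larger than the duration: a single truncated step
        out2 = integrate_segment(s, WAKE, 0.004, full_fit, dt=0.01)
        assert out2[-1].t == pytest.approx(0.004, abs=1e-12)

    def test_step_halving_self_consistency(self, full_fit):
        # Richardson check: halving dt changes the endpoint negligibly
        s = (0.0, 650.0, 600.0)
        _, A1, R1 = _advance(*s, WAKE, 24.0, full_fit, 0.01)
        _, A2, R2 = _advance(*s, WAKE, 24.0, full_fit, 0.005)
        assert R1 == pytest.approx(R2, rel=1e-8)
        assert A1 == pytest.approx(A2, rel=1e-12)  # exact update

    def test_extended_wake_saturates_to_wake_asymptote(self, full_fit):
        from adenosim import limit_cycle, regular_day
        lc = limit_cycle(regular_day(8.0), full_fit)
        out = integrate_segment(lc, WAKE, 96.0, full_fit, dt=0.02)
        assert abs(out[-1].A_tot - full_fit.mu_wake) < 1.0

    def test_atot_bounded_by_asymptotes(self, full_fit):
        s = SystemState(0.0, 700.0, 600.0, WAKE)
        states = integrate_segment(s, WAKE, 48.0, full_fit, dt=0.05)
        A = np.array([x.A_tot for x in states])
        assert np.all(A >= min(full_fit.mu_sleep, 700.0) - 1e-9)
        assert np.all(A <= max(full_fit.mu_wake, 700.0) + 1e-9)
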