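"""Wave separation, loop estimators, reflection indices and coefficients."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulsewave.errors import EstimationError, UndefinedIndexError
from pulsewave.fixtures import make_superposed_waves
from pulsewave.network import analytic_wave_speed
from pulsewave.solver import HemoTimeSeries
from pulsewave.units import mmhg_to_pa
from pulsewave.waves import (augmentation_index, estimate_c_pu,
                             estimate_zc_pq, input_impedance, rp_bifurcation,
                             rp_taper, rp_terminal, separate_waves,
                             vessel_reflection_indices)

RHO = 1050.0


def _series(t, P, Q, A=None):
    if A is None:
        A = np.full_like(t, 3e-4)
    return HemoTimeSeries(vessel_id=0, cell_index=0, x=0.0, elevation=0.0,
                          t=t, P=P, Q=Q, A=A)


def _pulse_series(zc=1e7, amp=2000.0, base_q=0.0):
    t = np.linspace(0, 0.8, 801)
    q = base_q + 1e-4 * np.exp(-0.5 * ((t - 0.2) / 0.05) ** 2)
    p = 8000.0 + zc * q
    return _series(t, p, q)


class TestLoopEstimators:
    def test_pq_slope_recovers_linear_impedance_exactly(self):
        s = _pulse_series(zc=1.0e7)
        est = estimate_zc_pq(s)
        assert est.Zc == pytest.approx(1.0e7, rel=1e-6)
        assert est.r2 > 0.999999

    def test_pq_early_window_tolerates_late_reflected_bump(self):
        t = np.linspace(0, 0.8, 801)
        q = 3e-4 * np.exp(-0.5 * ((t - 0.2) / 0.05) ** 2)
        p_back = 800.0 * np.exp(-0.5 * ((t - 0.42) / 0.05) ** 2)
        s = _series(t, 8000.0 + 1e7 * q + p_back, q)
        assert estimate_zc_pq(s).Zc == pytest.approx(1e7, rel=0.05)

    def test_flat_flow_is_an_estimation_error(self):
        t = np.linspace(0, 0.8, 801)
        s = _series(t, 8000 + 100 * np.sin(2 * np.pi * t / 0.8),
                    np.full_like(t, 2e-5))
        with pytest.raises(EstimationError):
            estimate_zc_pq(s)

    def test_pu_slope_recovers_wave_speed_exactly(self):
        t = np.linspace(0, 0.8, 801)
        a0 = 3e-4
        q = 1e-4 * np.exp(-0.5 * ((t - 0.2) / 0.05) ** 2)
        p = 8000.0 + RHO * 5.0 * q / a0        # P = rho c U
        s = _series(t, p, q, np.full_like(t, a0))
        assert estimate_c_pu(s, RHO).c == pytest.approx(5.0, rel=1e-6)

    def test_pu_matches_tube_law_on_matched_tube(self, stiff_matched_beat):
        net, res = stiff_matched_beat
        s = res.node(1, 10)
        c_pu = estimate_c_pu(s, RHO).c
        c_true = float(analytic_wave_speed(s.A.mean(), net.vessels[1], RHO,
                                           cell_index=10))
        assert c_pu == pytest.approx(c_true, rel=0.02)

    def test_impedance_identity_across_methods(self, stiff_matched_beat):
        """Zc * A / (rho c) = 1 within 5% on the same node."""
        _, res = stiff_matched_beat
        s = res.node(1, 10)
        zc = estimate_zc_pq(s).Zc
        rc = estimate_c_pu(s, RHO).rho_c
        assert zc * s.A.mean() / rc == pytest.approx(1.0, abs=0.05)


class TestSeparation:
    def test_pure_forward_has_no_backward_component(self):
        s = _pulse_series(zc=2e7)
        s = _series(s.t, s.P - 8000.0, s.Q)  # P = Zc Q exactly
        sep = separate_waves(s, 2e7)
        assert np.allclose(sep.P_b, 0.0, atol=1e-10 * np.max(s.P))
        assert np.allclose(sep.Q_b, 0.0, atol=1e-10 * np.max(s.Q))

    def test_blocked_line_splits_static_pressure_evenly(self):
        t = np.linspace(0, 0.8, 801)
        p0 = mmhg_to_pa(100.0)
        s = _series(t, np.full_like(t, p0), np.zeros_like(t))
        sep = separate_waves(s, 1e7)
        assert np.allclose(sep.P_f, p0 / 2) and np.allclose(sep.P_b, p0 / 2)

    def test_synthesis_then_analysis_round_trip(self):
        zc = 1.1e7
        s, pf, pb = make_superposed_waves(
            (mmhg_to_pa(20.0), 0.2, 0.04), (mmhg_to_pa(8.0), 0.5, 0.04), zc)
        sep = separate_waves(s, zc)
        scale = np.max(np.abs(s.P))
        assert np.allclose(sep.P_f, pf, atol=1e-10 * scale)
        assert np.allclose(sep.P_b, pb, atol=1e-10 * scale)

    @given(st.floats(5e6, 5e7), st.floats(0.0, 3000.0))
    @settings(max_examples=30, deadline=None)
    def test_reconstruction_identities(self, zc, backward_amp):
        s, _, _ = make_superposed_waves((2500.0, 0.2, 0.05),
                                        (backward_amp, 0.5, 0.06), zc)
        sep = separate_waves(s, zc)
        assert np.allclose(sep.P_f + sep.P_b, s.P, rtol=1e-10, atol=1e-8)
        assert np.allclose(sep.Q_f + sep.Q_b, s.Q, rtol=1e-10, atol=1e-14)


class TestReflectionIndices:
    def test_printed_pulse_pressures_give_printed_rm(self):
        """PP_f 41 / PP_b 22 mmHg reproduce the reported supine RM 0.53."""
        zc = 1e7
        s, _, _ = make_superposed_waves((mmhg_to_pa(41.0), 0.2, 0.04),
                                        (mmhg_to_pa(22.0), 0.5, 0.04), zc)
        idx = vessel_reflection_indices([separate_waves(s, zc)])
        assert idx.RM == pytest.approx(22.0 / 41.0, rel=1e-9)
        assert idx.RM == pytest.approx(0.53, abs=0.02)

    def test_no_backward_wave_means_zero_indices(self):
        zc = 1e7
        s, _, _ = make_superposed_waves((2000.0, 0.2, 0.04), (0.0, 0.5, 0.04),
                                        zc)
        idx = vessel_reflection_indices([separate_waves(s, zc)])
        assert idx.RM == pytest.approx(0.0, abs=1e-10)
        assert idx.RI == pytest.approx(0.0, abs=1e-10)

    @given(st.floats(0.01, 5.0))
    @settings(max_examples=50, deadline=None)
    def test_ri_is_rm_over_one_plus_rm(self, rm):
        zc = 1e7
        s, _, _ = make_superposed_waves((2000.0, 0.2, 0.04),
                                        (2000.0 * rm, 0.5, 0.04), zc)
        idx = vessel_reflection_indices([separate_waves(s, zc)])
        assert idx.RI == pytest.approx(idx.RM / (1 + idx.RM), abs=1e-12)

    def test_zero_forward_pulse_is_undefined(self):
        t = np.linspace(0, 0.8, 801)
        s = _series(t, np.full_like(t, 1e4), np.zeros_like(t))
        sep = separate_waves(s, 1e7)
        sep.P_f[:] = sep.P_f.mean()   # flat forward component
        with pytest.raises(UndefinedIndexError):
            vessel_reflection_indices([sep])


class TestAugmentationIndex:
    @staticmethod
    def _beat(p_shape):
        t = np.linspace(0, 0.8, 801)
        return _series(t, p_shape(t), np.zeros_like(t) + 1e-5)

    def test_early_shoulder_gives_positive_ap_of_known_height(self):
        def shape(t):
            main = 3000.0 * np.exp(-0.5 * ((t - 0.30) / 0.07) ** 2)
            shoulder = 1200.0 * np.exp(-0.5 * ((t - 0.15) / 0.04) ** 2)
            return 1e4 + main + shoulder
        s = self._beat(shape)
        ap, ai = augmentation_index(s)
        assert ap > 0 and ai > 0
        p_sys = s.P.max()
        # AP is the systolic-minus-shoulder offset, here a known construction
        assert ap == pytest.approx(p_sys - shape(np.array([0.19]))[0],
                                   rel=0.35)

    def test_late_shoulder_gives_negative_ai(self):
        def shape(t):
            main = 3000.0 * np.exp(-0.5 * ((t - 0.22) / 0.05) ** 2)
            late = 1500.0 * np.exp(-0.5 * ((t - 0.40) / 0.05) ** 2)
            return 1e4 + main + late
        ap, ai = augmentation_index(self._beat(shape))
        assert ap < 0 and ai < 0

    def test_single_gaussian_pulse_is_flagged_not_zero(self):
        def shape(t):
            return 1e4 + 3000.0 * np.exp(-0.5 * ((t - 0.25) / 0.06) ** 2)
        with pytest.raises(UndefinedIndexError):
            augmentation_index(self._beat(shape))


class TestReflectionCoefficients:
    def test_bifurcation_forward_arithmetic(self):
        assert rp_bifurcation(1.0, [3.0, 6.0]).value == pytest.approx(1 / 3)
        assert rp_bifurcation(1.0, [2.0, 2.0]).value == pytest.approx(0.0)

    def test_bifurcation_backward_matched_forward_case(self):
        # daughters 2 Zp each (forward-matched): |R_back| = 0.5 per daughter
        rc = rp_bifurcation(1.0, [2.0, 2.0], "backward")
        assert rc.value == pytest.approx(0.5, rel=1e-12)
        assert all(abs(v) == pytest.approx(0.5) for v in
                   rc.impedances["per_daughter"])

    def test_backward_on_continuation_reduces_to_two_vessel_mismatch(self):
        rc = rp_bifurcation(1.0, [3.0], "backward")
        assert rc.value == pytest.approx(abs((1.0 - 3.0) / (1.0 + 3.0)))

    @pytest.mark.parametrize("zs, expect", [
        ([1.0, 1.0, 1.0], 0.0),
        ([1.0, 3.0], 0.5),
        ([1.0, 2.0, 4.0], 2.0 / 3.0),
    ])
    def test_taper_telescoped_sum(self, zs, expect):
        assert rp_taper(zs).value == pytest.approx(expect, rel=1e-12)

    @pytest.mark.parametrize("r_down, zc, expect", [
        (1e8, 1e8, 0.0), (1e20, 1e8, 1.0), (3e8, 1e8, 0.5),
    ])
    def test_terminal_limits(self, r_down, zc, expect):
        assert rp_terminal(r_down, zc).value == pytest.approx(expect, abs=1e-9)


class TestInputImpedance:
    def test_resistive_line_has_flat_modulus_and_zero_phase(self):
        t = np.linspace(0, 0.8, 801)
        q = 2e-5 + 1e-5 * np.sin(2 * np.pi * t / 0.8) \
            + 5e-6 * np.cos(2 * np.pi * 3 * t / 0.8)
        z = 2e8
        s = _series(t, z * q, q)
        spec = input_impedance(s, p_reference=0.0)
        defined = spec.defined
        assert np.allclose(spec.modulus[defined], z, rtol=1e-8)
        assert np.allclose(spec.phase[defined], 0.0, atol=1e-8)

    def test_dc_equals_total_downstream_resistance(self, uniform_beat):
        net, res = uniform_beat
        s = res.node(1, net.vessels[1].n_cells - 1)
        spec = input_impedance(s, p_reference=net.terminals[1].P_out)
        assert spec.modulus[0] == pytest.approx(net.terminals[1].R_down,
                                                rel=0.01)

    def test_high_frequency_plateau_near_zc(self, uniform_beat):
        net, res = uniform_beat
        s = res.node(1, net.vessels[1].n_cells - 1)
        spec = input_impedance(s)
        zc = estimate_zc_pq(s).Zc
        hi = spec.modulus[6:13][spec.defined[6:13]]
        assert np.mean(hi) == pytest.approx(zc, rel=0.20)
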