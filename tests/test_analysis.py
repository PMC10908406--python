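"""Wave-analysis oracles: power decomposition, wave intensity, separation,
reflection index, pulsatility, cerebral flow."""

import math

import numpy as np
import pytest

from hemopulse import (WaveformRecord, cerebral_blood_flow,
                       make_waterhammer_waveforms, power_decomposition,
                       pulsatility_index, reflection_index, wave_intensity,
                       wave_power, wave_separation)
from hemopulse.units import LMIN

RHO, C = 1050.0, 6.0


def _rec(P, Q, T=1.0, U=None, A=None):
    n = len(P)
    t = np.linspace(0.0, T, n)
    U = U if U is not None else Q / 3e-5
    A = A if A is not None else np.full(n, 3e-5)
    return WaveformRecord(site="s", t=t, P=np.asarray(P, float),
                          Q=np.asarray(Q, float), U=np.asarray(U, float),
                          A=A)


def _sine_rec(a, b, phi=0.0, pm=1e4, qm=1e-5, T=1.0, n=2001):
    t = np.linspace(0.0, T, n)
    w = 2 * np.pi / T
    return _rec(pm + a * np.sin(w * t), qm + b * np.sin(w * t + phi), T=T)


class TestPowerDecomposition:
    def test_constant_signals_have_no_pulsatile_power(self):
        r = _rec(np.full(101, 1.2e4), np.full(101, 2e-5))
        ptot, ps, pp = power_decomposition(r)
        assert pp == pytest.approx(0.0, abs=1e-12)
        assert ptot == pytest.approx(1.2e4 * 2e-5)

    @pytest.mark.parametrize("phi,expect", [
        (0.0, 0.5), (np.pi / 3, 0.25), (np.pi / 2, 0.0), (np.pi, -0.5)])
    def test_in_and_out_of_phase_sinusoids(self, phi, expect):
        """P_pulse = (a b / 2) cos(phi) for sinusoidal P and Q."""
        a, b = 800.0, 4e-6
        _, _, pp = power_decomposition(_sine_rec(a, b, phi))
        assert pp == pytest.approx(a * b * expect, abs=abs(a * b) * 2e-4)

    def test_total_is_steady_plus_pulsatile_exactly(self):
        r = _sine_rec(500.0, 3e-6, 0.7)
        ptot, ps, pp = power_decomposition(r)
        assert ptot == ps + pp  # identity by construction

    def test_offsets_shift_only_the_steady_part(self):
        r1 = _sine_rec(500.0, 3e-6)
        r2 = _sine_rec(500.0, 3e-6, pm=2e4)
        pp1 = power_decomposition(r1)[2]
        pp2 = power_decomposition(r2)[2]
        assert pp1 == pytest.approx(pp2, rel=1e-9)
        assert power_decomposition(r2)[1] > power_decomposition(r1)[1]

    def test_nonuniform_grid_rejected(self):
        r = _sine_rec(500.0, 3e-6)
        r.t = r.t**1.01
        with pytest.raises(ValueError):
            power_decomposition(r)


class TestWaveIntensity:
    def test_forward_waterhammer_is_nonnegative_and_matches_closed_form(self):
        rec, _, _ = make_waterhammer_waveforms(
            rho=RHO, c=C, pulses=[("forward", 2000.0, 0.3, 0.05)])
        wi = wave_intensity(rec)
        assert np.all(wi.dI >= -1e-9 * np.max(np.abs(wi.dI)))
        # analytic oracle: dI = (dP/dt)^2 / (rho c) for dP = rho c dU
        t0, sig = 0.3, 0.05
        dpdt = (-2000.0 * (rec.t - t0) / sig**2
                * np.exp(-0.5 * ((rec.t - t0) / sig) ** 2))
        expected = dpdt**2 / (RHO * C)
        np.testing.assert_allclose(wi.dI, expected, rtol=1e-4,
                                   atol=1e-5 * expected.max())

    def test_backward_wave_is_nonpositive(self):
        rec, _, _ = make_waterhammer_waveforms(
            rho=RHO, c=C, pulses=[("backward", 1500.0, 0.4, 0.05)])
        wi = wave_intensity(rec)
        assert np.all(wi.dI <= 1e-9 * np.max(np.abs(wi.dI)))

    def test_flat_signal_reports_undefined_peaks(self):
        r = _rec(np.full(200, 1e4), np.full(200, 1e-5))
        wi = wave_intensity(r)
        assert not wi.ok
        assert math.isnan(wi.fcwi)

    def test_model_cycle_shows_fcwi_bcwi_fewi_sequence(self, baseline):
        """Carotid pattern: forward compression peak, then a backward
        (negative) trough, then a forward expansion peak, in that order."""
        from hemopulse.fixtures import CAROTID_SITE
        wi = wave_intensity(baseline.record(CAROTID_SITE))
        assert wi.ok
        assert wi.fcwi > 0 and wi.bcwi > 0 and wi.fewi > 0
        assert wi.t_fcwi < wi.t_bcwi < wi.t_fewi
        assert wi.fcwi > wi.bcwi  # dominant forward compression

    def test_space_reversal_flips_the_net_intensity_integral(self):
        """Reversing time AND velocity turns forward waves into backward
        ones, so the net dI integral (the forward/backward asymmetry)
        changes sign.  (Time reversal alone flips both derivative signs and
        leaves dI invariant.)"""
        rec, _, _ = make_waterhammer_waveforms(
            rho=RHO, c=C, pulses=[("forward", 2000.0, 0.3, 0.05),
                                  ("backward", -700.0, 0.6, 0.05)])
        wi = wave_intensity(rec)
        rev = WaveformRecord(site="r", t=rec.t, P=rec.P[::-1].copy(),
                             Q=-rec.Q[::-1].copy(), U=-rec.U[::-1].copy(),
                             A=rec.A[::-1].copy())
        wi_r = wave_intensity(rev)
        assert np.trapezoid(wi.dI, rec.t) == pytest.approx(
            -np.trapezoid(wi_r.dI, rec.t), rel=1e-6)
        assert np.trapezoid(wi.dI, rec.t) > 0  # net forward dominance


class TestWavePower:
    def test_zero_flow_gives_zero_wave_power(self):
        r = _rec(1e4 + 500 * np.sin(np.linspace(0, 2 * np.pi, 500)),
                 np.zeros(500))
        wp, _ = wave_power(r)
        np.testing.assert_allclose(wp, 0.0, atol=1e-12)

    def test_bilinear_in_flow(self):
        rec, _, _ = make_waterhammer_waveforms(
            rho=RHO, c=C, pulses=[("forward", 2000.0, 0.3, 0.05)])
        _, fcwp1 = wave_power(rec)
        rec2 = WaveformRecord(site="x", t=rec.t, P=rec.P, Q=2 * rec.Q,
                              U=rec.U, A=rec.A)
        _, fcwp2 = wave_power(rec2)
        assert fcwp2 == pytest.approx(2 * fcwp1, rel=1e-9)
        assert fcwp1 > 0


class TestWaveSeparation:
    def test_forward_only_leaves_no_backward_component(self):
        rec, pf_truth, _ = make_waterhammer_waveforms(
            rho=RHO, c=C, pulses=[("forward", 2000.0, 0.3, 0.05)])
        pf, pb = wave_separation(rec, RHO, C)
        pulse = np.ptp(rec.P)
        assert np.max(np.abs(pb - pb.mean())) < 0.01 * pulse
        np.testing.assert_allclose(pf, pf_truth, atol=0.01 * pulse)

    def test_known_composition_recovered_within_2pct(self):
        rec, pf_truth, pb_truth = make_waterhammer_waveforms(
            rho=RHO, c=C, pulses=[("forward", 2000.0, 0.30, 0.05),
                                  ("backward", 2000.0, 0.55, 0.05)])
        pf, pb = wave_separation(rec, RHO, C)
        assert np.ptp(pb) == pytest.approx(np.ptp(pb_truth), rel=0.02)
        assert np.ptp(pf) == pytest.approx(np.ptp(pf_truth), rel=0.02)

    def test_components_sum_to_the_total_exactly(self):
        rec, _, _ = make_waterhammer_waveforms(
            rho=RHO, c=C, pulses=[("forward", 1200.0, 0.3, 0.04),
                                  ("backward", 900.0, 0.5, 0.06)])
        pf, pb = wave_separation(rec, RHO, C)
        np.testing.assert_allclose(pf + pb, rec.P, rtol=0.0, atol=1e-9)

    def test_invalid_wave_speed_rejected(self):
        rec, _, _ = make_waterhammer_waveforms()
        with pytest.raises(ValueError):
            wave_separation(rec, RHO, 0.0)


class TestReflectionIndex:
    def test_constant_backward_means_zero(self):
        p = 1e4 + 500 * np.sin(np.linspace(0, 2 * np.pi, 300))
        assert reflection_index(p, np.full(300, 3.0), p) == 0.0

    def test_equal_opposed_amplitudes_give_50pct(self):
        # +2000 Pa forward compression, -2000 Pa backward expansion: the
        # total waveform spans 4000 Pa, the backward component 2000 Pa
        rec, pf, pb = make_waterhammer_waveforms(
            rho=RHO, c=C, pulses=[("forward", 2000.0, 0.30, 0.05),
                                  ("backward", -2000.0, 0.55, 0.05)])
        ri = reflection_index(pf, pb, rec.P)
        assert ri == pytest.approx(50.0, rel=0.02)
        assert reflection_index(pf, pb, rec.P,
                                convention="peak_over_peak") >= 0.0

    def test_half_amplitude_backward_gives_a_third(self):
        rec, pf, pb = make_waterhammer_waveforms(
            rho=RHO, c=C, pulses=[("forward", 2000.0, 0.30, 0.04),
                                  ("backward", -1000.0, 0.60, 0.04)])
        ri = reflection_index(pf, pb, rec.P)
        # total spans +2000 to -1000 -> RI = 100 * 1000/3000
        assert ri == pytest.approx(33.3, abs=0.5)

    def test_zero_pulse_pressure_rejected(self):
        with pytest.raises(ValueError):
            reflection_index(np.ones(10), np.ones(10), np.ones(10))


class TestPulsatilityAndPerfusion:
    def test_constant_flow_has_zero_pulsatility(self):
        assert pulsatility_index(_rec(np.full(101, 1e4),
                                      np.full(101, 2e-5))) == 0.0

    def test_half_amplitude_sine_gives_exactly_one(self):
        t = np.linspace(0, 1, 2001)
        q = 1e-5 * (1 + 0.5 * np.sin(2 * np.pi * t))
        assert pulsatility_index(_rec(np.full(2001, 1e4), q)) == \
            pytest.approx(1.0, abs=1e-6)

    def test_nonpositive_mean_flow_rejected(self):
        with pytest.raises(ValueError):
            pulsatility_index(_rec(np.full(101, 1e4), np.full(101, -1e-5)))

    def test_cbf_sums_the_four_brain_arteries(self):
        recs = [_rec(np.full(101, 1e4), np.full(101, 0.2 * LMIN))
                for _ in range(4)]
        assert cerebral_blood_flow(recs) == pytest.approx(0.8, rel=1e-9)
        with pytest.raises(ValueError):
            cerebral_blood_flow(recs[:3])


class TestSamplingStability:
    def test_metrics_stable_above_500_hz(self, tree, heart, sites, baseline):
        """Doubling the output sampling rate of the converged cycle moves
        every scalar metric by < 0.5%."""
        from hemopulse import SolverConfig, run_to_periodic
        from hemopulse.fixtures import CAROTID_SITE
        hi = run_to_periodic(tree, heart, SolverConfig(sample_rate=2000.0),
                             sites=sites, warm_start=baseline)
        r1 = baseline.record(CAROTID_SITE)
        r2 = hi.record(CAROTID_SITE)
        for fn in (lambda r: power_decomposition(r)[2],
                   pulsatility_index,
                   lambda r: wave_intensity(r).fcwi,
                   lambda r: wave_intensity(r).bcwi):
            assert fn(r2) == pytest.approx(fn(r1), rel=5e-3)


class TestExternalWaveforms:
    def test_record_from_two_column_csvs(self, tmp_path):
        from hemopulse import record_from_csv
        t = np.linspace(0.0, 1.0, 501)
        p = 1e4 + 800 * np.sin(2 * np.pi * t)
        q = 1e-5 * (1 + 0.5 * np.sin(2 * np.pi * t))
        pcsv, qcsv = tmp_path / "p.csv", tmp_path / "q.csv"
        np.savetxt(pcsv, np.column_stack([t, p]), delimiter=",",
                   header="t,P", comments="")
        np.savetxt(qcsv, np.column_stack([t, q]), delimiter=",",
                   header="t,Q", comments="")
        rec = record_from_csv(pcsv, flow_csv=qcsv, area=3e-5)
        assert pulsatility_index(rec) == pytest.approx(1.0, abs=1e-3)
        _, _, pp = power_decomposition(rec)
        assert pp == pytest.approx(0.5 * 800 * 0.5e-5, rel=1e-3)
        with pytest.raises(ValueError):
            record_from_csv(pcsv)
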