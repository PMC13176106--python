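"""Filtering, differentiation, windowing, extraction, and hemodynamics."""

import numpy as np
import pytest

import ivsi
from ivsi import (ConventionalEcho, CycleParams, DomainError, FilterSpec,
                  ParameterError, PressureTrace, ResolutionError, ValveEvents,
                  butterworth_lowpass, closed_form_radial_strain,
                  conventional_ratios, differentiate, hemodynamics,
                  ivsi_extract, peak_phase_metric, simulate_cycle,
                  window_trace)


def sine_amplitude(x, t, f):
    """Amplitude of the f-Hz component by quadrature demodulation."""
    return 2.0 * abs(np.mean(x * np.exp(-2j * np.pi * f * t)))


class TestButterworth:
    def test_dc_gain_unity(self, trace_factory):
        tr = trace_factory(np.full(2000, 3.7))
        for mode in ("single_pass", "zero_phase"):
            out = butterworth_lowpass(tr, FilterSpec(application=mode))
            # steady state after the causal startup transient has decayed
            np.testing.assert_allclose(out.values[1000:], 3.7, rtol=1e-6)

    @pytest.mark.parametrize("freq,expected,tol", [
        (20.0, 2 ** -0.5, 0.02),            # gain at the cutoff
        (200.0, (1 + 10 ** 4) ** -0.5, 0.10),  # analytic law at 10 fc
    ])
    def test_single_pass_magnitude_law(self, trace_factory, freq, expected,
                                       tol):
        fs = 10_000.0
        t = np.arange(int(fs)) / fs
        tr = trace_factory(np.sin(2 * np.pi * freq * t), fs=fs)
        out = butterworth_lowpass(tr, FilterSpec(application="single_pass"))
        # discard the transient before measuring the steady-state amplitude
        n0 = len(t) // 2
        amp = sine_amplitude(out.values[n0:], t[n0:], freq)
        assert amp == pytest.approx(expected, rel=tol)

    def test_cutoff_at_nyquist_rejected(self, trace_factory):
        tr = trace_factory(np.zeros(100), fs=40.0)
        with pytest.raises(ParameterError):
            butterworth_lowpass(tr, FilterSpec(cutoff_hz=20.0))

    def test_energy_never_increases(self, trace_factory):
        rng = np.random.default_rng(3)
        for mode in ("single_pass", "zero_phase"):
            x = rng.normal(size=4000)
            out = butterworth_lowpass(trace_factory(x),
                                      FilterSpec(application=mode))
            assert np.sum(out.values ** 2) <= np.sum(x ** 2)

    def test_zero_phase_preserves_pulse_timing(self, trace_factory):
        t = np.arange(1000) / 1000.0
        pulse = np.exp(-0.5 * ((t - 0.5) / 0.05) ** 2)
        tr = trace_factory(pulse)
        zp = butterworth_lowpass(tr, FilterSpec(application="zero_phase"))
        assert abs(int(np.argmax(zp.values)) - 500) <= 1
        sp = butterworth_lowpass(tr, FilterSpec(application="single_pass"))
        assert int(np.argmax(sp.values)) > 501  # causal pass lags


class TestDifferentiate:
    def test_linear_ramp_constant_slope(self, trace_factory):
        t = np.arange(100) / 1000.0
        out = differentiate(trace_factory(4.2 * t * 1000))
        np.testing.assert_allclose(out.values, 4200.0, rtol=1e-9)
        assert out.kind == "strain_rate" and out.unit == "%/s"

    def test_constant_trace_zero(self, trace_factory):
        out = differentiate(trace_factory(np.full(50, 2.0)))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-9)

    def test_sine_analytic_derivative(self, trace_factory):
        t = np.arange(1000) / 1000.0
        out = differentiate(trace_factory(np.sin(2 * np.pi * 5 * t)))
        exact = 10 * np.pi * np.cos(2 * np.pi * 5 * t)
        assert np.max(np.abs(out.values - exact)) < 1e-3 * 10 * np.pi

    def test_kind_and_unit_chain(self, trace_factory):
        sr = differentiate(trace_factory(np.sin(np.arange(10.0))))
        acc = differentiate(sr)
        assert (sr.kind, acc.kind) == ("strain_rate", "acceleration")
        assert (sr.unit, acc.unit) == ("%/s", "%/s^2")
        with pytest.raises(ParameterError):
            differentiate(acc)  # jerk is not a tracked kind

    def test_too_short(self, trace_factory):
        with pytest.raises(ResolutionError):
            differentiate(trace_factory(np.zeros(2)))

    def test_derivative_of_cumsum_identity(self, trace_factory):
        """differentiate after trapezoidal integration recovers a smooth
        signal to O(dt^2)."""
        fs = 1000.0
        t = np.arange(500) / fs
        x = np.sin(2 * np.pi * 3 * t)
        integral = np.concatenate([[0.0], np.cumsum(
            (x[1:] + x[:-1]) / 2)]) / fs
        out = differentiate(trace_factory(integral * 100))
        np.testing.assert_allclose(out.values[2:-2] / 100, x[2:-2],
                                   atol=2e-4)


class TestWindowing:
    def test_ivrt_inclusive_sample_count(self, trace_factory, events_50_68):
        tr = trace_factory(np.zeros(140))
        win, sub = window_trace(tr, events_50_68, "ivrt")
        assert sub.n == 19
        assert (win.t_start, win.t_end) == (0.050, 0.068)

    def test_low_frame_rate_resolution_error(self, events_50_68):
        t = np.arange(14) / 100.0
        tr = ivsi.StrainTrace(time=t, values=np.zeros(14),
                              direction="radial", layer="endocardial",
                              segment_id=1, kind="strain")
        with pytest.raises(ResolutionError):
            window_trace(tr, events_50_68, "ivrt")

    def test_window_outside_span(self, trace_factory):
        ev = ValveEvents(0.0, 0.050, 0.068, 0.140)
        tr = trace_factory(np.zeros(40))  # spans 0..0.039 s only
        with pytest.raises(ParameterError):
            window_trace(tr, ev, "ivrt")

    def test_windowed_start_matches_closed_form(self, noiseless_radial_cycle):
        cyc = noiseless_radial_cycle
        tr = cyc.traces[0]
        _, sub = window_trace(tr, cyc.events, "ivrt")
        p = cyc.params
        gain = p.layer_gains["endocardial"] * p.segment_gains[0]
        expected = closed_form_radial_strain(
            np.array([cyc.events.avc_time]), p, gain=gain)[0]
        assert sub.values[0] == pytest.approx(expected, rel=1e-9)

    def test_all_labels_nest_in_cycle(self, noiseless_radial_cycle):
        cyc = noiseless_radial_cycle
        for label in ("ivrt", "early_diastole", "systole", "full_diastole"):
            win, sub = window_trace(cyc.traces[0], cyc.events, label)
            assert win.t_start >= cyc.events.cycle_start - 1e-12
            assert win.t_end <= cyc.events.cycle_end + 1e-12
            assert sub.n >= 3


class TestIvsiExtract:
    def test_constant_strain_rate(self, trace_factory, events_50_68):
        tr = trace_factory(np.ones(140), kind="strain_rate", unit="%/s")
        m = ivsi_extract([tr], events_50_68)
        assert m.get("radial", "strain_rate", "max_value", segment=1) == 1.0
        assert m.get("radial", "strain_rate", "min_value", segment=1) == 1.0
        assert m.get("radial", "strain_rate", "max_accel", segment=1) == \
            pytest.approx(0.0, abs=1e-9)
        assert m.get("radial", "strain_rate", "min_accel", segment=1) == \
            pytest.approx(0.0, abs=1e-9)

    def test_quadratic_strain_constant_acceleration(self, trace_factory,
                                                    events_50_68):
        """s = -(t-t0)^2 has d2s/dt2 = -2 everywhere, so the windowed
        acceleration extrema coincide at -2."""
        t = np.arange(140) / 1000.0
        tr = trace_factory(-(t - 0.059) ** 2)
        m = ivsi_extract([tr], events_50_68, derive_rates=False)
        assert m.get("radial", "strain", "min_accel", segment=1,
                     signed=True) == pytest.approx(-2.0, rel=1e-6)
        assert m.get("radial", "strain", "max_accel", segment=1,
                     signed=True) == pytest.approx(-2.0, rel=1e-6)

    def test_rate_signal_differentiated_once(self, trace_factory,
                                             events_50_68):
        """Acceleration of a strain-rate signal is its first derivative."""
        t = np.arange(140) / 1000.0
        tr = trace_factory(-3.0 * t * 1000, kind="strain_rate", unit="%/s")
        m = ivsi_extract([tr], events_50_68)
        assert m.get("radial", "strain_rate", "min_accel", segment=1,
                     signed=True) == pytest.approx(-3000.0, rel=1e-9)

    def test_abs_and_mean_invariants(self, noiseless_cycle):
        m = ivsi_extract(noiseless_cycle.traces, noiseless_cycle.events)
        t = m.table
        np.testing.assert_allclose(t["abs"], np.abs(t["signed"]))
        segs = t[t.segment_id != "mean"]
        means = t[t.segment_id == "mean"]
        for _, row in means.iterrows():
            sel = segs[(segs.direction == row.direction)
                       & (segs.layer == row.layer) & (segs.kind == row.kind)
                       & (segs.metric == row.metric)]
            assert row["signed"] == pytest.approx(sel["signed"].mean())
        # per-signal ordering
        piv = t.pivot_table(index=["direction", "layer", "kind",
                                   "segment_id"], columns="metric",
                            values="signed", aggfunc="first")
        assert (piv["min_value"] <= piv["max_value"] + 1e-12).all()
        assert (piv["min_accel"] <= piv["max_accel"] + 1e-12).all()

    def test_scaling_equivariance(self, noiseless_radial_cycle):
        cyc = noiseless_radial_cycle
        m1 = ivsi_extract(cyc.traces, cyc.events)
        scaled = [tr.with_values(tr.values * 3.0) for tr in cyc.traces]
        m3 = ivsi_extract(scaled, cyc.events)
        np.testing.assert_allclose(m3.table["signed"],
                                   3.0 * m1.table["signed"], rtol=1e-9)

    def test_time_shift_invariance(self, noiseless_radial_cycle):
        cyc = noiseless_radial_cycle
        shift = 0.25
        ev = cyc.events
        shifted_traces = [
            ivsi.StrainTrace(time=tr.time + shift, values=tr.values,
                             direction=tr.direction, layer=tr.layer,
                             segment_id=tr.segment_id, kind=tr.kind,
                             unit=tr.unit) for tr in cyc.traces]
        shifted_ev = ValveEvents(ev.cycle_start + shift, ev.avc_time + shift,
                                 ev.mvo_time + shift, ev.cycle_end + shift)
        m0 = ivsi_extract(cyc.traces, cyc.events)
        m1 = ivsi_extract(shifted_traces, shifted_ev)
        np.testing.assert_allclose(m1.table["signed"], m0.table["signed"],
                                   rtol=1e-9)


class TestPeakPhaseMetric:
    def test_monotone_trace_systolic_peak_at_window_end(self, trace_factory):
        ev = ValveEvents(0.0, 0.050, 0.068, 0.139)
        t = np.arange(140) / 1000.0
        tr = trace_factory(t * 100)
        assert peak_phase_metric(tr, ev, "systole") == \
            pytest.approx(100 * 0.050)

    def test_e_wave_raised_cosine_peak(self, trace_factory):
        """A pure raised-cosine E-wave of amplitude -a peaks at -a."""
        ev = ValveEvents(0.0, 0.040, 0.060, 0.139, e_end=0.100)
        t = np.arange(140) / 1000.0
        vals = np.zeros_like(t)
        m = (t >= 0.060) & (t <= 0.100)
        vals[m] = -5.0 * 0.5 * (1 - np.cos(2 * np.pi * (t[m] - 0.060)
                                           / 0.040))
        tr = trace_factory(vals, kind="strain_rate", unit="%/s")
        assert peak_phase_metric(tr, ev, "early_diastole") == \
            pytest.approx(-5.0, rel=1e-6)

    def test_average_peak_is_segment_mean(self, noiseless_radial_cycle):
        cyc = noiseless_radial_cycle
        rates = [differentiate(tr) for tr in cyc.traces]
        avg = ivsi.average_peak(rates, cyc.events, "early_diastole")
        per_seg = [peak_phase_metric(tr, cyc.events, "early_diastole")
                   for tr in rates]
        assert avg == pytest.approx(np.mean(per_seg))


class TestHemodynamics:
    def make_pressure(self, tau=0.010, fs=10_000.0, p0=40.0, noise=0.0,
                      seed=0):
        t = np.arange(int(0.140 * fs)) / fs
        ev = ValveEvents(0.0, 0.050, 0.068, 0.139)
        p = np.empty_like(t)
        rise = t <= 0.050
        p[rise] = 5.0 + (p0 - 5.0) * np.sin(np.pi * t[rise] / 0.100) ** 2
        p[~rise] = p0 * np.exp(-(t[~rise] - 0.050) / tau)
        if noise:
            p = p + np.random.default_rng(seed).normal(0, noise, p.size)
            p = np.maximum(p, 0.5)
        return PressureTrace(time=t, pressure=p), ev

    def test_weiss_tau_exact_on_exponential(self):
        pt, ev = self.make_pressure(tau=0.010)
        hm = hemodynamics(pt, ev)
        assert hm.tau_weiss == pytest.approx(10.0, rel=1e-3)
        assert hm.dpdt_max > 0 > hm.dpdt_min

    def test_tau_invariant_to_pressure_scale(self):
        pt, ev = self.make_pressure()
        doubled = PressureTrace(time=pt.time, pressure=2 * pt.pressure)
        assert hemodynamics(doubled, ev).tau_weiss == \
            pytest.approx(hemodynamics(pt, ev).tau_weiss, rel=1e-9)

    def test_noisy_exponential_recovered_within_5pct(self):
        pt, ev = self.make_pressure(tau=0.010, fs=10_000.0, noise=0.5,
                                    seed=12)
        assert hemodynamics(pt, ev).tau_weiss == pytest.approx(10.0,
                                                               rel=0.05)

    def test_simulator_pressure_recovers_tau_active(self,
                                                    noiseless_radial_cycle):
        cyc = noiseless_radial_cycle
        hm = hemodynamics(cyc.pressure, cyc.events)
        assert hm.tau_weiss == pytest.approx(cyc.params.tau_active, rel=0.01)

    def test_nonpositive_pressure_rejected(self):
        pt, ev = self.make_pressure()
        bad = PressureTrace(time=pt.time, pressure=pt.pressure - 50.0)
        with pytest.raises(DomainError):
            hemodynamics(bad, ev)


class TestConventionalRatios:
    def test_fs_and_teichholz_ef(self):
        echo = ConventionalEcho(lvidd=4.0, lvids=2.0, e_wave=700, a_wave=700,
                                e_prime=25)
        out = conventional_ratios(echo)
        assert out["FS"] == pytest.approx(50.0)
        assert out["LV_Vold"] == pytest.approx(70.0)
        assert out["LV_Vols"] == pytest.approx(12.7273, rel=1e-4)
        assert out["EF"] == pytest.approx(81.8, abs=0.05)
        assert out["E_A"] == pytest.approx(1.0)
        assert out["E_Eprime"] == pytest.approx(28.0)

    def test_lvids_ge_lvidd_rejected(self):
        with pytest.raises(DomainError):
            ConventionalEcho(lvidd=2.0, lvids=2.0, e_wave=1, a_wave=1,
                             e_prime=1)


class TestPipelineOracleAgreement:
    def test_metrics_match_dense_grid_within_5pct(self):
        """1000 Hz unfiltered extraction vs a 10 kHz dense evaluation of the
        same closed-form kinematics, across a tau grid."""
        for tau in (12.0, 24.0):
            coarse = simulate_cycle(CycleParams(noise_sd=0.0,
                                                tau_active=tau),
                                    directions=("radial",),
                                    layers=("endocardial",))
            m = ivsi_extract(coarse.traces, coarse.events)
            v_coarse = m.min_accel_radial_strain_rate()
            p = CycleParams(noise_sd=0.0, tau_active=tau, frame_rate=10_000)
            t = np.arange(int(round(p.cycle_length * 10_000))) / 10_000
            vals = []
            for k, g in enumerate(p.segment_gains, start=1):
                s = closed_form_radial_strain(t, p, gain=g)
                acc = np.gradient(np.gradient(s, 1e-4, edge_order=2), 1e-4,
                                  edge_order=2)
                ev = p.valve_events()
                mask = (t >= ev.avc_time - 1e-9) & (t <= ev.mvo_time + 1e-9)
                vals.append(abs(acc[mask].min()))
            assert v_coarse == pytest.approx(np.mean(vals), rel=0.05)
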