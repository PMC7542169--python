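"""Integration, spike detection, feature extraction, spectral analysis."""

import numpy as np
import pytest

from pacesim.model import steady_gates
from pacesim.simulate import (
    Trace,
    cessation_test,
    dimensionless_waveform,
    dominant_frequency,
    extract_features,
    integrate,
    read_trace,
    write_trace,
)
from pacesim.synth import RecordingSpec, make_recording


def _sinusoid(freq_hz=300.0, amp=10.0, offset=-55.0, duration_ms=50.0, dt=0.002):
    t = dt * np.arange(int(duration_ms / dt) + 1)
    return Trace(t0=0.0, dt=dt, v=offset + amp * np.sin(2 * np.pi * freq_hz * t / 1000.0))


class TestIntegrate:
    def test_leak_only_matches_closed_form(self, leak_only):
        v0 = -40.0
        tr = integrate(leak_only, 40.0, dt=0.01,
                       initial=steady_gates(v0, leak_only))
        expected = leak_only.E_Leak + (v0 - leak_only.E_Leak) * np.exp(
            -leak_only.G_Leak * tr.t)
        assert np.max(np.abs(tr.v - expected)) < 1e-3

    def test_canonical_oscillates_post_transient(self, canonical_trace):
        feat = extract_features(canonical_trace.window(50.0))
        assert feat.frequency > 100.0
        assert feat.peak_to_peak > 5.0

    def test_step_halving_changes_little(self, canonical):
        # dt is only the output grid; halving it must not move samples
        tr1 = integrate(canonical, 60.0, dt=0.02)
        tr2 = integrate(canonical, 60.0, dt=0.01)
        assert np.max(np.abs(tr1.v - tr2.v[::2])) < 0.1

    def test_nearby_starts_converge_to_same_cycle(self, canonical):
        from pacesim.fitting import align_by_first_spike, rms_error
        tr1 = integrate(canonical, 250.0, dt=0.01, keep_gates=True)
        y = np.concatenate([[tr1.v[-1] + 0.5], np.clip(tr1.gates[:, -1] * 1.01, 0, 1)])
        from pacesim.model import ModelState
        tr2 = integrate(canonical, 250.0, dt=0.01,
                        initial=ModelState.from_array(y))
        a, b = align_by_first_spike(tr1.window(200.0), tr2.window(200.0))
        assert rms_error(a, b) < 0.1

    def test_rejects_bad_arguments(self, leak_only):
        with pytest.raises(ValueError):
            integrate(leak_only, -1.0)


class TestExtractFeatures:
    def test_sinusoid_closed_form(self):
        f, a = 300.0, 10.0
        tr = _sinusoid(freq_hz=f, amp=a)
        feat = extract_features(tr)
        assert feat.frequency == pytest.approx(f, rel=0.01)
        assert feat.peak_to_peak == pytest.approx(2 * a, rel=1e-3)
        rate = 2 * np.pi * f * a / 1000.0  # mV/ms
        assert feat.max_rise_rate == pytest.approx(rate, rel=1e-3)
        assert feat.max_fall_rate == pytest.approx(rate, rel=1e-3)

    def test_constant_trace_is_rest(self):
        tr = Trace(t0=0.0, dt=0.01, v=np.full(1000, -60.0))
        feat = extract_features(tr)
        assert feat.frequency == 0.0
        assert feat.peak_to_peak == 0.0

    def test_time_reversal_swaps_rates(self, canonical_trace):
        w = canonical_trace.window(50.0, 150.0)
        fwd = extract_features(w)
        rev = extract_features(Trace(t0=0.0, dt=w.dt, v=w.v[::-1].copy()))
        assert fwd.max_rise_rate == pytest.approx(rev.max_fall_rate, rel=1e-9)
        assert fwd.max_fall_rate == pytest.approx(rev.max_rise_rate, rel=1e-9)

    def test_offset_invariance(self, canonical_trace):
        w = canonical_trace.window(50.0, 150.0)
        shifted = Trace(t0=w.t0, dt=w.dt, v=w.v + 17.3)
        f0, f1 = extract_features(w), extract_features(shifted)
        assert f0.frequency == pytest.approx(f1.frequency)
        assert f0.peak_to_peak == pytest.approx(f1.peak_to_peak)
        assert f0.max_rise_rate == pytest.approx(f1.max_rise_rate)


class TestDimensionlessWaveform:
    def test_spans_unit_interval(self, canonical_trace):
        w = dimensionless_waveform(canonical_trace.window(50.0))
        assert w.min() == pytest.approx(0.0)
        assert w.max() == pytest.approx(1.0)

    def test_gain_and_timescale_invariance(self, canonical_trace):
        base = canonical_trace.window(50.0, 150.0)
        w1 = dimensionless_waveform(base)
        scaled = Trace(t0=0.0, dt=base.dt * 2.5, v=3.0 * base.v + 40.0)
        w2 = dimensionless_waveform(scaled)
        assert np.max(np.abs(w1 - w2)) < 1e-6

    def test_needs_spikes(self):
        tr = Trace(t0=0.0, dt=0.01, v=np.full(1000, -60.0))
        with pytest.raises(ValueError):
            dimensionless_waveform(tr)


class TestSpectral:
    def test_dominant_frequency_of_sinusoid(self):
        tr = _sinusoid(freq_hz=437.0, duration_ms=1000.0, dt=0.01)
        f, p = dominant_frequency(tr)
        assert abs(f - 437.0) <= 1.0

    def test_pure_line_noise(self):
        tr = _sinusoid(freq_hz=60.0, duration_ms=1000.0, dt=0.01)
        f, _ = dominant_frequency(tr)
        assert abs(f - 60.0) <= 1.0

    def test_larger_power_wins(self):
        t = 0.01 * np.arange(100001)
        v = np.sin(2 * np.pi * 0.3 * t) + 0.1 * np.sin(2 * np.pi * 0.06 * t)
        tr = Trace(t0=0.0, dt=0.01, v=v)
        f, _ = dominant_frequency(tr)
        assert abs(f - 300.0) <= 1.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            dominant_frequency(_sinusoid(duration_ms=200.0))

    def test_agrees_with_interval_frequency_on_spike_train(self):
        rec = make_recording(RecordingSpec(spike_frequency=400.0, noise_sd=0.0,
                                           line60_amplitude=0.0))
        f_spec, _ = dominant_frequency(rec)
        feat = extract_features(rec)
        assert abs(f_spec - feat.frequency) <= 1.0


class TestCessation:
    def test_strong_spiking_is_firing(self):
        rec = make_recording(RecordingSpec(spike_frequency=400.0,
                                           spike_amplitude=1.0,
                                           noise_sd=0.02,
                                           line60_amplitude=0.05, seed=1))
        assert cessation_test(rec) == "firing"

    def test_low_snr_off_harmonic_is_ceased(self):
        # weak 170 Hz dominant component, >= 10 Hz from any 60 Hz harmonic
        t = np.arange(100000) / 1e5
        v = 1.0 * np.sin(2 * np.pi * 60 * t) + 1.1 * np.sin(2 * np.pi * 170 * t)
        tr = Trace(t0=0.0, dt=0.01, v=v)
        verdict = cessation_test(tr)
        assert verdict == "ceased"

    def test_low_snr_near_harmonic_is_rejected(self):
        t = np.arange(100000) / 1e5
        v = 1.0 * np.sin(2 * np.pi * 60 * t) + 1.1 * np.sin(2 * np.pi * 182 * t)
        tr = Trace(t0=0.0, dt=0.01, v=v)
        assert cessation_test(tr) == "rejected_noisy"


class TestTraceIO:
    def test_round_trip(self, tmp_path, canonical_trace):
        w = canonical_trace.window(50.0, 60.0)
        path = tmp_path / "trace.csv"
        write_trace(w, path)
        back = read_trace(path)
        assert back.dt == pytest.approx(w.dt, rel=1e-9)
        assert np.allclose(back.v, w.v, atol=1e-6)
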