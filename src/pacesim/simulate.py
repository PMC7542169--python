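"""Time integration, spike detection and waveform-feature extraction.

The analysis pipeline mirrors standard pacemaker-slice practice: simulate
(or load) a membrane-potential trace, detect action-potential peaks, and
summarize the waveform by oscillation frequency, peak-to-peak amplitude,
and maximal rise/fall rates.  A Fourier-based dominant-frequency measure
and a signal-to-noise cessation criterion handle noisy extracellular-style
recordings sampled at 100 kHz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks

from .model import ModelParams, ModelState, vector_field, jacobian

__all__ = [
    "Trace",
    "WaveformFeatures",
    "IntegrationError",
    "integrate",
    "detect_spikes",
    "extract_features",
    "dimensionless_waveform",
    "dominant_frequency",
    "cessation_test",
    "read_trace",
    "write_trace",
]

#: default transient discarded before limit-cycle statistics (ms);
#: >= ~13 cycles at 260 Hz
DEFAULT_TRANSIENT_MS = 50.0


class IntegrationError(RuntimeError):
    """Integration produced a non-finite state or failed to converge."""


@dataclass
class Trace:
    """Uniformly sampled membrane-potential time series.

    Attributes
    ----------
    t0 : float
        Time of the first sample (ms).
    dt : float
        Sampling interval (ms); must be > 0.
    v : ndarray
        Voltage samples (mV); at least two, all finite.
    gates : ndarray or None
        Optional (6, N) array of gate samples in b, g, m, h, n, q order.
    """

    t0: float
    dt: float
    v: np.ndarray
    gates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.v.size < 2:
            raise ValueError("trace needs at least 2 samples")
        if not np.all(np.isfinite(self.v)):
            raise ValueError("trace contains non-finite samples")

    @property
    def t(self) -> np.ndarray:
        """Sample times (ms)."""
        return self.t0 + self.dt * np.arange(self.v.size)

    @property
    def duration(self) -> float:
        return self.dt * (self.v.size - 1)

    def window(self, start: float, stop: float | None = None) -> "Trace":
        """Sub-trace for times in [start, stop] (ms, absolute)."""
        t = self.t
        stop = t[-1] if stop is None else stop
        mask = (t >= start) & (t <= stop)
        if mask.sum() < 2:
            raise ValueError("window too short")
        g = self.gates[:, mask] if self.gates is not None else None
        return Trace(t0=float(t[mask][0]), dt=self.dt, v=self.v[mask], gates=g)


@dataclass
class WaveformFeatures:
    """Scalar summary of an oscillating (or resting) waveform.

    ``frequency`` is 1/mean inter-peak interval in Hz, with 0 encoding the
    rest state.  ``max_fall_rate`` is reported as a positive magnitude.
    """

    frequency: float
    peak_to_peak: float
    max_rise_rate: float
    max_fall_rate: float
    spike_times: np.ndarray = field(default_factory=lambda: np.array([]))


def integrate(
    params: ModelParams,
    duration: float,
    dt: float = 0.01,
    initial: ModelState | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    keep_gates: bool = False,
) -> Trace:
    """Integrate the pacemaker model and sample it on a uniform grid.

    Uses LSODA (adaptive, stiff-capable) with tight tolerances; the dense
    output is sampled every ``dt`` ms so downstream feature extraction sees
    a uniform grid regardless of internal step sizes.

    Parameters
    ----------
    params : ModelParams
    duration : float
        Total simulated time (ms).
    dt : float
        Output sampling interval (ms).
    initial : ModelState, optional
        Starting state; defaults to all gates at steady state for v = -70 mV.
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    if initial is None:
        from .model import steady_gates
        initial = steady_gates(-70.0, params)
    y0 = initial.to_array()
    n = int(np.ceil(duration / dt)) + 1
    t_eval = dt * np.arange(n)

    sol = solve_ivp(
        lambda t, y: vector_field(y, params),
        (0.0, t_eval[-1]),
        y0,
        method="LSODA",
        jac=lambda t, y: jacobian(y, params),
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"integration failed: {sol.message}")
    if not np.all(np.isfinite(sol.y)):
        bad = np.argmax(~np.all(np.isfinite(sol.y), axis=0))
        raise IntegrationError(f"non-finite state at t = {t_eval[bad]:.3f} ms")
    gates = sol.y[1:] if keep_gates else None
    return Trace(t0=0.0, dt=dt, v=sol.y[0], gates=gates)


def detect_spikes(trace: Trace, threshold: float | None = None) -> np.ndarray:
    """Spike (action-potential peak) times in ms.

    A spike is a local voltage maximum above ``threshold``; by default the
    threshold is the midpoint of the trace's global min/max, which a flat
    trace never crosses as a local maximum with prominence.
    """
    v = trace.v
    vmin, vmax = v.min(), v.max()
    if threshold is None:
        threshold = 0.5 * (vmin + vmax)
    if vmax - vmin < 1e-9:
        return np.array([])
    idx, _ = find_peaks(v, height=threshold)
    return trace.t0 + trace.dt * idx


def extract_features(trace: Trace, spike_threshold: float | None = None) -> WaveformFeatures:
    """Waveform features over the (assumed post-transient) trace.

    frequency = 1000 / mean inter-spike-peak interval (Hz), 0 with < 2
    spikes; peak_to_peak = max - min voltage; rise/fall rates are extrema
    of the first difference quotient, fall as positive magnitude.
    """
    if trace.v.size < 3:
        raise ValueError("trace too short for feature extraction")
    spikes = detect_spikes(trace, spike_threshold)
    if spikes.size >= 2:
        freq = 1000.0 / np.mean(np.diff(spikes))
    else:
        freq = 0.0
    dvdt = np.gradient(trace.v, trace.dt)
    return WaveformFeatures(
        frequency=float(freq),
        peak_to_peak=float(trace.v.max() - trace.v.min()),
        max_rise_rate=float(max(dvdt.max(), 0.0)),
        max_fall_rate=float(max(-dvdt.min(), 0.0)),
        spike_times=spikes,
    )


def sustained_features(trace: Trace, transient: float = DEFAULT_TRANSIENT_MS,
                       amp_floor: float = 0.5,
                       decay_ratio: float = 0.7) -> WaveformFeatures:
    """Features of a *sustained* oscillation, with rest reported as 0 Hz.

    Near a Hopf bifurcation a transient can ring for hundreds of
    milliseconds while slowly decaying toward a stable fixed point.  To
    avoid mistaking such ringing for a limit cycle, the post-transient
    window is split in half: the oscillation counts as sustained only if
    the second half clears ``amp_floor`` (mV peak-to-peak) and has not
    decayed below ``decay_ratio`` times the first half's amplitude.
    Features are measured on the second half.
    """
    w = trace.window(trace.t0 + transient)
    mid = w.t0 + 0.5 * w.duration
    first, second = w.window(w.t0, mid), w.window(mid)
    amp1 = float(first.v.max() - first.v.min())
    feat = extract_features(second)
    sustained = (feat.frequency > 0
                 and feat.peak_to_peak >= amp_floor
                 and feat.peak_to_peak >= decay_ratio * amp1)
    if not sustained:
        return WaveformFeatures(0.0, feat.peak_to_peak, feat.max_rise_rate,
                                feat.max_fall_rate, np.array([]))
    return feat


def dimensionless_waveform(trace: Trace, n_points: int = 512) -> np.ndarray:
    """Average cycle normalized to unit period and unit amplitude.

    Spike-to-spike cycles are resampled onto a fixed phase grid on [0, 1)
    with the spike peak at phase 0, averaged, then shifted/scaled so the
    voltage spans exactly [0, 1].  Waveforms differing only by gain and
    time scale map to the same dimensionless cycle.
    """
    spikes = detect_spikes(trace)
    if spikes.size < 3:
        raise ValueError("need >= 3 spikes to build a dimensionless waveform")
    phase_grid = np.arange(n_points) / n_points
    t = trace.t
    cycles = []
    for a, b in zip(spikes[:-1], spikes[1:]):
        ts = a + phase_grid * (b - a)
        cycles.append(np.interp(ts, t, trace.v))
    mean_cycle = np.mean(cycles, axis=0)
    lo, hi = mean_cycle.min(), mean_cycle.max()
    if hi - lo < 1e-12:
        raise ValueError("cycle has no amplitude; cannot normalize")
    return (mean_cycle - lo) / (hi - lo)


def _power_spectrum(trace: Trace) -> tuple[np.ndarray, np.ndarray]:
    """One-sided power spectrum with mean removal, rectangular window."""
    v = trace.v - trace.v.mean()
    spec = np.fft.rfft(v)
    power = np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(v.size, d=trace.dt * 1e-3)  # dt ms -> s
    return freqs, power


def dominant_frequency(recording: Trace) -> tuple[float, float]:
    """Highest-power (dominant) frequency of a recording, in Hz.

    Returns ``(frequency, power)`` over (0, Nyquist), excluding the DC bin.
    Requires at least one second of data for 1 Hz spectral resolution.
    """
    if recording.duration < 999.0:  # ms; ~1 s
        raise ValueError("recording must be at least 1 s long")
    freqs, power = _power_spectrum(recording)
    k = 1 + int(np.argmax(power[1:]))
    return float(freqs[k]), float(power[k])


def _power_near(freqs: np.ndarray, power: np.ndarray, f: float) -> float:
    return float(power[int(np.argmin(np.abs(freqs - f)))])


def cessation_test(recording: Trace) -> str:
    """Classify a 1-s recording as ``firing``, ``ceased`` or ``rejected_noisy``.

    Firing has ceased when the power at the dominant frequency is less than
    1.5 times the power at 60 Hz (SNR < 1.5).  A ceased verdict whose
    dominant frequency lies within 5 Hz of a power-line harmonic (any
    multiple of 60 Hz up to Nyquist) marks an overly noisy recording to be
    excluded from analysis: ``rejected_noisy``.
    """
    freqs, power = _power_spectrum(recording)
    k = 1 + int(np.argmax(power[1:]))
    f_dom, p_dom = float(freqs[k]), float(power[k])
    p_line = _power_near(freqs, power, 60.0)
    snr = p_dom / p_line if p_line > 0 else np.inf
    if snr >= 1.5:
        return "firing"
    nyquist = freqs[-1]
    harmonics = np.arange(60.0, nyquist + 1e-9, 60.0)
    if harmonics.size and np.min(np.abs(harmonics - f_dom)) <= 5.0:
        return "rejected_noisy"
    return "ceased"


# -- text I/O ------------------------------------------------------------

def write_trace(trace: Trace, path: str | Path) -> None:
    """Write a trace as two-column delimited text (time_ms, v_mV)."""
    arr = np.column_stack([trace.t, trace.v])
    np.savetxt(path, arr, fmt="%.9g", delimiter=",", header="time_ms,v_mV", comments="")


def read_trace(path: str | Path) -> Trace:
    """Read a trace written by :func:`write_trace` (uniform grid required)."""
    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    t, v = arr[:, 0], arr[:, 1]
    dts = np.diff(t)
    if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-12):
        raise ValueError("trace is not uniformly sampled")
    return Trace(t0=float(t[0]), dt=float(dts[0]), v=v)
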