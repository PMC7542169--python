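"""Synthetic inputs: reference parameters, target waveforms, recordings.

Everything the toolkit consumes can be generated here, deterministically
from a seed: the committed reference ("canonical") parameter set, clean or
noisy two-cycle target waveforms for fitting, and 1-second
extracellular-style recordings sampled at 100 kHz with additive Gaussian
noise and 60 Hz power-line contamination, as used by the dominant-frequency
and firing-cessation analyses.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass

import numpy as np

from .model import ModelParams
from .simulate import Trace, detect_spikes, extract_features, integrate

__all__ = [
    "RecordingSpec",
    "canonical_params",
    "make_target_waveform",
    "make_recording",
]


def canonical_params() -> ModelParams:
    """The repository's reference pacemaker parameter set.

    A committed 44-parameter fixture, tuned so the model reproduces the
    hallmark pacemaker dynamics: a ~380 Hz, ~25 mV peak-to-peak oscillation
    at the control sodium reversal potential (E_Na ~ 58 mV, i.e. 148 mM
    bath sodium over 15 mM intracellular), a small calcium conductance
    whose complete block leaves the oscillation intact, and a supercritical
    Hopf bifurcation as E_Na is lowered, with oscillation ceasing abruptly
    at a nonzero minimum frequency.  Produced by scripts/make_canonical.py.
    """
    text = importlib.resources.files("pacesim.data").joinpath(
        "canonical_params.json").read_text()
    return ModelParams.from_dict(json.loads(text))


@dataclass
class RecordingSpec:
    """Recipe for a synthetic extracellular-style recording.

    Amplitudes are in arbitrary units; ``fs`` must exceed twice the spike
    frequency.
    """

    duration: float = 1.0        # s
    fs: float = 100_000.0        # Hz
    spike_frequency: float = 400.0  # Hz
    spike_amplitude: float = 1.0
    noise_sd: float = 0.05
    line60_amplitude: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not self.fs > 2 * self.spike_frequency:
            raise ValueError("fs must exceed twice the spike frequency")


def make_target_waveform(
    params: ModelParams,
    n_cycles: int = 2,
    dt: float = 0.005,
    noise_sd: float = 0.0,
    seed: int = 0,
    transient: float = 50.0,
) -> Trace:
    """Post-transient segment containing exactly ``n_cycles`` spike-to-spike
    cycles of the model's oscillation, with optional additive Gaussian noise.

    Mirrors a standard two-action-potential fitting target; deterministic
    given ``seed``.
    """
    if n_cycles < 2:
        raise ValueError("need at least 2 cycles")
    # enough time for the transient plus the requested cycles at >= 200 Hz
    feat_probe = extract_features(
        integrate(params, transient + 60.0, dt=dt).window(transient))
    if feat_probe.frequency <= 0:
        raise RuntimeError("model does not oscillate; cannot build target")
    period_ms = 1000.0 / feat_probe.frequency
    duration = transient + (n_cycles + 3) * period_ms
    tr = integrate(params, duration, dt=dt)
    post = tr.window(transient)
    spikes = detect_spikes(post)
    if spikes.size < n_cycles + 2:
        raise RuntimeError("too few spikes for requested cycle count")
    # exactly n_cycles periods, offset by half a period so every spike peak
    # is interior to the segment and detectable
    isi = (spikes[n_cycles + 1] - spikes[1]) / n_cycles
    seg = post.window(spikes[1] - 0.5 * isi, spikes[n_cycles + 1] - 0.5 * isi)
    v = seg.v.copy()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sd, size=v.size)
    return Trace(t0=0.0, dt=seg.dt, v=v)


def _spike_pulse(t_ms: np.ndarray, rise: float = 0.2, decay: float = 0.8) -> np.ndarray:
    """Difference-of-exponentials pulse, peak-normalized to 1."""
    p = np.exp(-t_ms / decay) - np.exp(-t_ms / rise)
    return p / p.max()


def make_recording(spec: RecordingSpec) -> Trace:
    """Synthetic 1-s style recording: periodic sharp spikes + noise + 60 Hz.

    A difference-of-exponentials pulse train at ``spike_frequency`` plus
    Gaussian noise and a 60 Hz sinusoid; deterministic given ``spec.seed``.
    Returned as a Trace with times in ms.
    """
    n = int(round(spec.duration * spec.fs))
    dt_ms = 1000.0 / spec.fs
    t_s = np.arange(n) / spec.fs
    v = np.zeros(n)
    if spec.spike_amplitude != 0:
        period_ms = 1000.0 / spec.spike_frequency
        pulse_t = np.arange(0.0, 5.0, dt_ms)  # 5 ms support
        pulse = spec.spike_amplitude * _spike_pulse(pulse_t)
        k = 0
        while True:
            start = int(round(k * period_ms / dt_ms))
            if start >= n:
                break
            stop = min(n, start + pulse.size)
            v[start:stop] += pulse[: stop - start]
            k += 1
    if spec.line60_amplitude != 0:
        v = v + spec.line60_amplitude * np.sin(2 * np.pi * 60.0 * t_s)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        v = v + rng.normal(0.0, spec.noise_sd, size=n)
    return Trace(t0=0.0, dt=dt_ms, v=v)
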