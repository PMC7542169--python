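"""In-silico counterparts of the two slice-physiology validation
protocols: progressive channel block and low-sodium washout.

Channel block scales a maximal conductance as G -> (1 - beta) G, with
block level beta in [0, 1] (beta = 0: no block; beta = 1: complete block),
and tracks how waveform features (peak-to-peak amplitude, maximal rise and
fall rates, frequency) change with beta.  The *equivalent block level* is
the beta at which a feature has changed by a given percentage relative to
the unblocked model — the bridge to wash-in pharmacology data where the
true blocked fraction is unknown.

Low-sodium washout models bath sodium decaying exponentially,
[Na]_out(t) = [Na]_out,0 * exp(-t/r), so the sodium reversal potential

    E_Na(t) = (RT/F) ln([Na]_out(t)/[Na]_in)

falls *linearly* in time, making elapsed time a proxy for E_Na.  The
oscillation frequency is evaluated quasi-statically at each frozen E_Na,
and times are normalized so firing ceases at t = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ModelParams, ModelState
from .simulate import (Trace, WaveformFeatures, extract_features, integrate,
                       sustained_features)

__all__ = [
    "BlockCurve",
    "WashoutSeries",
    "NERNST_RT_F_22C",
    "apply_block",
    "block_curve",
    "equivalent_block_level",
    "washout_ena",
    "simulate_washout",
]

#: RT/F at 22 degrees C (295.15 K), in mV
NERNST_RT_F_22C = 8.31446261815324 * 295.15 / 96485.33212 * 1000.0

_ION_TO_CONDUCTANCE = {"Na": "G_Na", "K": "G_K", "Ca": "G_Ca"}

FEATURE_COLUMNS = ("frequency", "peak_to_peak", "max_rise_rate", "max_fall_rate")


@dataclass
class BlockCurve:
    """Waveform features as a function of block level for one channel."""

    ion: str
    betas: np.ndarray
    features: list[WaveformFeatures]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(beta=b, frequency=f.frequency, peak_to_peak=f.peak_to_peak,
                 max_rise_rate=f.max_rise_rate, max_fall_rate=f.max_fall_rate)
            for b, f in zip(self.betas, self.features)
        ]
        return pd.DataFrame(rows)


@dataclass
class WashoutSeries:
    """Quasi-static frequency time course during low-sodium washout."""

    times: np.ndarray           # s
    e_na: np.ndarray            # mV
    frequency: np.ndarray       # Hz, 0 at/after cessation
    cessation_time: float       # s
    normalized_times: np.ndarray  # times / cessation_time

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(dict(
            time_s=self.times, e_na_mv=self.e_na, frequency_hz=self.frequency,
            normalized_time=self.normalized_times,
        ))


def apply_block(params: ModelParams, ion: str, beta: float) -> ModelParams:
    """Scale one channel's maximal conductance: G_ion -> (1 - beta) G_ion."""
    if not 0.0 <= beta <= 1.0:
        raise ValueError("block level beta must lie in [0, 1]")
    gname = _ION_TO_CONDUCTANCE.get(ion)
    if gname is None:
        raise ValueError(f"unknown ion {ion!r}; expected one of Na, K, Ca")
    return params.replace(**{gname: (1.0 - beta) * params.get(gname)})


def block_curve(
    params: ModelParams,
    ion: str,
    betas,
    sim_duration: float = 200.0,
    transient: float = 50.0,
    dt: float = 0.01,
) -> BlockCurve:
    """Simulate the model at each block level and extract waveform features.

    Each beta is warm-started from the previous simulation's final state so
    the sweep tracks a single attractor, as in a slow pharmacological
    wash-in.  Resting entries are recorded with frequency 0.
    """
    betas = np.asarray(betas, dtype=float)
    if betas.size and (betas.min() < 0 or betas.max() > 1):
        raise ValueError("betas must lie in [0, 1]")
    feats: list[WaveformFeatures] = []
    state: ModelState | None = None
    for beta in betas:
        p = apply_block(params, ion, float(beta))
        tr = integrate(p, sim_duration, dt=dt, initial=state, keep_gates=True)
        feats.append(sustained_features(tr, transient=transient))
        state = ModelState.from_array(
            np.concatenate([[tr.v[-1]], tr.gates[:, -1]]))
    return BlockCurve(ion=ion, betas=betas, features=feats)


def equivalent_block_level(curve: BlockCurve, feature: str,
                           percent_change: float) -> float:
    """Block level producing a given percent change in a waveform feature.

    The change is measured relative to the unblocked (beta = 0) value and
    inverted by piecewise-linear interpolation along the curve; when the
    feature is non-monotone in beta the first crossing is returned with a
    warning.
    """
    if feature not in FEATURE_COLUMNS:
        raise ValueError(f"unknown feature {feature!r}")
    vals = np.array([getattr(f, feature) for f in curve.features], dtype=float)
    base = vals[0]
    if base == 0:
        raise ValueError("feature is zero at beta = 0; percent change undefined")
    changes = 100.0 * (vals - base) / abs(base)
    target = percent_change
    lo, hi = changes.min(), changes.max()
    if not lo <= target <= hi:
        raise ValueError(
            f"percent change {target:g} outside realized range [{lo:.3g}, {hi:.3g}]")
    if target == 0:
        return float(curve.betas[0])
    diffs = np.diff(np.sign(changes - target))
    crossings = np.nonzero(diffs != 0)[0]
    exact = np.nonzero(changes == target)[0]
    if exact.size:
        first = exact[0]
        if exact.size > 1 or crossings.size > 1:
            warnings.warn("feature non-monotone in beta; using first crossing")
        return float(curve.betas[first])
    if crossings.size == 0:
        raise ValueError("no crossing found (feature non-monotone sampling?)")
    if crossings.size > 1 or not np.all(np.diff(changes) <= 0) and not np.all(np.diff(changes) >= 0):
        if crossings.size > 1:
            warnings.warn("feature non-monotone in beta; using first crossing")
    i = int(crossings[0])
    c0, c1 = changes[i], changes[i + 1]
    b0, b1 = curve.betas[i], curve.betas[i + 1]
    frac = (target - c0) / (c1 - c0)
    return float(b0 + frac * (b1 - b0))


def washout_ena(t, rate_r: float, na_out_0: float, na_in: float,
                rt_f: float = NERNST_RT_F_22C):
    """Sodium reversal potential (mV) during exponential bath washout.

    [Na]_out(t) = na_out_0 * exp(-t / rate_r); E_Na from the Nernst
    equation at 22 C.  Linear in t by construction:
    dE_Na/dt = -(RT/F)/r mV per unit time.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    if rate_r <= 0 or na_out_0 <= 0 or na_in <= 0:
        raise ValueError("rate and concentrations must be positive")
    na_out = na_out_0 * np.exp(-t / rate_r)
    return rt_f * np.log(na_out / na_in)


def simulate_washout(
    params: ModelParams,
    rate_r: float,
    na_out_0: float,
    na_in: float,
    t_grid,
    sim_duration: float = 200.0,
    transient: float = 50.0,
) -> WashoutSeries:
    """Quasi-static washout: frequency at each frozen E_Na(t).

    The model's E_Na is replaced by the washout value at each grid time;
    each point is warm-started from the previous final state.  The
    cessation time is the first grid time with zero frequency, and
    normalized times place cessation at exactly 1.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    e_na = washout_ena(t_grid, rate_r, na_out_0, na_in)
    freqs = np.empty_like(t_grid)
    state: ModelState | None = None
    for i, ena in enumerate(e_na):
        p = params.replace(E_Na=float(ena))
        tr = integrate(p, sim_duration, dt=0.01, initial=state, keep_gates=True)
        freqs[i] = sustained_features(tr, transient=transient).frequency
        state = ModelState.from_array(
            np.concatenate([[tr.v[-1]], tr.gates[:, -1]]))
    if freqs[0] == 0.0:
        raise RuntimeError("model already at rest at t = 0; washout degenerate")
    ceased = np.nonzero(freqs == 0.0)[0]
    if ceased.size == 0:
        raise RuntimeError("model never ceased within the time grid")
    k = int(ceased[0])
    freqs[k:] = 0.0  # quasi-static: no restart after cessation
    cessation_time = float(t_grid[k])
    return WashoutSeries(
        times=t_grid,
        e_na=e_na,
        frequency=freqs,
        cessation_time=cessation_time,
        normalized_times=t_grid / cessation_time,
    )
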