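"""Bifurcation analysis: fixed points, stability, Hopf detection and
classification, and orbit/frequency diagrams over any scalar model
parameter.

The central question for the pacemaker is how oscillation stops when the
sodium reversal potential falls (low-sodium washout) or a conductance is
blocked.  The machinery here locates fixed points of the 7-dimensional
vector field, computes their linear stability from the analytic Jacobian,
establishes limit-cycle existence by direct simulation (shooting from a
perturbed fixed point with warm-started continuation), refines the
stability crossing by bisection, and decides super- vs sub-criticality
empirically from (i) a quasi-static hysteresis sweep and (ii) the
square-root amplitude scaling characteristic of a supercritical Hopf.

A light ``System`` protocol keeps the sweep/detect/classify machinery
generic, so textbook normal forms serve as independent checks of the
classification logic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq
from scipy.stats import linregress

from .model import ModelParams, ModelState, jacobian, steady_gates, vector_field
from .simulate import (IntegrationError, Trace, extract_features, integrate,
                       sustained_features)

__all__ = [
    "BranchPoint",
    "HopfPoint",
    "PacemakerSystem",
    "HopfNormalForm",
    "find_fixed_point",
    "sweep_parameter",
    "detect_hopf",
    "classify_hopf",
    "frequency_curve",
    "branch_to_frame",
]

#: |Re lambda| tolerance (per ms) for calling an eigenvalue pair marginal
HOPF_EIG_TOL = 1e-6


class RootFailure(RuntimeError):
    """No fixed point found in the search interval."""


@dataclass
class BranchPoint:
    """One point of a one-parameter branch.

    ``cycle_min``/``cycle_max`` are the limit-cycle voltage extrema (mV)
    when an oscillation exists, else None; ``frequency`` is 0 at rest.
    """

    param_value: float
    fixed_point: object
    eigenvalues: np.ndarray
    stable: bool
    cycle_min: float | None = None
    cycle_max: float | None = None
    frequency: float = 0.0
    error: str | None = None


@dataclass
class HopfPoint:
    """A located stability crossing with oscillatory eigenvalues."""

    param_value: float
    onset_frequency: float  # Hz, |Im lambda| / 2 pi at the crossing
    criticality: str = "undetermined"  # supercritical | subcritical | undetermined


# ----------------------------------------------------------------------
# System protocol: the pacemaker model and toy normal forms share the
# sweep / Hopf-detection / classification machinery.
# ----------------------------------------------------------------------

class PacemakerSystem:
    """Adapter exposing the pacemaker model as a parameterized system.

    ``name`` is the swept scalar parameter (e.g. ``"E_Na"``, ``"G_Na"``,
    or a flattened gate key like ``"n_tau_base"``).
    """

    def __init__(self, params: ModelParams, name: str):
        self.base = params
        self.name = name

    def at(self, value: float) -> ModelParams:
        return self.base.replace(**{self.name: float(value)})

    def equilibrium(self, value: float, v_guess: float) -> np.ndarray:
        st = find_fixed_point(self.at(value), v_guess)
        return st.to_array()

    def eigenvalues(self, value: float, y: np.ndarray) -> np.ndarray:
        return np.linalg.eigvals(jacobian(y, self.at(value)))

    def simulate(self, value: float, y0: np.ndarray, duration: float,
                 dt: float = 0.01) -> Trace:
        return integrate(self.at(value), duration, dt=dt,
                         initial=ModelState.from_array(y0), keep_gates=True)

    #: smallest peak-to-peak (mV) counted as a sustained oscillation
    amp_floor = 0.5

    def amplitude_and_frequency(self, trace: Trace,
                                transient: float = 50.0) -> tuple[float, float, float, float]:
        """(cycle_min, cycle_max, amplitude, frequency Hz) post-transient.

        Decaying near-Hopf ringing is screened out by
        :func:`pacesim.simulate.sustained_features`.
        """
        feat = sustained_features(trace, transient=transient,
                                  amp_floor=self.amp_floor)
        if feat.frequency <= 0:
            ymin = ymax = float(trace.v[-1])
            return ymin, ymax, 0.0, 0.0
        w = trace.window(trace.t0 + transient)
        mid = w.t0 + 0.5 * w.duration
        second = w.window(mid)
        return (float(second.v.min()), float(second.v.max()),
                feat.peak_to_peak, feat.frequency)


class HopfNormalForm:
    """Planar Hopf normal form in Cartesian coordinates.

    dr/dt = mu r + a3 r^3 + a5 r^5, dtheta/dt = omega.  With a3 = -1,
    a5 = 0 the Hopf at mu = 0 is supercritical; with a3 = +1, a5 = -1 it
    is subcritical with a saddle-node of cycles at mu = -1/4 (closed-form
    hysteresis window of width 1/4).
    """

    def __init__(self, a3: float = -1.0, a5: float = 0.0, omega: float = 1.0):
        self.a3, self.a5, self.omega = a3, a5, omega

    def _rhs(self, y: np.ndarray, mu: float) -> np.ndarray:
        x, z = y
        r2 = x * x + z * z
        g = mu + self.a3 * r2 + self.a5 * r2 * r2
        return np.array([g * x - self.omega * z, g * z + self.omega * x])

    def equilibrium(self, value: float, v_guess: float) -> np.ndarray:
        return np.zeros(2)

    def eigenvalues(self, value: float, y: np.ndarray) -> np.ndarray:
        return np.array([value + 1j * self.omega, value - 1j * self.omega])

    def simulate(self, value: float, y0: np.ndarray, duration: float,
                 dt: float = 0.05) -> Trace:
        n = int(np.ceil(duration / dt)) + 1
        t_eval = dt * np.arange(n)
        sol = solve_ivp(lambda t, y: self._rhs(y, value), (0, t_eval[-1]), y0,
                        t_eval=t_eval, rtol=1e-7, atol=1e-10)
        # keep the second state as a "gate" row so warm-started sweeps
        # reseed from the full planar state (radius and phase), not just x
        return Trace(t0=0.0, dt=dt, v=sol.y[0], gates=sol.y[1:])

    amp_floor = 1e-3

    def amplitude_and_frequency(self, trace: Trace,
                                transient: float = 50.0) -> tuple[float, float, float, float]:
        w = trace.window(trace.t0 + transient)
        mid = w.t0 + 0.5 * w.duration
        first, second = w.window(w.t0, mid), w.window(mid)
        amp1 = float(first.v.max() - first.v.min())
        amp = float(second.v.max() - second.v.min())
        if amp < self.amp_floor or amp < 0.7 * amp1:
            return float(w.v[-1]), float(w.v[-1]), 0.0, 0.0
        freq = 1000.0 * self.omega / (2 * np.pi)  # Trace times are "ms"
        return float(second.v.min()), float(second.v.max()), amp, freq


# ----------------------------------------------------------------------
# Fixed points
# ----------------------------------------------------------------------

def find_fixed_point(params: ModelParams, v_guess: float,
                     search_halfwidth: float = 60.0) -> ModelState:
    """Fixed point of the pacemaker model near ``v_guess``.

    The 7-D equilibrium problem reduces exactly to a scalar root of the
    current-balance equation in v with every gate at steady state.  The
    root nearest ``v_guess`` inside ``v_guess +/- search_halfwidth`` is
    bracketed on a fine scan and polished with Brent's method.
    """
    def balance(v: float) -> float:
        return float(vector_field(steady_gates(v, params), params)[0])

    lo, hi = v_guess - search_halfwidth, v_guess + search_halfwidth
    vs = np.linspace(lo, hi, 1201)
    fs = np.array([balance(v) for v in vs])
    roots = []
    for a, b, fa, fb in zip(vs[:-1], vs[1:], fs[:-1], fs[1:]):
        if fa == 0.0:
            roots.append(float(a))
        elif fa * fb < 0:
            roots.append(float(brentq(balance, a, b, xtol=1e-13)))
    if not roots:
        raise RootFailure(
            f"no fixed point in [{lo:.1f}, {hi:.1f}] mV")
    v_star = min(roots, key=lambda r: abs(r - v_guess))
    return steady_gates(v_star, params)


# ----------------------------------------------------------------------
# Branch sweep
# ----------------------------------------------------------------------

def sweep_parameter(
    params: ModelParams,
    name: str,
    values: Sequence[float],
    v_guess: float = -60.0,
    sim_duration: float = 200.0,
    transient: float = 50.0,
    perturb_mv: float = 1.0,
    system: object | None = None,
) -> list[BranchPoint]:
    """Compute a one-parameter branch of fixed points and limit cycles.

    For each value (in the given order): locate the fixed point warm-started
    from the previous one, compute eigenvalues, and establish limit-cycle
    existence by simulating from the previous cycle state (or from the
    perturbed fixed point); post-transient voltage extrema and frequency are
    recorded where an oscillation is found.  Integration failures are
    recorded per point and the sweep continues.
    """
    sys_ = system if system is not None else PacemakerSystem(params, name)
    branch: list[BranchPoint] = []
    guess = v_guess
    warm_state: np.ndarray | None = None
    for val in values:
        try:
            y_star = sys_.equilibrium(val, guess)
            eig = sys_.eigenvalues(val, y_star)
            stable = bool(np.all(eig.real < 0))
            guess = float(y_star[0])
            y0 = warm_state
            if y0 is None:
                y0 = y_star.copy()
                y0[0] += perturb_mv
            tr = sys_.simulate(val, y0, sim_duration)
            cmin, cmax, amp, freq = sys_.amplitude_and_frequency(tr, transient)
            if freq > 0:
                if tr.gates is not None:
                    warm_state = np.concatenate([[tr.v[-1]], tr.gates[:, -1]])
                branch.append(BranchPoint(float(val), y_star, eig, stable,
                                          cmin, cmax, freq))
            else:
                warm_state = None
                branch.append(BranchPoint(float(val), y_star, eig, stable,
                                          None, None, 0.0))
        except (IntegrationError, RootFailure) as exc:
            branch.append(BranchPoint(float(val), None, np.array([]), False,
                                      error=str(exc)))
    return branch


# ----------------------------------------------------------------------
# Hopf detection and classification
# ----------------------------------------------------------------------

def detect_hopf(branch: list[BranchPoint],
                system: object | None = None,
                rel_tol: float = 1e-6) -> HopfPoint | None:
    """Locate a stability crossing along a branch by bisection.

    Scans consecutive branch points for a sign change of the maximal
    eigenvalue real part; the crossing is refined to relative tolerance
    ``rel_tol`` in the parameter by bisection on that sign.  Returns None
    when every fixed point on the branch has the same stability.
    """
    ok = [bp for bp in branch if bp.error is None and bp.eigenvalues.size]
    if len(ok) < 2:
        return None
    pair = None
    for a, b in zip(ok[:-1], ok[1:]):
        if a.stable != b.stable:
            pair = (a, b)
            break
    if pair is None:
        return None
    a, b = pair
    if system is None:
        raise ValueError("detect_hopf needs the swept system to refine the crossing")

    def max_re(val: float, guess: float) -> tuple[float, float, np.ndarray]:
        y = system.equilibrium(val, guess)
        eig = system.eigenvalues(val, y)
        k = int(np.argmax(eig.real))
        return float(eig.real[k]), float(y[0]), eig

    lo, hi = a.param_value, b.param_value
    guess = float(a.fixed_point[0]) if isinstance(a.fixed_point, np.ndarray) else float(np.atleast_1d(np.asarray(a.fixed_point))[0])
    f_lo, guess_lo, _ = max_re(lo, guess)
    f_hi, guess_hi, _ = max_re(hi, guess)
    scale = max(abs(lo), abs(hi), 1.0)
    while abs(hi - lo) > rel_tol * scale:
        mid = 0.5 * (lo + hi)
        f_mid, g_mid, _ = max_re(mid, 0.5 * (guess_lo + guess_hi))
        if (f_mid > 0) == (f_lo > 0):
            lo, f_lo, guess_lo = mid, f_mid, g_mid
        else:
            hi, f_hi, guess_hi = mid, f_mid, g_mid
    val_c = 0.5 * (lo + hi)
    _, _, eig = max_re(val_c, 0.5 * (guess_lo + guess_hi))
    k = int(np.argmax(eig.real))
    omega = abs(eig.imag[k])
    if omega == 0:
        return None
    # Trace time unit is ms; omega is rad/ms -> Hz
    onset_hz = omega / (2 * np.pi) * 1000.0
    return HopfPoint(param_value=float(val_c), onset_frequency=float(onset_hz))


def _quasi_static_sweep(system, values: np.ndarray, y0: np.ndarray,
                        settle: float, transient: float,
                        kick: float = 0.0) -> np.ndarray:
    """Amplitude at each value, seeding each step with the previous state.

    ``kick`` adds a small perturbation to the first state variable at every
    step (a stand-in for biological noise); without it a quasi-static sweep
    can track the unstable fixed point past a supercritical onset for many
    steps, mimicking hysteresis that is not there.
    """
    amps = np.empty(values.size)
    y = y0.copy()
    for i, val in enumerate(values):
        y[0] += kick
        tr = system.simulate(val, y, settle + transient)
        _, _, amp, _ = system.amplitude_and_frequency(tr, transient)
        amps[i] = amp
        if tr.gates is not None:
            y = np.concatenate([[tr.v[-1]], tr.gates[:, -1]])
        else:
            y = y.copy()
            y[0] = tr.v[-1]
    return amps


def classify_hopf(
    system,
    hopf: HopfPoint,
    span: float | None = None,
    n_steps: int = 40,
    settle: float = 100.0,
    transient: float = 50.0,
    amp_threshold: float = 0.5,
    scaling_window: float | None = None,
    r2_min: float = 0.99,
    kick: float | None = None,
) -> str:
    """Empirical criticality of a detected Hopf point.

    Two independent tests must agree, else ``undetermined``:

    1. *Hysteresis*: quasi-static forward and backward sweeps across the
       bifurcation (each step seeded with the previous final state).  A
       supercritical Hopf switches between rest and oscillation at the
       same parameter value in both directions; a subcritical one shows a
       bistable window.
    2. *Amplitude scaling*: on the oscillating side near onset the squared
       cycle amplitude grows linearly in the parameter distance past the
       bifurcation (R^2 > ``r2_min``) for a supercritical Hopf; for a
       subcritical Hopf the amplitude is finite at onset.
    """
    pc = hopf.param_value
    if span is None:
        span = max(abs(pc) * 0.5, 2.0)
    if kick is None:
        kick = 0.4 * amp_threshold
    # which side oscillates? probe both sides
    def osc_amp(val):
        y = np.asarray(system.equilibrium(val, -60.0), dtype=float).copy()
        y[0] += 1.0
        tr = system.simulate(val, y, settle + transient)
        return system.amplitude_and_frequency(tr, transient)[2]

    amp_hi = osc_amp(pc + span)
    amp_lo = osc_amp(pc - span)
    sign = 1.0 if amp_hi > amp_lo else -1.0  # oscillating side direction
    osc_end, rest_end = pc + sign * span, pc - sign * span

    # hysteresis test
    values_fwd = np.linspace(rest_end, osc_end, n_steps)   # rest -> oscillation
    values_bwd = values_fwd[::-1]
    y_rest = np.asarray(system.equilibrium(rest_end, -60.0), dtype=float).copy()
    y_rest[0] += 0.5
    amps_fwd = _quasi_static_sweep(system, values_fwd, y_rest, settle, transient,
                                   kick=kick)
    y_osc = np.asarray(system.equilibrium(osc_end, -60.0), dtype=float).copy()
    y_osc[0] += 1.0
    # settle onto the cycle first
    tr0 = system.simulate(osc_end, y_osc, settle + transient)
    if tr0.gates is not None:
        y_osc = np.concatenate([[tr0.v[-1]], tr0.gates[:, -1]])
    else:
        y_osc = np.array([tr0.v[-1], 0.1]) if y_osc.size == 2 else y_osc
    amps_bwd = _quasi_static_sweep(system, values_bwd, y_osc, settle, transient,
                                   kick=kick)

    def onset_param(values, amps):
        on = amps > amp_threshold
        return values[np.argmax(on)] if on.any() else None

    on_fwd = onset_param(values_fwd, amps_fwd)          # first oscillating going up
    off_bwd = onset_param(values_bwd[::-1], amps_bwd[::-1])  # last oscillating going down
    step = abs(values_fwd[1] - values_fwd[0])
    if on_fwd is None or off_bwd is None:
        hysteresis_verdict = "undetermined"
    elif abs(on_fwd - off_bwd) <= 1.5 * step:
        hysteresis_verdict = "supercritical"
    else:
        hysteresis_verdict = "subcritical"

    # amplitude-scaling test near onset, on the oscillating side
    if scaling_window is None:
        scaling_window = 0.15 * span
    dists = np.linspace(0.15, 1.0, 8) * scaling_window
    amps = []
    y = np.asarray(system.equilibrium(pc + sign * dists[0], -60.0), dtype=float).copy()
    y[0] += 0.5
    for d in dists:
        tr = system.simulate(pc + sign * d, y, 2 * settle + transient)
        _, _, amp, _ = system.amplitude_and_frequency(tr, transient)
        amps.append(amp)
        if tr.gates is not None:
            y = np.concatenate([[tr.v[-1]], tr.gates[:, -1]])
    amps = np.asarray(amps)
    if np.any(amps <= 0):
        scaling_verdict = "subcritical"  # finite/absent amplitude jump at onset
    else:
        fit = linregress(dists, amps ** 2)
        r2 = fit.rvalue ** 2
        # supercritical: amp^2 linear through ~0 at onset
        intercept_small = abs(fit.intercept) < 0.5 * np.max(amps ** 2)
        scaling_verdict = ("supercritical"
                           if (r2 > r2_min and fit.slope > 0 and intercept_small)
                           else "subcritical")

    if hysteresis_verdict == scaling_verdict:
        return hysteresis_verdict
    return "undetermined"


def frequency_curve(branch: list[BranchPoint]) -> pd.DataFrame:
    """(param_value, frequency) series from a computed branch."""
    rows = [(bp.param_value, bp.frequency) for bp in branch if bp.error is None]
    return pd.DataFrame(rows, columns=["param_value", "frequency"])


def branch_to_frame(branch: list[BranchPoint]) -> pd.DataFrame:
    """Tabulate a branch for delimited-text export."""
    rows = []
    for bp in branch:
        if bp.error is not None:
            rows.append(dict(param_value=bp.param_value, v_fixed=np.nan,
                             max_Re_eig=np.nan, stable=False,
                             cycle_min=np.nan, cycle_max=np.nan,
                             frequency=np.nan, error=bp.error))
            continue
        v_fixed = float(np.asarray(bp.fixed_point)[0])
        rows.append(dict(
            param_value=bp.param_value,
            v_fixed=v_fixed,
            max_Re_eig=float(np.max(bp.eigenvalues.real)),
            stable=bp.stable,
            cycle_min=np.nan if bp.cycle_min is None else bp.cycle_min,
            cycle_max=np.nan if bp.cycle_max is None else bp.cycle_max,
            frequency=bp.frequency,
            error="",
        ))
    return pd.DataFrame(rows)
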