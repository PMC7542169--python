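"""Conductance-based pacemaker-cell model.

A single-compartment Hodgkin-Huxley-type model of a pacemaker neuron from
the medullary pacemaker nucleus of the weakly electric fish *Apteronotus*.
Four currents drive the membrane potential ``v`` (mV):

.. math::

    dv/dt = -(I_{Leak} + I_{Ca} + I_{Na} + I_K)

with

.. math::

    I_{Leak} = G_{Leak}(v - E_{Leak}), \\qquad
    I_{Ca}   = G_{Ca} b^2 g^2 (v - E_{Ca}),

    I_{Na}   = G_{Na} m h (v - E_{Na}), \\qquad
    I_K      = G_K n^2 q^2 (v - E_K).

Membrane capacitance is normalized to 1 (conductances are per-capacitance,
so ``dv/dt`` is in mV/ms directly and conductance units are ms^-1,
equivalent to mS/cm^2 at C = 1 uF/cm^2).

``b``, ``m``, ``n`` are calcium, sodium and potassium activation variables;
``g``, ``h``, ``q`` the respective inactivation variables.  Each gate ``x``
relaxes toward a Boltzmann steady state with a bell-shaped voltage-dependent
time constant:

.. math::

    dx/dt = (x_\\infty(v) - x) / \\tau_x(v)

    x_\\infty(v) = 1 / (1 + e^{(v_{1/2} - v)/k}), \\qquad
    \\tau_x(v) = \\tau_{base} + \\tau_{amp}
                 e^{-((v - \\tau_{vmid})/\\tau_{width})^2}.

The full parameter vector has 44 scalars: four conductances, four reversal
potentials, and six kinetic constants for each of the six gates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterator

import numpy as np

__all__ = [
    "GateSpec",
    "ModelParams",
    "ModelState",
    "GATE_NAMES",
    "gate_steady_state",
    "gate_time_constant",
    "ionic_currents",
    "steady_gates",
    "vector_field",
    "jacobian",
    "load_params",
    "save_params",
]

GATE_NAMES = ("b", "g", "m", "h", "n", "q")

#: fields of a GateSpec, in serialization order
_GATE_FIELDS = ("half_voltage", "slope", "tau_base", "tau_amp", "tau_vmid", "tau_width")


class ParameterError(ValueError):
    """Raised when a parameter set violates its physical constraints."""


@dataclass(frozen=True)
class GateSpec:
    """Kinetics of one gating variable.

    Parameters
    ----------
    half_voltage : float
        Voltage (mV) at which the steady state equals 0.5.
    slope : float
        Boltzmann slope factor (mV).  Positive for activation gates
        (steady state increases with voltage), negative for inactivation.
    tau_base : float
        Voltage-independent floor of the time constant (ms); must be > 0.
    tau_amp : float
        Amplitude of the Gaussian bell added to ``tau_base`` (ms); >= 0.
    tau_vmid : float
        Center voltage of the bell (mV).
    tau_width : float
        Width of the bell (mV); must be > 0.
    """

    half_voltage: float
    slope: float
    tau_base: float
    tau_amp: float = 0.0
    tau_vmid: float = 0.0
    tau_width: float = 10.0

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ParameterError("gate slope must be nonzero")
        if not self.tau_base > 0:
            raise ParameterError("tau_base must be positive")
        if self.tau_amp < 0:
            raise ParameterError("tau_amp must be nonnegative")
        if not self.tau_width > 0:
            raise ParameterError("tau_width must be positive")


def gate_steady_state(v, gate: GateSpec):
    """Boltzmann steady state of a gate at voltage ``v`` (mV).

    Strictly in (0, 1) for finite ``v``; monotone in ``v`` with the sign
    of ``gate.slope``.
    """
    return 1.0 / (1.0 + np.exp((gate.half_voltage - v) / gate.slope))


def gate_time_constant(v, gate: GateSpec):
    """Bell-shaped voltage-dependent time constant (ms) of a gate.

    Equals ``tau_base + tau_amp`` at the bell center ``tau_vmid`` and
    decays to ``tau_base`` far from it; strictly positive everywhere.
    """
    u = (v - gate.tau_vmid) / gate.tau_width
    return gate.tau_base + gate.tau_amp * np.exp(-u * u)


@dataclass(frozen=True)
class ModelParams:
    """The 44 scalars of the pacemaker model.

    Conductances ``G_*`` are in ms^-1 (per unit capacitance), reversal
    potentials ``E_*`` in mV, and each of the six gates carries a
    :class:`GateSpec`.
    """

    G_Leak: float
    G_Ca: float
    G_Na: float
    G_K: float
    E_Leak: float
    E_Ca: float
    E_Na: float
    E_K: float
    b: GateSpec = field(default=None)  # type: ignore[assignment]
    g: GateSpec = field(default=None)  # type: ignore[assignment]
    m: GateSpec = field(default=None)  # type: ignore[assignment]
    h: GateSpec = field(default=None)  # type: ignore[assignment]
    n: GateSpec = field(default=None)  # type: ignore[assignment]
    q: GateSpec = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for name in ("G_Leak", "G_Ca", "G_Na", "G_K"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be nonnegative")
        if not self.E_Na > self.E_K:
            raise ParameterError("E_Na must exceed E_K")
        for gname in GATE_NAMES:
            if not isinstance(getattr(self, gname), GateSpec):
                raise ParameterError(f"gate '{gname}' must be a GateSpec")

    # -- flat key/value view (serialization and sweeps) ------------------

    def replace(self, **kwargs) -> "ModelParams":
        """Return a copy with scalar fields or gates replaced.

        Accepts top-level names (``E_Na``, ``m``, ...) and flattened gate
        keys (``m_half_voltage``, ``n_tau_base``, ...).
        """
        top = {f.name: getattr(self, f.name) for f in fields(self)}
        for key, value in kwargs.items():
            if key in top and key not in GATE_NAMES:
                top[key] = value
            elif key in GATE_NAMES:
                top[key] = value
            elif "_" in key and key.split("_", 1)[0] in GATE_NAMES:
                gname, fname = key.split("_", 1)
                if fname not in _GATE_FIELDS:
                    raise KeyError(key)
                gd = {f: getattr(top[gname], f) for f in _GATE_FIELDS}
                gd[fname] = value
                top[gname] = GateSpec(**gd)
            else:
                raise KeyError(key)
        return ModelParams(**top)

    def get(self, key: str) -> float:
        """Look up a scalar parameter by flat name (e.g. ``E_Na``, ``m_slope``)."""
        if key in ("G_Leak", "G_Ca", "G_Na", "G_K",
                   "E_Leak", "E_Ca", "E_Na", "E_K"):
            return getattr(self, key)
        gname, _, fname = key.partition("_")
        if gname in GATE_NAMES and fname in _GATE_FIELDS:
            return getattr(getattr(self, gname), fname)
        raise KeyError(key)

    def to_dict(self) -> dict[str, float]:
        """Flatten to the 44 named scalars."""
        out = {k: float(getattr(self, k))
               for k in ("G_Leak", "G_Ca", "G_Na", "G_K",
                         "E_Leak", "E_Ca", "E_Na", "E_K")}
        for gname in GATE_NAMES:
            spec = getattr(self, gname)
            for fname in _GATE_FIELDS:
                out[f"{gname}_{fname}"] = float(getattr(spec, fname))
        return out

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ModelParams":
        gates = {}
        for gname in GATE_NAMES:
            gates[gname] = GateSpec(**{f: d[f"{gname}_{f}"] for f in _GATE_FIELDS})
        return cls(
            G_Leak=d["G_Leak"], G_Ca=d["G_Ca"], G_Na=d["G_Na"], G_K=d["G_K"],
            E_Leak=d["E_Leak"], E_Ca=d["E_Ca"], E_Na=d["E_Na"], E_K=d["E_K"],
            **gates,
        )

    def gates(self) -> Iterator[tuple[str, GateSpec]]:
        for gname in GATE_NAMES:
            yield gname, getattr(self, gname)


@dataclass(frozen=True)
class ModelState:
    """One point in the 7-dimensional state space: voltage plus six gates."""

    v: float
    b: float
    g: float
    m: float
    h: float
    n: float
    q: float

    def __post_init__(self) -> None:
        for gname in GATE_NAMES:
            x = getattr(self, gname)
            if not 0.0 <= x <= 1.0:
                raise ParameterError(f"gating variable {gname}={x} outside [0, 1]")

    def to_array(self) -> np.ndarray:
        return np.array([self.v, self.b, self.g, self.m, self.h, self.n, self.q])

    @classmethod
    def from_array(cls, y: np.ndarray) -> "ModelState":
        # clip tiny integrator overshoot outside the invariant unit box
        ga = np.clip(y[1:], 0.0, 1.0)
        return cls(float(y[0]), *map(float, ga))


def steady_gates(v: float, params: ModelParams) -> ModelState:
    """State with every gate at its steady-state value for voltage ``v``."""
    vals = {g: float(gate_steady_state(v, spec)) for g, spec in params.gates()}
    return ModelState(v=float(v), **vals)


def ionic_currents(state: ModelState | np.ndarray, params: ModelParams):
    """The four membrane currents (mV/ms, per unit capacitance).

    Returns a dict with keys ``Leak``, ``Ca``, ``Na``, ``K``.  Accepts a
    :class:`ModelState` or a raw array ``[v, b, g, m, h, n, q]`` (which may
    be 2-D with states in columns for vectorized evaluation).
    """
    y = state.to_array() if isinstance(state, ModelState) else np.asarray(state)
    v, b, g, m, h, n, q = y[0], y[1], y[2], y[3], y[4], y[5], y[6]
    return {
        "Leak": params.G_Leak * (v - params.E_Leak),
        "Ca": params.G_Ca * b * b * g * g * (v - params.E_Ca),
        "Na": params.G_Na * m * h * (v - params.E_Na),
        "K": params.G_K * n * n * q * q * (v - params.E_K),
    }


def vector_field(state: ModelState | np.ndarray, params: ModelParams) -> np.ndarray:
    """Time derivative of the full state (units mV/ms and ms^-1).

    Vectorized: ``state`` may be a (7,) array or a (7, S) array of S states.
    """
    y = state.to_array() if isinstance(state, ModelState) else np.asarray(state)
    v = y[0]
    cur = ionic_currents(y, params)
    dv = -(cur["Leak"] + cur["Ca"] + cur["Na"] + cur["K"])
    out = np.empty_like(y, dtype=float)
    out[0] = dv
    for i, (gname, spec) in enumerate(params.gates(), start=1):
        xinf = gate_steady_state(v, spec)
        tau = gate_time_constant(v, spec)
        out[i] = (xinf - y[i]) / tau
    return out


def _dxinf_dv(v, spec: GateSpec):
    s = gate_steady_state(v, spec)
    return s * (1.0 - s) / spec.slope


def _dtau_dv(v, spec: GateSpec):
    u = (v - spec.tau_vmid) / spec.tau_width
    return spec.tau_amp * np.exp(-u * u) * (-2.0 * u / spec.tau_width)


def jacobian(state: ModelState | np.ndarray, params: ModelParams) -> np.ndarray:
    """Analytic 7x7 Jacobian of :func:`vector_field` at ``state``."""
    y = state.to_array() if isinstance(state, ModelState) else np.asarray(state, dtype=float)
    v, b, g, m, h, n, q = y
    p = params
    J = np.zeros((7, 7))

    # voltage row: dv/dt = -(sum of currents)
    J[0, 0] = -(p.G_Leak
                + p.G_Ca * b * b * g * g
                + p.G_Na * m * h
                + p.G_K * n * n * q * q)
    J[0, 1] = -2.0 * p.G_Ca * b * g * g * (v - p.E_Ca)
    J[0, 2] = -2.0 * p.G_Ca * b * b * g * (v - p.E_Ca)
    J[0, 3] = -p.G_Na * h * (v - p.E_Na)
    J[0, 4] = -p.G_Na * m * (v - p.E_Na)
    J[0, 5] = -2.0 * p.G_K * n * q * q * (v - p.E_K)
    J[0, 6] = -2.0 * p.G_K * n * n * q * (v - p.E_K)

    # gate rows: dx/dt = (xinf(v) - x)/tau(v)
    for i, (gname, spec) in enumerate(params.gates(), start=1):
        x = y[i]
        xinf = gate_steady_state(v, spec)
        tau = gate_time_constant(v, spec)
        J[i, i] = -1.0 / tau
        J[i, 0] = (_dxinf_dv(v, spec) / tau
                   - (xinf - x) * _dtau_dv(v, spec) / (tau * tau))
    return J


# -- serialization -------------------------------------------------------

def save_params(params: ModelParams, path: str | Path) -> None:
    """Write a parameter set as flat key -> value JSON."""
    Path(path).write_text(json.dumps(params.to_dict(), indent=2) + "\n")


def load_params(path: str | Path) -> ModelParams:
    """Read a parameter set written by :func:`save_params`."""
    return ModelParams.from_dict(json.loads(Path(path).read_text()))
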