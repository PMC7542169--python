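"""Orbit diagram over the sodium reversal potential and Hopf detection.

Lowering E_Na (the in-silico analogue of washing out bath sodium) slows
the oscillation and eventually destroys it. This script sweeps E_Na from
the physiological 58 mV down to -35 mV, tabulates the branch (fixed
point, stability, cycle extrema, frequency), refines the stability
crossing by bisection, and classifies its criticality.

Takes a few minutes: each branch point is a 200 ms stiff integration.
"""

import numpy as np

from pacesim.dynamics import (
    PacemakerSystem,
    branch_to_frame,
    classify_hopf,
    detect_hopf,
    sweep_parameter,
)
from pacesim.synth import canonical_params

params = canonical_params()
system = PacemakerSystem(params, "E_Na")
grid = np.linspace(58.0, -35.0, 33)

branch = sweep_parameter(params, "E_Na", grid, system=system)
frame = branch_to_frame(branch)
print(frame.to_string(index=False, float_format=lambda x: f"{x:9.3f}"))

hopf = detect_hopf(branch, system=system)
print(f"\nHopf bifurcation at E_Na = {hopf.param_value:.2f} mV")
print(f"onset frequency (|Im lambda|/2pi) = {hopf.onset_frequency:.1f} Hz")

verdict = classify_hopf(system, hopf, span=6.0, n_steps=25,
                        settle=150.0, transient=100.0)
print(f"criticality: {verdict}")

frame.to_csv("branch_ena.csv", index=False)
print("branch written to branch_ena.csv")
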