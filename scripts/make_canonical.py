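"""Generate the repository's reference ("canonical") parameter set.

The reference model is a hand-parameterized pacemaker cell, refined with a
Nelder-Mead polish against four dynamical targets chosen to match the
hallmark behaviour of *Apteronotus* pacemaker neurons:

* control oscillation near 380 Hz with ~25 mV peak-to-peak amplitude at
  the control sodium reversal potential (E_Na = 58 mV, i.e. 148 mM bath
  sodium over 15 mM intracellular at 22 C),
* loss of the oscillation through a Hopf bifurcation near E_Na = -12.8 mV,
* an onset (eigenvalue) frequency near 260 Hz at the bifurcation,
* a small calcium conductance whose complete block leaves the oscillation
  intact.

Running this script re-runs the polish from the committed starting point
and rewrites src/pacesim/data/canonical_params.json; it is deterministic
(Nelder-Mead on deterministic simulations).  The committed JSON is the
package's source of truth; this script documents how it was produced.

Usage: python scripts/make_canonical.py [--polish]
"""

import argparse
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from pacesim.model import GateSpec, ModelParams, save_params  # noqa: E402

# polished free coordinates: G_Na, G_K, tau-scale(h), tau-scale(n),
# half-voltage offset (h,n), half-voltage offset (m), G_Leak
POLISHED_X = np.array([
    3.19392269, 3.17737950, 1.04822564, 0.42544412,
    0.02039241, -0.00918376, 0.05411880,
])


def build(x: np.ndarray) -> ModelParams:
    gna, gk, sh, sn, hn_off, m_off, gleak = x
    return ModelParams(
        G_Leak=float(gleak), G_Ca=0.15, G_Na=float(gna), G_K=float(gk),
        E_Leak=-70.0, E_Ca=100.0, E_Na=58.0, E_K=-88.0,
        b=GateSpec(-45.0, 6.0, 0.3, 0.3, -55.0, 20.0),
        g=GateSpec(-45.0, -8.0, 2.0, 2.0, -60.0, 20.0),
        m=GateSpec(-52.0 + float(m_off), 5.0, 0.02, 0.05, -55.0, 15.0),
        h=GateSpec(-58.0 + float(hn_off), -5.0, 0.4 * float(sh), 1.0 * float(sh), -60.0, 15.0),
        n=GateSpec(-55.0 + float(hn_off), 8.0, 0.4 * float(sn), 1.0 * float(sn), -60.0, 20.0),
        q=GateSpec(-20.0, -8.0, 2.0, 2.0, -60.0, 20.0),
    )


def polish(x0: np.ndarray) -> np.ndarray:
    """Nelder-Mead refinement against the four dynamical targets."""
    from scipy.optimize import brentq, minimize

    from pacesim.dynamics import find_fixed_point
    from pacesim.model import jacobian
    from pacesim.simulate import extract_features, integrate

    def max_re(p, ena):
        pp = p.replace(E_Na=float(ena))
        st = find_fixed_point(pp, v_guess=-60.0, search_halfwidth=80.0)
        eig = np.linalg.eigvals(jacobian(st, pp))
        return eig[np.argmax(eig.real)]

    def crossing(p):
        f = lambda e: max_re(p, e).real
        if f(-60.0) * f(58.0) > 0:
            return None
        return brentq(f, -60.0, 58.0, xtol=1e-3)

    def score(x):
        try:
            if x[6] < 0.05 or x[6] > 0.5 or min(x[0], x[1]) < 0.2 or min(x[2], x[3]) < 0.1:
                return 1e3
            p = build(x)
            c = crossing(p)
            if c is None:
                return 1e3
            f_onset = abs(max_re(p, c).imag) / 2 / np.pi * 1000
            feat = extract_features(integrate(p, 150.0, dt=0.01).window(50.0))
            if feat.frequency == 0:
                return 1e3
            return (((feat.frequency - 380) / 10) ** 2
                    + ((feat.peak_to_peak - 25) / 2) ** 2
                    + ((c + 12.8) / 0.8) ** 2
                    + ((f_onset - 260) / 8) ** 2)
        except Exception:
            return 1e3

    res = minimize(score, x0, method="Nelder-Mead",
                   options=dict(maxfev=500, xatol=1e-4, fatol=1e-3))
    return res.x


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--polish", action="store_true",
                    help="re-run the Nelder-Mead polish (slow) instead of "
                         "writing the committed coordinates directly")
    args = ap.parse_args()
    x = polish(POLISHED_X) if args.polish else POLISHED_X
    params = build(x)
    out = Path(__file__).resolve().parents[1] / "src" / "pacesim" / "data" / "canonical_params.json"
    save_params(params, out)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
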