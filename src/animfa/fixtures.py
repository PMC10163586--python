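"""Deterministic fixture generation and closed-form reference values.

The four built-in response pairs admit closed-form equilibria and thresholds:

* rlad: R0 = tau/(1+omega); EE at (1 - (1+omega)/tau, 1/(1+omega)).
* linear_breaking: R0 = tau; EE at ((tau-1)/(tau+omega),
  (tau+omega)/(tau(1+omega))).
* asis: R0 = tau; unique EE prevalence
  y = 1 - (1-2 omega)/(2 tau) - sqrt(((1-2 omega)/(2 tau))^2 + 2 omega/tau).
* aid: the next-generation R0 is undefined (f_cr(0) = 0); the threshold where
  the two endemic equilibria are born is tau* = (omega + 2 + sqrt(8 omega))/2,
  equivalently R0 = 2 tau / (omega + 2 + sqrt(8 omega)); the EE prevalences
  are (2 tau + omega - 2 +/- sqrt((2 tau + omega - 2)^2 - 8 tau omega))/(4 tau).

These formulas are used as independent references in fixture files and the
test suite; the numerical equilibrium finder never sees them.

:func:`generate_fixtures` writes one config per (example x regime) for the
two regimes below and above each example's threshold, plus an expected-value
JSON computed from the closed forms.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

from .config import RunConfig, dump_config

__all__ = [
    "closed_form_ee",
    "closed_form_r0",
    "closed_form_threshold",
    "generate_fixtures",
]


def closed_form_ee(name: str, tau: float, omega: float) -> list:
    """Feasible endemic equilibria (y, z) of a built-in pair, closed form."""
    out = []

    def push(y):
        if 0.0 < y < 1.0:
            z = 1.0 / (tau * (1.0 - y))
            if 0.0 < z <= 1.0:
                out.append((y, z))

    if name == "rlad":
        push(1.0 - (1.0 + omega) / tau)
    elif name == "linear_breaking":
        push((tau - 1.0) / (tau + omega))
    elif name == "asis":
        a = (1.0 - 2.0 * omega) / (2.0 * tau)
        push(1.0 - a - math.sqrt(a * a + 2.0 * omega / tau))
    elif name == "aid":
        b = 2.0 * tau + omega - 2.0
        disc = b * b - 8.0 * tau * omega
        if disc >= 0.0:
            for s in (-1.0, 1.0):
                push((b + s * math.sqrt(disc)) / (4.0 * tau))
    else:
        raise ValueError(f"no closed form for pair {name!r}")
    return sorted(out)


def closed_form_r0(name: str, tau: float, omega: float) -> float:
    """Closed-form reproduction number of a built-in pair (aid: fold-based)."""
    if name == "rlad":
        return tau / (1.0 + omega)
    if name in ("linear_breaking", "asis"):
        return tau
    if name == "aid":
        return 2.0 * tau / (omega + 2.0 + math.sqrt(8.0 * omega))
    raise ValueError(f"no closed form for pair {name!r}")


def closed_form_threshold(name: str, omega: float) -> float:
    """The critical tau where endemic equilibria appear, closed form."""
    if name == "rlad":
        return 1.0 + omega
    if name in ("linear_breaking", "asis"):
        return 1.0
    if name == "aid":
        return (omega + 2.0 + math.sqrt(8.0 * omega)) / 2.0
    raise ValueError(f"no closed form for pair {name!r}")


# study conditions: zeta = xi = 1 (omega = 1) with tau below/above threshold
_REGIMES = {
    "rlad": {"subcritical": 0.8 * 2.0, "supercritical": 3.0},
    "linear_breaking": {"subcritical": 0.8, "supercritical": 3.0},
    "asis": {"subcritical": 0.8, "supercritical": 3.0},
    "aid": {"subcritical": 0.8, "supercritical": 3.0},
}


def generate_fixtures(out_dir) -> list:
    """Write 8 example configs (4 pairs x 2 regimes) plus expected values.

    Expected values come from the closed forms above, so fixture files can
    serve as an independent cross-check of the numerical machinery.  Returns
    the list of written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    expected = {}
    for name, regimes in _REGIMES.items():
        for regime, tau in regimes.items():
            cfg = RunConfig(
                parameters={"tau": tau, "zeta": 1.0, "xi": 1.0},
                responses={"builtin": name},
                analysis={"horizon": 200.0},
                output={"dir": f"out_{name}_{regime}"},
                seed=0,
            )
            path = out / f"{name}_{regime}.yaml"
            path.write_text(dump_config(cfg))
            written.append(path)
            omega = 1.0
            key = f"{name}_{regime}"
            entry = {
                "tau": tau,
                "omega": omega,
                "ee": [list(p) for p in closed_form_ee(name, tau, omega)],
                "tau_star": closed_form_threshold(name, omega),
                "r0": closed_form_r0(name, tau, omega),
            }
            expected[key] = entry
    exp_path = out / "expected.json"
    exp_path.write_text(json.dumps(expected, indent=2, sort_keys=True) + "\n")
    written.append(exp_path)
    return written
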