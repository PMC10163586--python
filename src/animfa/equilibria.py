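"""Equilibria, linear stability, and the basic reproduction number.

The disease-free equilibrium (DFE) always exists at y = 0 with link density

    z0 = f_cr(0) / (omega * f_br(0) + f_cr(0))

unless both responses vanish at 0, in which case every point of the segment
{y = 0, z in [0, 1]} is an equilibrium (a degenerate DFE family).  Endemic
equilibria (EE) are the roots y in (0, 1) of the scalar balance equation

    omega * f_br(y) - (tau - 1) * f_cr(y) + tau * y * f_cr(y) = 0

with link density z = 1/(tau * (1 - y)); y = 1 is never feasible.  When the
next-generation splitting applies (f_cr(0) > 0), the basic reproduction
number is R0 = tau * f_cr(0) / (omega * f_br(0) + f_cr(0)) and R0 > 1
guarantees at least one endemic equilibrium.  When f_cr(0) = 0 the splitting
is undefined and the epidemic threshold is instead located as the value of
tau where endemic equilibria are born (a fold), found by bisection on the
root count.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .dynamics import ModelParameters, vector_field_arrays
from .responses import FunctionalResponsePair, response_derivative

__all__ = [
    "Equilibrium",
    "ThresholdResult",
    "NextGenerationNotApplicable",
    "disease_free_equilibrium",
    "endemic_equilibria",
    "all_equilibria",
    "jacobian",
    "classify_stability",
    "basic_reproduction_number",
    "critical_threshold",
]

#: stability tolerance on eigenvalue real parts; marginal cases are reported
#: as "undetermined", never silently resolved
STABILITY_TOL = 1e-8

#: number of scan points for root bracketing of the equilibrium equation
_SCAN_POINTS = 2001
_Y_LO, _Y_HI = 1e-9, 1.0 - 1e-9


@dataclasses.dataclass(frozen=True)
class Equilibrium:
    """A fixed point with its local linearisation.

    ``kind`` is ``dfe``, ``endemic`` or ``dfe_family`` (the degenerate case
    where both responses vanish at 0 and the whole segment y=0, z in [0,1] is
    stationary; then ``z`` is NaN and ``z_range`` gives the segment).
    ``multiplicity`` is 2 for a tangent (fold) root of the balance equation.
    """

    y: float
    z: float
    kind: str
    jacobian: Optional[np.ndarray] = None
    eigenvalues: Optional[tuple] = None
    stability: str = "undetermined"
    residual: float = 0.0
    multiplicity: int = 1
    z_range: Optional[tuple] = None

    def as_dict(self) -> dict:
        d = {
            "y": self.y,
            "z": self.z,
            "kind": self.kind,
            "stability": self.stability,
            "residual": self.residual,
            "multiplicity": self.multiplicity,
        }
        if self.eigenvalues is not None:
            d["eigenvalues"] = [
                {"re": float(np.real(l)), "im": float(np.imag(l))}
                for l in self.eigenvalues
            ]
        if self.z_range is not None:
            d["z_range"] = list(self.z_range)
        return d


class NextGenerationNotApplicable(ValueError):
    """The next-generation splitting needs f_cr(0) > 0."""


def jacobian(state, params: ModelParameters, pair: FunctionalResponsePair) -> np.ndarray:
    """Jacobian of the vector field at ``state`` (uses analytic derivatives
    of the responses when available, numeric otherwise)."""
    if hasattr(state, "y"):
        y, z = float(state.y), float(state.z)
    else:
        y, z = float(state[0]), float(state[1])
    tau, zeta, xi = params.tau, params.zeta, params.xi
    dbr = response_derivative(pair, "br", y)
    dcr = response_derivative(pair, "cr", y)
    return np.array(
        [
            [-1.0 + tau * (1.0 - 2.0 * y) * z, tau * y * (1.0 - y)],
            [-zeta * z * dbr + xi * (1.0 - z) * dcr, -zeta * pair.br(y) - xi * pair.cr(y)],
        ]
    )


def classify_stability(eigenvalues, tol: float = STABILITY_TOL) -> str:
    """Classify a planar fixed point from its eigenvalue pair.

    Both real parts < -tol: stable (node if real, spiral if complex); both
    > tol: unstable likewise; opposite signs: saddle; any real part within
    tol of zero: undetermined (linear analysis is inconclusive).
    """
    if tol <= 0.0:
        raise ValueError("tol must be positive")
    l1, l2 = complex(eigenvalues[0]), complex(eigenvalues[1])
    re = np.array([l1.real, l2.real])
    is_complex = abs(l1.imag) > tol or abs(l2.imag) > tol
    if np.any(np.abs(re) <= tol):
        return "undetermined"
    if np.all(re < 0.0):
        return "stable_spiral" if is_complex else "stable_node"
    if np.all(re > 0.0):
        return "unstable_spiral" if is_complex else "unstable_node"
    return "saddle"


def _finish(y, z, kind, params, pair, multiplicity=1, z_range=None) -> Equilibrium:
    if z_range is not None:
        # degenerate family: no single linearisation applies
        return Equilibrium(
            y=y,
            z=float("nan"),
            kind=kind,
            jacobian=None,
            eigenvalues=None,
            stability="undetermined",
            residual=0.0,
            z_range=z_range,
        )
    J = jacobian((y, z), params, pair)
    eigs = tuple(np.linalg.eigvals(J))
    dy, dz = vector_field_arrays(y, z, params, pair)
    residual = float(max(abs(dy), abs(dz)))
    return Equilibrium(
        y=float(y),
        z=float(z),
        kind=kind,
        jacobian=J,
        eigenvalues=eigs,
        stability=classify_stability(eigs),
        residual=residual,
        multiplicity=multiplicity,
    )


def disease_free_equilibrium(
    params: ModelParameters, pair: FunctionalResponsePair
) -> Equilibrium:
    """The disease-free equilibrium (or the degenerate DFE family).

    z0 = f_cr(0) / (omega f_br(0) + f_cr(0)) when the denominator is nonzero;
    when f_br(0) = f_cr(0) = 0 the whole segment {y=0, z in [0,1]} is
    stationary and is returned as kind ``dfe_family`` with ``z_range=(0,1)``.
    """
    fb0, fc0 = pair.br(0.0), pair.cr(0.0)
    denom = params.omega * fb0 + fc0
    if denom == 0.0:
        return _finish(0.0, float("nan"), "dfe_family", params, pair, z_range=(0.0, 1.0))
    return _finish(0.0, fc0 / denom, "dfe", params, pair)


def _balance(y, params: ModelParameters, pair: FunctionalResponsePair):
    """The endemic balance function whose roots in (0,1) are EE prevalences."""
    tau, omega = params.tau, params.omega
    fb, fc = pair.br(y), pair.cr(y)
    return omega * fb - (tau - 1.0) * fc + tau * np.asarray(y) * fc


def endemic_equilibria(
    params: ModelParameters, pair: FunctionalResponsePair
) -> list:
    """All endemic equilibria: roots of the balance equation in (0, 1).

    A dense sign-scan (2001 points) is refined by Brent's method; near-tangent
    root pairs that fall between scan points are recovered by refining local
    extrema of the balance function and re-bracketing, and exact tangencies
    (|balance| <= 1e-10 at the extremum) are reported with multiplicity 2.
    Roots whose link density z = 1/(tau(1-y)) falls outside (0, 1] are
    infeasible and discarded; an empty list is a valid outcome.
    """
    tau = params.tau
    grid = np.linspace(_Y_LO, _Y_HI, _SCAN_POINTS)
    g = np.asarray(_balance(grid, params, pair), dtype=float)
    finite = np.isfinite(g)

    roots: list = []

    def _refine(a, b):
        try:
            r = brentq(lambda yy: float(_balance(yy, params, pair)), a, b, xtol=1e-14)
        except ValueError:
            return
        roots.append((float(r), 1))

    sign = np.sign(g)
    for i in range(len(grid) - 1):
        if not (finite[i] and finite[i + 1]):
            continue
        if sign[i] == 0.0:
            roots.append((float(grid[i]), 1))
        elif sign[i] * sign[i + 1] < 0.0:
            _refine(grid[i], grid[i + 1])
    if sign[-1] == 0.0 and finite[-1]:
        roots.append((float(grid[-1]), 1))

    # interior extrema: catch tangencies and root pairs closer than the scan step
    interior = np.arange(1, len(grid) - 1)
    for i in interior:
        if not (finite[i - 1] and finite[i] and finite[i + 1]):
            continue
        is_min = g[i] <= g[i - 1] and g[i] <= g[i + 1] and g[i] > 0.0
        is_max = g[i] >= g[i - 1] and g[i] >= g[i + 1] and g[i] < 0.0
        if not (is_min or is_max):
            continue
        a, b = grid[i - 1], grid[i + 1]
        fun = (lambda yy: float(_balance(yy, params, pair))) if is_min else (
            lambda yy: -float(_balance(yy, params, pair))
        )
        res = minimize_scalar(fun, bounds=(a, b), method="bounded",
                              options={"xatol": 1e-13})
        ym, vm = float(res.x), float(res.fun) * (1.0 if is_min else -1.0)
        if abs(vm) <= 1e-10:
            roots.append((ym, 2))  # tangent (fold) root
        elif (vm < 0.0) == is_min:
            # the extremum crosses zero: two roots hide between scan points
            for lo, hi in ((a, ym), (ym, b)):
                glo = float(_balance(lo, params, pair))
                ghi = float(_balance(hi, params, pair))
                if glo * ghi < 0.0:
                    _refine(lo, hi)

    # merge duplicates, keep feasible roots, attach link density
    roots.sort()
    merged: list = []
    for r, mult in roots:
        if merged and abs(r - merged[-1][0]) <= 1e-8:
            merged[-1] = (merged[-1][0], max(merged[-1][1], mult))
        else:
            merged.append((r, mult))

    out = []
    for r, mult in merged:
        if not (0.0 < r < 1.0):
            continue
        z = 1.0 / (tau * (1.0 - r))
        if not (0.0 < z <= 1.0):
            continue
        out.append(_finish(r, z, "endemic", params, pair, multiplicity=mult))
    return out


def all_equilibria(params: ModelParameters, pair: FunctionalResponsePair) -> list:
    """DFE (or DFE family) followed by the endemic equilibria."""
    return [disease_free_equilibrium(params, pair)] + endemic_equilibria(params, pair)


def basic_reproduction_number(
    params: ModelParameters, pair: FunctionalResponsePair
) -> float:
    """Next-generation R0 = tau * f_cr(0) / (omega f_br(0) + f_cr(0)).

    Requires f_cr(0) > 0; otherwise the splitting of the DFE linearisation
    into new-infection and transition parts does not exist and
    :class:`NextGenerationNotApplicable` is raised (use
    :func:`critical_threshold` to locate the fold threshold instead).
    """
    fb0, fc0 = pair.br(0.0), pair.cr(0.0)
    if not fc0 > 0.0:
        raise NextGenerationNotApplicable(
            "next-generation method not applicable: f_cr(0) = 0"
        )
    return params.tau * fc0 / (params.omega * fb0 + fc0)


@dataclasses.dataclass(frozen=True)
class ThresholdResult:
    """A critical effective infection rate located by bisection on the
    endemic-equilibrium count.  ``ee_count_below``/``ee_count_above`` are the
    counts on either side of the bracket; which bifurcation occurred
    (transcritical vs fold) is left to the report layer."""

    tau_star: float
    ee_count_below: int
    ee_count_above: int
    bracket_width: float


def critical_threshold(
    params_template: ModelParameters,
    pair: FunctionalResponsePair,
    tau_range,
    tol: float = 1e-6,
) -> ThresholdResult:
    """Bisect on tau for the value where the endemic-equilibrium count changes.

    ``params_template`` supplies zeta and xi (hence omega); tau is swept over
    ``tau_range``.  Raises ValueError when the count is the same at both ends.
    """
    lo, hi = float(tau_range[0]), float(tau_range[1])
    if not (0.0 < lo < hi):
        raise ValueError("tau_range must satisfy 0 < lo < hi")

    def count(tau):
        p = ModelParameters(tau=tau, zeta=params_template.zeta, xi=params_template.xi)
        return len(endemic_equilibria(p, pair))

    c_lo, c_hi = count(lo), count(hi)
    if c_lo == c_hi:
        raise ValueError(
            f"no threshold in range: EE count is {c_lo} at both tau={lo} and tau={hi}"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if count(mid) == c_lo:
            lo = mid
        else:
            hi = mid
    return ThresholdResult(
        tau_star=0.5 * (lo + hi),
        ee_count_below=c_lo,
        ee_count_above=c_hi,
        bracket_width=hi - lo,
    )
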