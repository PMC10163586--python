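"""Functional responses for link-breaking and link-creation.

The contact network reacts to the epidemic through two prevalence-dependent
multipliers: ``f_br(y)`` scales the link-breaking rate and ``f_cr(y)`` the
link-creation rate, with the prevalence ``y`` in [0, 1].  Both responses must
be non-negative on [0, 1] and must not vanish identically together (otherwise
the link density is frozen and the model degenerates to static SIS).

Four named pairs are built in:

===================  ==================  ==================
name                 f_br(y)             f_cr(y)
===================  ==================  ==================
``rlad``             1                   1
``linear_breaking``  y                   1
``asis``             2 y (1 - y)         (1 - y)^2
``aid``              (1 - y)^2           2 y (1 - y)
===================  ==================  ==================

``rlad`` is the random link-activation/deactivation network (density evolves
independently of the disease), ``linear_breaking`` breaks links in proportion
to prevalence, ``asis`` is the adaptive-SIS response (links broken between
susceptible and infected, created between susceptibles), and ``aid`` is the
adaptive information-diffusion response (links created *because* the spreading
item is attractive).  The factor 2 in the asis/aid pairs is a conversion
factor from the underlying Markovian network model and is kept verbatim.

User-supplied pairs are accepted either as plain callables or as expression
strings in a restricted arithmetic grammar (variable ``y``, ``+ - * / ^``,
parentheses, ``exp``, ``log``); expressions are differentiated symbolically.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Optional, Sequence

import numpy as np
import sympy as sp

__all__ = [
    "FunctionalResponsePair",
    "ValidationReport",
    "RladClosedForm",
    "builtin_pair",
    "BUILTIN_NAMES",
    "pair_from_expressions",
    "pair_from_callables",
    "validate_pair",
    "response_derivative",
    "rlad_closed_form",
    "rlad_coefficients",
]

#: central-difference step for the numeric derivative fallback; responses are
#: polynomial-like, so truncation and roundoff balance near 1e-10 at this h
_DIFF_STEP = 1e-6

#: negativity slack on the validation grid, absorbs roundoff of valid responses
_NEG_TOL = -1e-12


def _eval(f: Callable, y):
    """Evaluate a response at scalar or array ``y``, always returning floats."""
    arr = np.asarray(y, dtype=float)
    out = np.asarray(f(arr), dtype=float)
    if out.shape != arr.shape:
        out = np.broadcast_to(out, arr.shape)
    if arr.ndim == 0:
        return float(out)
    return np.array(out, dtype=float)


@dataclasses.dataclass(frozen=True)
class FunctionalResponsePair:
    """A link-breaking/link-creation response pair with optional derivatives.

    Attributes
    ----------
    name:
        Label used in reports.
    f_br, f_cr:
        Non-negative maps [0, 1] -> R+ (vectorised over numpy arrays).
    dfbr, dfcr:
        Optional analytic derivatives; when absent, central differences with
        one-sided stencils at the boundary are used.
    smoothness_hint:
        True when analytic derivatives were supplied (or derived symbolically).
    expressions:
        The source expression strings when the pair was built from text.
    """

    name: str
    f_br: Callable
    f_cr: Callable
    dfbr: Optional[Callable] = None
    dfcr: Optional[Callable] = None
    smoothness_hint: bool = False
    expressions: Optional[tuple] = None

    def br(self, y):
        return _eval(self.f_br, y)

    def cr(self, y):
        return _eval(self.f_cr, y)

    def dbr(self, y):
        return response_derivative(self, "br", y)

    def dcr(self, y):
        return response_derivative(self, "cr", y)


_BUILTINS = {
    "rlad": dict(
        f_br=lambda y: np.ones_like(y),
        f_cr=lambda y: np.ones_like(y),
        dfbr=lambda y: np.zeros_like(y),
        dfcr=lambda y: np.zeros_like(y),
        expressions=("1", "1"),
    ),
    "linear_breaking": dict(
        f_br=lambda y: y,
        f_cr=lambda y: np.ones_like(y),
        dfbr=lambda y: np.ones_like(y),
        dfcr=lambda y: np.zeros_like(y),
        expressions=("y", "1"),
    ),
    "asis": dict(
        f_br=lambda y: 2.0 * y * (1.0 - y),
        f_cr=lambda y: (1.0 - y) ** 2,
        dfbr=lambda y: 2.0 - 4.0 * y,
        dfcr=lambda y: -2.0 * (1.0 - y),
        expressions=("2*y*(1-y)", "(1-y)^2"),
    ),
    "aid": dict(
        f_br=lambda y: (1.0 - y) ** 2,
        f_cr=lambda y: 2.0 * y * (1.0 - y),
        dfbr=lambda y: -2.0 * (1.0 - y),
        dfcr=lambda y: 2.0 - 4.0 * y,
        expressions=("(1-y)^2", "2*y*(1-y)"),
    ),
}

BUILTIN_NAMES = tuple(_BUILTINS)


def builtin_pair(name: str) -> FunctionalResponsePair:
    """Return one of the built-in response pairs by name.

    Raises
    ------
    ValueError
        If ``name`` is not one of :data:`BUILTIN_NAMES`.
    """
    try:
        spec = _BUILTINS[name]
    except KeyError:
        raise ValueError(
            f"unknown builtin response pair {name!r}; "
            f"valid names are {', '.join(BUILTIN_NAMES)}"
        ) from None
    return FunctionalResponsePair(
        name=name,
        f_br=spec["f_br"],
        f_cr=spec["f_cr"],
        dfbr=spec["dfbr"],
        dfcr=spec["dfcr"],
        smoothness_hint=True,
        expressions=spec["expressions"],
    )


_Y = sp.Symbol("y", real=True)

# restricted grammar: only these names may appear in user expressions
_EXPR_LOCALS = {"y": _Y, "exp": sp.exp, "log": sp.log}
_ALLOWED_FUNCS = (sp.exp, sp.log)


def _parse_expression(text: str) -> sp.Expr:
    expr = sp.parse_expr(
        text.replace("^", "**"),
        local_dict=_EXPR_LOCALS,
        global_dict={
            "Integer": sp.Integer,
            "Float": sp.Float,
            "Rational": sp.Rational,
            "Symbol": sp.Symbol,
        },
        evaluate=True,
    )
    if not expr.free_symbols <= {_Y}:
        bad = sorted(str(s) for s in expr.free_symbols - {_Y})
        raise ValueError(f"expression may only use the variable 'y'; got {bad}")
    for f in expr.atoms(sp.Function):
        if not isinstance(f, _ALLOWED_FUNCS):
            raise ValueError(
                f"function {f.func} not allowed; only exp and log are supported"
            )
    return expr


def pair_from_expressions(
    f_br: str, f_cr: str, name: str = "custom"
) -> FunctionalResponsePair:
    """Build a response pair from expression strings in ``y``.

    The grammar is restricted to ``y``, arithmetic (+ - * / ^), parentheses
    and the functions ``exp`` and ``log``.  Derivatives are computed
    symbolically, so Jacobian-based analyses use exact derivatives.
    """
    br_expr, cr_expr = _parse_expression(f_br), _parse_expression(f_cr)
    mods = ["numpy"]
    return FunctionalResponsePair(
        name=name,
        f_br=sp.lambdify(_Y, br_expr, modules=mods),
        f_cr=sp.lambdify(_Y, cr_expr, modules=mods),
        dfbr=sp.lambdify(_Y, sp.diff(br_expr, _Y), modules=mods),
        dfcr=sp.lambdify(_Y, sp.diff(cr_expr, _Y), modules=mods),
        smoothness_hint=True,
        expressions=(f_br, f_cr),
    )


def pair_from_callables(
    f_br: Callable,
    f_cr: Callable,
    dfbr: Optional[Callable] = None,
    dfcr: Optional[Callable] = None,
    name: str = "custom",
) -> FunctionalResponsePair:
    """Wrap plain callables as a response pair (numeric derivatives unless given)."""
    return FunctionalResponsePair(
        name=name,
        f_br=f_br,
        f_cr=f_cr,
        dfbr=dfbr,
        dfcr=dfcr,
        smoothness_hint=dfbr is not None and dfcr is not None,
        expressions=None,
    )


@dataclasses.dataclass(frozen=True)
class ValidationReport:
    valid: bool
    violations: tuple
    grid_size: int


def _numeric_derivative(f: Callable, y):
    """Central difference, one-sided (2nd order) stencils at the boundary."""
    arr = np.atleast_1d(np.asarray(y, dtype=float))
    h = _DIFF_STEP
    out = np.empty_like(arr)
    lo = arr < h
    hi = arr > 1.0 - h
    mid = ~(lo | hi)
    if mid.any():
        ym = arr[mid]
        out[mid] = (_eval(f, ym + h) - _eval(f, ym - h)) / (2.0 * h)
    if lo.any():
        ym = arr[lo]
        out[lo] = (
            -3.0 * _eval(f, ym) + 4.0 * _eval(f, ym + h) - _eval(f, ym + 2 * h)
        ) / (2.0 * h)
    if hi.any():
        ym = arr[hi]
        out[hi] = (
            3.0 * _eval(f, ym) - 4.0 * _eval(f, ym - h) + _eval(f, ym - 2 * h)
        ) / (2.0 * h)
    if np.asarray(y).ndim == 0:
        return float(out[0])
    return out


def response_derivative(pair: FunctionalResponsePair, which: str, y):
    """Derivative of one response at ``y``: analytic if available, else numeric.

    ``which`` selects ``"br"`` or ``"cr"``.  Valid for ``y`` in [0, 1]; the
    boundary is handled by one-sided stencils in the numeric fallback.
    """
    if which == "br":
        fn, dfn = pair.f_br, pair.dfbr
    elif which == "cr":
        fn, dfn = pair.f_cr, pair.dfcr
    else:
        raise ValueError(f"which must be 'br' or 'cr', got {which!r}")
    if dfn is not None:
        return _eval(dfn, y)
    return _numeric_derivative(fn, y)


def validate_pair(
    pair: FunctionalResponsePair, grid_size: int = 10001
) -> ValidationReport:
    """Check the response-pair invariants on a uniform grid over [0, 1].

    Reported violations: non-finite values, negativity beyond roundoff
    (tolerance -1e-12), both responses identically zero, and (when analytic
    derivatives were supplied) disagreement with a central difference beyond
    1e-6.  Violations are collected, never raised.
    """
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    grid = np.linspace(0.0, 1.0, grid_size)
    violations = []
    values = {}
    for which, fn in (("f_br", pair.f_br), ("f_cr", pair.f_cr)):
        try:
            vals = _eval(fn, grid)
        except Exception as exc:  # user callables may do anything
            violations.append(f"{which}: evaluation failed ({exc})")
            vals = np.full_like(grid, np.nan)
        values[which] = vals
        bad = ~np.isfinite(vals)
        if bad.any():
            violations.append(
                f"{which}: non-finite value at y={grid[bad][0]:.6g} "
                f"({int(bad.sum())} grid points)"
            )
        neg = np.isfinite(vals) & (vals < _NEG_TOL)
        if neg.any():
            violations.append(
                f"{which}: negative value {vals[neg].min():.6g} at "
                f"y={grid[neg][0]:.6g} ({int(neg.sum())} grid points)"
            )
    with np.errstate(invalid="ignore"):
        br_zero = np.all(np.abs(values["f_br"]) <= 1e-15)
        cr_zero = np.all(np.abs(values["f_cr"]) <= 1e-15)
    if br_zero and cr_zero:
        violations.append("both responses identically zero on [0,1]")
    if pair.dfbr is not None or pair.dfcr is not None:
        # compare on a coarser grid; h-stencils at 1e-6 need room
        dgrid = np.linspace(0.0, 1.0, min(grid_size, 1001))
        for which, fn, dfn in (
            ("f_br", pair.f_br, pair.dfbr),
            ("f_cr", pair.f_cr, pair.dfcr),
        ):
            if dfn is None:
                continue
            analytic = _eval(dfn, dgrid)
            numeric = _numeric_derivative(fn, dgrid)
            with np.errstate(invalid="ignore"):
                dev = np.nanmax(np.abs(analytic - numeric)) if np.isfinite(
                    analytic
                ).any() else np.inf
            if not np.isfinite(dev) or dev > 1e-6:
                violations.append(
                    f"{which}: analytic derivative deviates from central "
                    f"difference by {dev:.3g} (> 1e-6)"
                )
    return ValidationReport(
        valid=not violations, violations=tuple(violations), grid_size=grid_size
    )


@dataclasses.dataclass(frozen=True)
class RladClosedForm:
    """Coefficients of the logistic closed form for the RLAD prevalence.

    With the link density held at its limit ``z* = 1/(1+omega)``, the
    prevalence obeys a logistic equation with steady state
    ``y_eq = 1 - (1+omega)/tau``, growth rate ``growth_rate = tau/(1+omega) - 1``
    and inflection ("epidemic peak") time ``t_peak``.  ``t_peak`` is finite
    only for 0 < y(0) < y_eq; it is NaN otherwise (the closed form itself
    remains valid for y(0) > y_eq).
    """

    y_eq: float
    growth_rate: float
    t_peak: float
    z_limit: float


def rlad_coefficients(params, y0: float) -> RladClosedForm:
    """Logistic coefficients for the RLAD model (requires tau > 1 + omega)."""
    tau, omega = params.tau, params.omega
    if tau <= 1.0 + omega:
        raise ValueError(
            "no endemic logistic branch: requires tau > 1 + omega "
            f"(tau={tau:.6g}, omega={omega:.6g})"
        )
    y_eq = 1.0 - (1.0 + omega) / tau
    growth = tau / (1.0 + omega) - 1.0
    if 0.0 < y0 < y_eq:
        t_peak = math.log(y_eq / y0 - 1.0) / growth
    else:
        t_peak = math.nan
    return RladClosedForm(
        y_eq=y_eq, growth_rate=growth, t_peak=t_peak, z_limit=1.0 / (1.0 + omega)
    )


def rlad_closed_form(params, y0: float, z0: float, t):
    """Closed-form RLAD state (y(t), z(t)) under the fast-z approximation.

    The link density decouples from the disease:
    ``z(t) = z* + (z0 - z*) exp(-(xi+zeta) t)`` with ``z* = 1/(1+omega)``.
    Holding z at z*, the prevalence solves a logistic equation; this requires
    ``tau > 1 + omega``.  ``y0 = 0`` returns y(t) = 0 exactly, and ``y0`` at
    the steady state returns it unchanged.  ``t`` may be a scalar or array.
    """
    t_arr = np.asarray(t, dtype=float)
    z_star = 1.0 / (1.0 + params.omega)
    z = z_star + (z0 - z_star) * np.exp(-(params.xi + params.zeta) * t_arr)
    if y0 == 0.0:
        y = np.zeros_like(t_arr)
    else:
        cf = rlad_coefficients(params, y0)
        if y0 == cf.y_eq:
            y = np.full_like(t_arr, y0)
        else:
            # y = y_eq / (1 + (y_eq/y0 - 1) e^{-K t}); valid on both sides of y_eq
            y = cf.y_eq / (1.0 + (cf.y_eq / y0 - 1.0) * np.exp(-cf.growth_rate * t_arr))
    if t_arr.ndim == 0:
        return float(y), float(z)
    return y, z
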