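"""The planar adaptive-SIS vector field and trajectory integration.

State: prevalence ``y`` (fraction infected) and link density ``z`` (fraction
of realized contacts), both in [0, 1].  After rescaling time by the curing
rate, the dynamics are

    dy/dt = -y + tau * y * (1 - y) * z
    dz/dt = -zeta * z * f_br(y) + xi * (1 - z) * f_cr(y)

with effective infection rate ``tau = beta/delta``, link-breaking rate
``zeta``, link-creation rate ``xi`` and the effective link-breaking ratio
``omega = zeta/xi``.  The unit square is forward invariant: the flow points
inward (or is tangent) on every edge, so trajectories starting in [0,1]^2
stay there.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .responses import FunctionalResponsePair

__all__ = [
    "ModelParameters",
    "State",
    "Trajectory",
    "SimulationError",
    "rescale_parameters",
    "vector_field",
    "vector_field_arrays",
    "simulate",
]

#: post-step clamp allowance; larger boundary excursions indicate solver failure
#: since forward invariance holds analytically
CLAMP_TOL = 1e-9


@dataclasses.dataclass(frozen=True)
class ModelParameters:
    """Dimensionless model rates (per rescaled time unit).

    ``tau`` is the effective infection rate beta/delta, ``zeta`` and ``xi``
    the link-breaking and link-creation rates after rescaling by the curing
    rate.  ``omega = zeta/xi`` is always recomputed, never stored.  The
    optional ``delta_raw``/``beta_raw`` record the pre-rescaling rates, and
    ``epsilon`` the slow-fast time-scale separation (0 < epsilon < 1).
    """

    tau: float
    zeta: float = 1.0
    xi: float = 1.0
    delta_raw: Optional[float] = None
    beta_raw: Optional[float] = None
    epsilon: Optional[float] = None

    def __post_init__(self):
        for name in ("tau", "zeta", "xi"):
            if not getattr(self, name) > 0.0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.epsilon is not None and not (0.0 < self.epsilon < 1.0):
            raise ValueError(f"epsilon must be in (0, 1), got {self.epsilon}")

    @property
    def omega(self) -> float:
        return self.zeta / self.xi


def rescale_parameters(
    delta: float, beta: float, zeta_raw: float, xi_raw: float
) -> ModelParameters:
    """Rescale raw per-time rates by the curing rate delta.

    tau = beta/delta, zeta = zeta_raw/delta, xi = xi_raw/delta; omega = zeta/xi
    is invariant under the rescaling.
    """
    for name, value in (
        ("delta", delta),
        ("beta", beta),
        ("zeta_raw", zeta_raw),
        ("xi_raw", xi_raw),
    ):
        if not value > 0.0:
            raise ValueError(f"{name} must be positive, got {value}")
    return ModelParameters(
        tau=beta / delta,
        zeta=zeta_raw / delta,
        xi=xi_raw / delta,
        delta_raw=delta,
        beta_raw=beta,
    )


@dataclasses.dataclass(frozen=True)
class State:
    y: float
    z: float

    def __post_init__(self):
        if not (0.0 <= self.y <= 1.0 and 0.0 <= self.z <= 1.0):
            raise ValueError(f"state ({self.y}, {self.z}) outside [0,1]^2")

    def as_array(self) -> np.ndarray:
        return np.array([self.y, self.z], dtype=float)


def vector_field_arrays(y, z, params: ModelParameters, pair: FunctionalResponsePair):
    """Vectorised right-hand side; y and z may be arrays (clipped to [0,1])."""
    y = np.clip(np.asarray(y, dtype=float), 0.0, 1.0)
    z = np.clip(np.asarray(z, dtype=float), 0.0, 1.0)
    dy = -y + params.tau * y * (1.0 - y) * z
    dz = -params.zeta * z * pair.br(y) + params.xi * (1.0 - z) * pair.cr(y)
    return dy, dz


def vector_field(state, params: ModelParameters, pair: FunctionalResponsePair):
    """The planar vector field (dy/dt, dz/dt) at a single state."""
    if isinstance(state, State):
        y, z = state.y, state.z
    else:
        y, z = state
    dy, dz = vector_field_arrays(y, z, params, pair)
    return float(dy), float(dz)


@dataclasses.dataclass
class Trajectory:
    """A simulated orbit: strictly increasing times, states in [0,1]^2.

    ``terminal_event`` is ``"horizon_reached"``, ``"converged:<id>"`` (the id
    names the nearest known equilibrium, or ``interior`` when detection used
    the vector-field norm alone), or ``"none"``.  ``max_clamp`` records the
    largest boundary excursion before clamping.
    """

    times: np.ndarray
    y: np.ndarray
    z: np.ndarray
    terminal_event: str = "none"
    max_clamp: float = 0.0
    solver_stats: dict = dataclasses.field(default_factory=dict)

    @property
    def states(self) -> np.ndarray:
        return np.column_stack([self.y, self.z])

    def terminal_state(self):
        return float(self.y[-1]), float(self.z[-1])


class SimulationError(RuntimeError):
    """Raised on integrator failure; carries the last valid state and time."""

    def __init__(self, message, t=None, state=None):
        super().__init__(message)
        self.t = t
        self.state = state


def simulate(
    params: ModelParameters,
    pair: FunctionalResponsePair,
    initial,
    horizon: float,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    equilibria: Optional[Sequence] = None,
    vf_tol: float = 1e-9,
    eq_tol: float = 1e-6,
    t_eval=None,
    max_clamp: float = CLAMP_TOL,
) -> Trajectory:
    """Integrate the model from ``initial`` up to ``horizon`` (rescaled time).

    Integration is adaptive and stiffness-capable (LSODA).  The run stops
    early when the vector-field norm drops below ``vf_tol`` or the state comes
    within ``eq_tol`` of a known equilibrium (``equilibria`` may be a sequence
    of objects with ``y``/``z`` attributes or plain pairs); the nearest
    equilibrium is reported in ``terminal_event``.  States are clamped to
    [0,1]^2 after the fact; excursions beyond ``max_clamp`` raise
    :class:`SimulationError`, since the square is invariant analytically.
    """
    if horizon <= 0.0:
        raise ValueError("horizon must be positive")
    if isinstance(initial, State):
        u0 = initial.as_array()
    else:
        u0 = np.asarray(initial, dtype=float)
        State(float(u0[0]), float(u0[1]))  # validates membership in [0,1]^2

    eq_points = []
    for eq in equilibria or ():
        if hasattr(eq, "y"):
            pt = (float(eq.y), float(eq.z))
            label = getattr(eq, "kind", "eq")
        else:
            pt = (float(eq[0]), float(eq[1]))
            label = "eq"
        if np.isfinite(pt).all():
            eq_points.append((pt, label))

    def rhs(t, u):
        dy, dz = vector_field_arrays(u[0], u[1], params, pair)
        return [dy, dz]

    events = []

    def vf_norm_event(t, u):
        dy, dz = vector_field_arrays(u[0], u[1], params, pair)
        return float(np.hypot(dy, dz)) - vf_tol

    vf_norm_event.terminal = True
    vf_norm_event.direction = -1
    events.append(vf_norm_event)

    if eq_points:

        def eq_prox_event(t, u):
            # fire at half the tolerance so the stored terminal state is
            # strictly within eq_tol despite event root-finding error
            d = min(np.hypot(u[0] - p[0], u[1] - p[1]) for p, _ in eq_points)
            return d - 0.5 * eq_tol

        eq_prox_event.terminal = True
        eq_prox_event.direction = -1
        events.append(eq_prox_event)

    sol = solve_ivp(
        rhs,
        (0.0, float(horizon)),
        u0,
        method=method,
        rtol=rtol,
        atol=atol,
        dense_output=False,
        t_eval=t_eval,
        events=events,
    )
    if not sol.success:
        last_t = float(sol.t[-1]) if sol.t.size else 0.0
        last_u = sol.y[:, -1] if sol.t.size else u0
        raise SimulationError(
            f"integrator failed at t={last_t:.6g}: {sol.message}",
            t=last_t,
            state=(float(last_u[0]), float(last_u[1])),
        )

    ys, zs = sol.y[0], sol.y[1]
    excursion = float(
        max(
            np.max(np.maximum(-ys, ys - 1.0), initial=0.0),
            np.max(np.maximum(-zs, zs - 1.0), initial=0.0),
            0.0,
        )
    )
    if excursion > max_clamp:
        raise SimulationError(
            f"trajectory left [0,1]^2 by {excursion:.3g} (> {max_clamp:.3g}); "
            "forward invariance violated numerically",
            t=float(sol.t[-1]),
            state=(float(ys[-1]), float(zs[-1])),
        )
    ys = np.clip(ys, 0.0, 1.0)
    zs = np.clip(zs, 0.0, 1.0)

    terminal = "horizon_reached" if sol.status == 0 else "none"
    if sol.status == 1:  # a terminal event fired
        yf, zf = ys[-1], zs[-1]
        if eq_points:
            dists = [np.hypot(yf - p[0], zf - p[1]) for p, _ in eq_points]
            k = int(np.argmin(dists))
            if dists[k] <= max(eq_tol, 1e-3):
                pt, label = eq_points[k]
                terminal = f"converged:{label}({pt[0]:.6g},{pt[1]:.6g})"
            else:
                terminal = "converged:interior"
        else:
            terminal = "converged:interior"

    return Trajectory(
        times=sol.t.copy(),
        y=ys,
        z=zs,
        terminal_event=terminal,
        max_clamp=excursion,
        solver_stats={
            "method": method,
            "rtol": rtol,
            "atol": atol,
            "nfev": int(sol.nfev),
            "steps": int(sol.t.size),
        },
    )
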