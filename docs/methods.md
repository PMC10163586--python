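# Methods

## Model and assumptions

The toolkit analyses a planar mean-field model of an SIS process on an
adaptive contact network. The state is (y, z) ∈ [0,1]²: prevalence and
average link density. After rescaling time by the curing rate δ (so τ = β/δ,
ζ and ξ are per rescaled time unit), the dynamics are

    dy/dt = −y + τ y (1 − y) z,
    dz/dt = −ζ z f_br(y) + ξ (1 − z) f_cr(y).

Assumptions inherited from the modelling frame: homogeneous mixing (z enters
the infection term as an average contact weight), non-negative responses
f_br, f_cr on [0,1] that do not vanish identically together, and O(1)
positive rates. The square [0,1]² is forward invariant because the flow is
inward or tangent on each edge (dy/dt = 0 at y=0, = −1 at y=1;
dz/dt ≥ 0 at z=0, ≤ 0 at z=1).

Responses are required to be continuous with finite one-sided derivatives;
non-differentiable user inputs are flagged by validation (derivative
mismatch against a central difference), not rejected, since the vector field
itself needs no derivatives — only Jacobian-based analyses do.

## Parameters

| parameter | meaning | units | default |
|---|---|---|---|
| τ | effective infection rate β/δ | dimensionless | — (study conditions use 3.0 supercritical, 0.8 subcritical) |
| ζ, ξ | link-breaking / creation rates | per rescaled time | 1.0, 1.0 |
| ω | ζ/ξ, derived, never stored | dimensionless | 1.0 under defaults |
| ε | slow-fast scale (network reacts at rate ε) | dimensionless | 0.01 |

The defaults ζ = ξ = 1 and the τ ∈ {0.8, 3} regimes are the standard study
conditions for the four built-in response pairs; ε = 0.01 for slow-network
runs.

## Numerical choices

**Integration.** `scipy.integrate.solve_ivp` with LSODA, rtol 1e-8,
atol 1e-10. Convergence is detected by two terminal events: vector-field
norm < 1e-9, or distance to a known equilibrium < 1e-6 (the event fires at
half that distance so the stored terminal state is strictly within
tolerance; the nearest equilibrium is reported). States are clamped to
[0,1]² post hoc; excursions beyond 1e-9 abort with an error, because
invariance holds analytically and larger excursions indicate solver failure.
The right-hand side clips its arguments to the square, which keeps
excursions at roundoff level.

**Derivatives of responses.** Analytic when supplied (built-ins, and
expression inputs via symbolic differentiation); otherwise central
differences with step 1e-6 and second-order one-sided stencils at y ∈ {0,1}.
For smooth polynomial-like responses, truncation and roundoff balance near
1e-10.

**Endemic root finding.** The balance function
g(y) = ω f_br − (τ−1) f_cr + τ y f_cr is scanned on 2001 uniform points of
[1e-9, 1−1e-9]; sign changes are refined by Brent's method (xtol 1e-14) and
duplicates merged within 1e-8. Positive local minima (and negative maxima)
of g are additionally refined by bounded scalar minimisation: if the
extremum crosses zero, the two hidden roots are re-bracketed (this is what
keeps fold thresholds accurate to better than 1e-6 even when the emerging
root pair is closer than the scan spacing); if |g| ≤ 1e-10 at the extremum,
a tangent root with multiplicity 2 is reported. The scan density is a
documented limitation for adversarial user responses with structure finer
than ~5e-4 in y.

**Stability labels.** Eigenvalue real parts are compared against tol = 1e-8;
anything within tolerance of zero is reported as `undetermined` rather than
silently resolved, matching the analytic treatment of the marginal cases
(e.g. the transcritical point, and the degenerate DFE family when both
responses vanish at 0, for which no linearisation label is assigned).

**Region of attraction.** P solves P J + JᵀP = −I
(`scipy.linalg.solve_continuous_lyapunov`); V(x) = (x−x*)ᵀP(x−x*) and
dV/dt = 2(x−x*)ᵀP f(x) are evaluated on a lattice (default 401×401). The
level c* is taken directly as the minimum of V over lattice points with
dV/dt ≥ 0 (excluding the equilibrium itself), shrunk by a 1e-6 relative
margin — the exact quantity a bisection on c converges to. Sublevel sets are
intersected with [0,1]². The estimate is sound (every Ω point flows to the
equilibrium; verified by simulation in tests) but conservative, especially
for the endemic attractor of the information-diffusion pair, as is typical
of linearisation-based Lyapunov candidates.

**Separatrix.** When the interior equilibrium between two attractors is a
saddle — as it is for the information-diffusion pair at τ=3, ζ=ξ=1, where
the Jacobian at (1/3, 1/2) has determinant −2/9 — the dividing curve is its
stable manifold, computed by backward integration from ±1e-6 along the
stable eigenvector (LSODA, rtol 1e-10), stopped at the boundary of the
square. A column-wise bisection on initial conditions (to 1e-6) is also
implemented as a fallback for configurations without a real stable
eigendirection; reports record which method was used.

**Basin maps.** All lattice points are integrated as one stacked ODE system
(RK45, rtol 1e-6) in chunks of 10 time units; after each chunk, points
within 1e-6 of an attractor are labelled and frozen. Batch integration is
what makes 201×201 lattices take seconds; correctness is unaffected because
the dynamics are non-stiff at O(1) rates and (by the Dulac argument) every
orbit converges to an equilibrium. Unresolved points at the default horizon
of 500 time units keep a sentinel label, never a forced one.

**Entry-exit map.** The generalized integrand is (τz−1)/g₀(z) with g₀ the
reduced slow flow on the disease-free branch; the classical constant-creation
case is the specialisation f_br(0)=0, f_cr(0)>0, for which the closed-form
antiderivative (−τz − (τ−1)log(1−z))/(ξ f_cr(0)) is used. Otherwise the
cumulative integral is computed by adaptive quadrature on [z_in, 1−1e-12]
(the integrand diverges at z→1, which is exactly why z_out < 1). The root is
bracketed on (1/τ, 1) and refined by Brent to 1e-13. The map requires the
slow flow to be strictly positive on [z_in, 1); otherwise the orbit is not
transported past the stability exchange and an error is raised. The
generalization beyond the constant-creation case follows the entry-exit
literature and is an extension of the worked example, flagged as such here.

**Slow-fast simulation.** The slow-network system substitutes ζ → ζε,
ξ → ε — the literal substitution from the source analysis, so ξ is absorbed
into ε and ζ remains the only free slow rate (the asymmetry is intentional
and documented). Integration uses per-component absolute tolerances with
atol_y = 1e-30: during the dormant phase the prevalence is exponentially
small (~e^{−c/ε}) and must be tracked in magnitude for the delayed
re-eruption to occur at the correct link density. The "neighbourhood of
y = 0" used to compare simulations with the asymptotic map is the
configurable threshold y = 0.01 (0.02 for the ε-refinement comparison, where
entry from z(0) = 0.02 gives crossings at every ε tested); the threshold
choice is recorded in outputs.

## What the built-in examples exercise

The four built-in pairs are analytic benchmarks, each with closed-form
equilibria kept in `animfa.fixtures` (independent of the numerical root
finder): RLAD reduces to a logistic epidemic over a decoupled network
(growth rate τ/(1+ω) − 1, steady prevalence 1 − (1+ω)/τ — note the growth
rate is the value that actually solves the fixed-z logistic ODE);
linear-breaking and adaptive-SIS have a unique globally stable endemic state
above R₀ = 1; information-diffusion has a fold at
τ* = (ω+2+√(8ω))/2 and bistability above it. Passing tests on these pairs
demonstrates correctness of the machinery on smooth low-order polynomial
responses; they do not probe responses with fine-scale structure, cusps, or
behaviour concentrated near the boundary, which are the known limitations of
the fixed scan density and lattice resolutions.

## Problem sizes used in the test suite

Dulac grids 201×201; basin map 201×201 with horizon 500; ROA lattices
101×101 with every Ω point re-simulated; 150 random supercritical parameter
draws for the existence property; slow-fast runs at ε ∈ {0.05, 0.02, 0.01}.
These sizes resolve all the qualitative features (basins, separatrix, fold
thresholds) while keeping the default suite fast.

## Known limitations

- Root scanning can miss structure finer than the 2001-point grid for
  adversarial user-supplied responses (mitigated, not eliminated, by the
  extremum refinement).
- Lyapunov ROA estimates are conservative by construction; they are inner
  bounds, not approximations, of basins.
- The degenerate DFE family (both responses vanishing at 0) carries no
  stability label; trajectory-based statements use the initial condition's
  own z.
- No stochastic or network-level simulation, no delay terms, and no
  fast-network (opposite) time-scale decomposition.
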