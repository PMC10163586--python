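# animfa

Phase-plane analysis toolkit for a minimal adaptive-network SIS model: an
epidemic (or rumour, or any SIS-type spreading process) whose contact network
reacts to the current prevalence by breaking and creating links.

## The model

Two coupled ODEs describe the prevalence *y* (fraction infected) and the link
density *z* (fraction of realized contacts), after rescaling time by the
curing rate:

    dy/dt = −y + τ y (1 − y) z
    dz/dt = −ζ z f_br(y) + ξ (1 − z) f_cr(y)

with effective infection rate τ, link-breaking rate ζ, link-creation rate ξ
(effective ratio ω = ζ/ξ), and two non-negative *functional responses*
f_br(y), f_cr(y) encoding how risk perception reshapes the network. The unit
square [0,1]² is forward invariant.

The package implements, for arbitrary (built-in or user-supplied) responses:

- **Simulation** — stiffness-capable adaptive integration with convergence
  detection and forward-invariance safeguards.
- **Equilibria & stability** — the disease-free equilibrium (DFE)
  z₀ = f_cr(0)/(ω f_br(0)+f_cr(0)), all endemic equilibria as roots of
  ω f_br(y) = (τ−1−τy) f_cr(y) with z = 1/(τ(1−y)), Jacobian eigenvalues and
  node/spiral/saddle/undetermined labels.
- **Basic reproduction number** — next-generation formula
  R₀ = τ f_cr(0)/(ω f_br(0)+f_cr(0)) when f_cr(0) > 0, with an automatic
  fallback that locates the critical τ where endemic equilibria are born
  (fold) by bisection on the root count.
- **Global analysis** — limit-cycle exclusion via the Bendixson–Dulac
  multiplier 1/(yz) (F = −τ − ξ f_cr(y)/(y z²) < 0 on the open square),
  quadratic-Lyapunov region-of-attraction estimates (P J + JᵀP = −I), basin
  maps, and separatrices by stable-manifold shooting or bisection.
- **Slow network dynamics** — critical manifold {y=0} ∪ {y=(τz−1)/(τz)},
  layer-problem stability, reduced slow flow, and the entry-exit map
  ∫(τz−1)/g₀(z) dz = 0 describing delayed re-eruption of the epidemic after
  a dormant phase.

Four named response pairs are built in: `rlad` (density independent of the
disease), `linear_breaking` (f_br = y, f_cr = 1), `asis` (adaptive SIS:
2y(1−y), (1−y)²) and `aid` (adaptive information diffusion: (1−y)², 2y(1−y)).

## Worked example

The information-diffusion pair at τ = 3, ζ = ξ = 1 is bistable:

```
$ animfa equilibria --config aid.yaml
dfe         (0, 0)                   stable_node
endemic     (0.333333, 0.5)          saddle
endemic     (0.5, 0.666667)          stable_node

$ animfa r0 --config aid.yaml
tau* = 2.914214 (method=threshold, R0-equivalent tau/tau* = 1.029437)

$ animfa simulate --config aid.yaml --y0 0.5 --z0 0.9
terminal state (0.5, 0.666667) [converged:endemic(0.5,0.666667)]
```

with `aid.yaml`:

```yaml
parameters: {tau: 3.0, zeta: 1.0, xi: 1.0}
responses:  {builtin: aid}
analysis:   {horizon: 200.0}
output:     {dir: out}
seed: 0
```

Reading: the news-free state (0, 0) is always stable here, since link
creation shuts down when nobody knows the rumour (f_cr(0) = 0). Above the
fold threshold τ* = (ω + 2 + √(8ω))/2 ≈ 2.914 two endemic states appear; the
saddle at (1/3, 1/2) organises the boundary between the two basins, and the
run started at (0.5, 0.9) settles on the endemic state (1/2, 2/3). Because
the next-generation formula does not apply when f_cr(0) = 0, the `r0`
command falls back to the fold threshold: it reports τ* and the equivalent
threshold measure τ/τ* ≈ 1.03 > 1.

The same library surface is importable (`import animfa`); the CLI subcommands
`simulate`, `equilibria`, `r0`, `threshold`, `basins`, `roa`, `slowfast`,
`report` and `fixtures` write CSV/JSON artifacts.

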