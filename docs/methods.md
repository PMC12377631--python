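# Methods

## The model

Two populations compete for space and resources: tumor cells `x` and
host (healthy) cells `y`, both in cells or interchangeably in cm³ of
tumor volume. Each grows logistically and inhibits the other:

    dx/dt = rx x (1 − x/Kx) − αxy x y
    dy/dt = ry y (1 − y/Ky) − αyx x y

with growth rates `rx, ry` (per day), carrying capacities `Kx, Ky`,
and interaction coefficients `αxy, αyx` (per day per cell). The
interaction can be decomposed as `αxy = δxy + rx γ/K` with
`γ = Ky/Kx`: a pure kill rate plus the shared-capacity term. When the
kill coefficients are non-negative this implies the bound
`αxy ≥ rx/Kx` (enforced only by `KineticParams.validate_strict`,
because several of the benchmark parameter sets violate it — see
"Numerical and design choices").

Rescaling `τ = rx t`, `x = Kx u`, `y = (rx Ky/ry) v` gives

    u̇ = u − u² − c u v,     v̇ = d v − v² − f u v

with `c = Ky αxy/ry`, `d = ry/rx`, `f = Kx αyx/rx`. The triple
`(c, d, f)` fully determines the dynamics.

### Regimes

The fixed points are P1 = (0,0), P2 = (0,d), P3 = (1,0) and, when
`cf ≠ 1`, P4 = ((1−cd)/(1−cf), (d−f)/(1−cf)). Eigenvalues are always
computed numerically from the analytic Jacobian

    J(u,v) = [[1−2u−cv, −cu], [−fv, d−2v−fu]]

rather than from closed-form per-point expressions. The sign pattern
of `(cd−1, f−d)` classifies the regime:

| Regime | Conditions | Attractor | Clinical reading |
|---|---|---|---|
| I | cd>1, f<d | P2 | tumor eliminated by the host |
| II | cd<1, f<d (⇒ cf<1) | P4 | stable coexistence |
| III | cd>1, f>d (⇒ cf>1) | P2 or P3 | bistable, split by the separatrix |
| IV | cd<1, f>d | P3 | tumor dominance |

Parameters within 1e-12 of a boundary manifold are labelled
DEGENERATE instead of silently picking a side.

A Dulac function `R = u^m v^n` with `m = (cf+f−2)/(1−cf)`,
`n = (cf+c−2)/(1−cf)` makes the divergence of the rescaled field
proportional to `κ = (cd−1+f−d)/(1−cf)`; whenever `κ ≠ 0` there are
no closed orbits in the open quadrant, so every trajectory ends at a
fixed point. The certificate is inconclusive exactly on the manifold
`cd−1 = d−f`, which the report flags.

### Separatrix

In Regime III the stable manifold of the saddle P4 divides the basins
of P2 and P3. It is grown by integrating the field backward in time
from `P4 ± ε e_s` (ε = 1e-6 along the stable eigenvector), with a
tight tolerance (rtol 1e-10) and a stopping box `[0, 5]²`; the points
are returned ordered along the curve through P4.

### Potential analogy

Eliminating `v` reduces the unperturbed tumor equation to a particle
in a quartic potential `V(u)` with
`−dV/du = (1/c−d)u + (d+f−2/c)u² + (1/c−f)u³`, normalized by
`V(0) = 0` (only derivatives matter). Its extrema are found in closed
form — `dV/du = u·a(u−1)(u−u₃)` with `u₃ = (1−cd)/(1−cf)` — not by
iterative root-finding. Each extremum is classified by the sign of
the actual curvature there: at `u=0` it is `(cd−1)/c`, at `u=1` it is
`f−d`, and at `u₃` its sign equals that of `(cd−1)(d−f)/(cf−1)`. The
characteristic angular frequency at a minimum is `Ω = sqrt(V'')`; at
`u* = 1` this is `Ω = sqrt(f−d)` (≈ 0.663 dimensionless, i.e.
`rx·Ω ≈ 0.066`/day, for the aggressive-tumor benchmark). `Ω` sets the
frequency scale a near-resonant periodic therapy should target.

## Therapies

`TherapySpec.mode` makes the unit duality of the effect coefficients
explicit rather than overloading one field:

- **proportional_constant** — kills `D βx x` and `D βy y` cells/day
  (βs are per-day rates). Equivalent to rescaling `rx → rx − D βx`,
  `ry → ry − D βy` (capacities rescale along). Only
  `d*(D) = (ry−Dβy)/(rx−Dβx)` moves; therapy is *effective* iff
  `ry βx − rx βy > 0`. Crossing
  `D1 = ry(rx−Ky αxy)/(ry βx − βy Ky αxy)` flips `c d* > 1`, crossing
  `D2 = rx(Kx αyx−ry)/(βx Kx αyx − rx βy)` flips `d* > f`; doses above
  `rx/βx` (`ry/βy`) drive the tumor (host) extinct outright. The
  planner implements the per-regime decision lists and flags that the
  system relapses to baseline if therapy is withdrawn before the
  tumor crosses a practical elimination floor.
- **additive_constant** — host-directed stimulation: `βx = 0`,
  `βy < 0`, adding `A = −D βy ry/(rx² Ky) > 0` to the dimensionless
  host equation. The forced system has boundary equilibria
  `Q1,2 = (0, (d ∓ √(d²+4A))/2)` (Q1 always unstable; Q2 stable for
  `A > A1 = (1−cd)/c²`) and an interior pair Q3/Q4 from
  `(cf−1)v² + (d−f)v + A = 0`, real while
  `Δ = (f−d)² − 4A(cf−1) ≥ 0`. For `cf > 1` the pair collides in a
  saddle-node at `A2 = (f−d)²/(4(cf−1))`; the collided point is
  reported once under the tag `Q3=Q4` and carries a zero eigenvalue.
  Non-physical equilibria are retained with `physical=False` because
  the outcome logic reasons about their signs. Dose thresholds D1/D2
  satisfy `A(Di) = Ai` identically; outcome labels carry a star (I*,
  II*, III*) to distinguish perturbed-system regimes. Because
  `(x, 0)` is never an equilibrium of the forced system, the host
  cannot vanish under this therapy.
- **periodic_additive** — dose `D(t) = D(1 − cos ωt)`, non-negative
  with mean `D` over a period, applied to the host only.

## Stroboscopic analysis

The forced system is sampled once per forcing period `T = 2π/ω` after
a transient of `max(50 periods, min_transient_time)` — the transient
must outlast the slowest contraction rate toward the attractor (for
the benchmark in original time, ~0.017/day, hence the 1200-day
default used in the analyses). Convergence of the k-fold strobe map
(k ≤ 8, tolerance 1e-7) detects period-k orbits; the within-period
excursion of each population, relative to its carrying capacity,
separates a **period-1 limit cycle** from the **small-loop
attractor** at a floor of 1e-3. The floor sits between the visible
cycle at ω = 6/day (relative excursion ≈ 8e-3) and the shrunken
high-frequency attractor at ω = 60/day (≈ 8e-4), which is the
qualitative distinction the classification must reproduce; a smaller
floor would label the high-frequency attractor a limit cycle.
Integration caps the step at T/20 so the forcing is always resolved.

## Lyapunov exponents

The spectrum of the forced dimensionless system uses tangent-space
renormalization: the reference trajectory and two tangent vectors of
the variational system `ẇ = J(u(τ), v(τ)) w` are integrated with a
hand-coded fixed-step classical RK4 (defaults h = 0.02, matching the
renormalization interval τ_r = 0.1 exactly). Every τ_r the leading
vector's stretch `d_k` is recorded and the vector reset to unit norm;
the second exponent uses the Gram-Schmidt complement. The running
estimate is `σ_n = (1/(n τ_r)) Σ ln d_k`. Resetting to unit norm
makes the estimate independent of the initial tangent scale `d₀`
(kept as a settings field for completeness, default 1). Convergence
is declared when σ_n drifts less than 1e-3 over the last quartile of
the run; 40 000 renormalizations (τ = 4000) are used at the reported
search optimum, 12 000–15 000 for parameter sweeps. Halving τ_r moves
the converged exponents by < 1e-6 at the optimum.

Correctness anchors: (i) at a fixed point the scheme returns the
Jacobian eigenvalues exactly (constant stretch); (ii) for a
trajectory attracted to a stable node the spectrum converges to the
node's eigenvalues; (iii) the exponent sum matches the time-averaged
divergence of the field (dissipativity).

The Monte-Carlo search over `(c, d, f, A, ω)` spends half its budget
on uniform draws from the box `c∈[0.5,2], d,f∈[0.5,1.5], A∈[0,0.5],
ω∈[0.05,5]` and the rest on Gaussian proposals shrinking around the
incumbent; it is bit-reproducible for a fixed seed. At the reported
optimum `(0.933816, 0.999086, 1.27836, 0.100613, 0.496117)` the
spectrum converges to ≈ (−0.0177, −1.185): negative but close to
zero, consistent with the forcing amplitude sitting just below the
saddle-node value A2 ≈ 0.10064 for that triple — the maximum of the
exponent rides the bifurcation, which also explains the kink in the
one-at-a-time sweeps.

## Growth-curve fitting

Only the tumor component is observed (`V(t) ∝ x(t)`; the host is
latent), so the objective is unweighted linear-scale least squares
`Σ (x(t_i; θ) − V_i)²` over
θ = (rx, ry, αxy, αyx, Kx, Ky, x0, y0), with bounds rates ∈
[1e-3, 20]/day, capacities ∈ [0.1, 20] cm³, interactions ∈ [0, 20].
The landscape is rugged with narrow global basins, so the optimizer
is a portfolio: a closed-form logistic pre-fit (itself multi-started
across decades of growth rate) seeds three full-model starts
(host-inert, half-coupled, strongly coupled), Latin-hypercube draws
fill the remaining start budget, each start runs bounded
trust-region-reflective least squares, and the winner is re-polished
with a coarser finite-difference step (1e-5) that clears the
ODE-solver noise floor. Everything is deterministic for a fixed seed.

Identifiability is reported, not assumed: the fit is flagged
rank-deficient when the smallest singular value of the final Jacobian
falls below 1e-5 of the largest (directions weaker than that are not
informed by the data at the solver's noise level). In practice even
noiseless fits of this model are rank-deficient — combinations like
`αxy ≈ rx/Kx` make the host term mimic self-limitation — so recovery
is asserted at the *curve* level with the symmetric Hausdorff
distance on `(t, V)` points in natural units (no rescaling), computed
via the standard directed-distance routine. A generic second-curve
slot allows comparison against any other growth model's curve.

## Synthetic data

The generator replaces the experimental inputs the analysis would
normally consume (Ehrlich carcinoma volumes in mice: growth from
≈ 0.5 cm³ toward a 2–3 cm³ plateau over ~30 days):

- `fixtures()` ships the benchmark parameter sets (one per regime,
  the forced aggressive-tumor scenario, the Lyapunov search optimum,
  and the reference fitted octet). The Regime-III kinetic set is
  internally inconsistent with its dimensionless triple (it yields
  c ≈ 0.38, not 1.65) and is shipped with an explicit
  `kinetics_inconsistent` flag; analyses use the triple directly.
- `generate_volume_series` simulates `x(t)` and applies
  multiplicative log-normal noise with σ = 0.05 by default — tumor
  volume measurement error scales with size, and σ is then the
  per-point coefficient of variation (verified to ±0.005 over 1000
  replicates). Default sampling is 12 points over 30 days; the
  parameter-recovery experiments use a denser 121-point grid over the
  same horizon so the curve is constrained through its rise.
- `generate_scenario_suite` rejection-samples regime-labelled
  `(c, d, f)` triples (covering both `cf` subcases of Regime IV) with
  effective/ineffective therapy coefficient draws for planner tests.

What the synthetic data do not emulate: measurement-schedule
irregularity, inter-animal variability of the kinetic parameters, the
detection floor of caliper measurements, and any real host-cell
readout. Passing tests therefore demonstrate internal consistency of
the pipeline under the model's own assumptions, not validity of the
model for real tumors.

## Numerical and design choices

- Trajectory integration: adaptive explicit RK (scipy `solve_ivp`,
  RK45), rtol 1e-8 / atol 1e-10 defaults, configurable. Negative
  undershoot is not clipped; quadrant invariance is asserted only to
  solver tolerance.
- The capacity-simplex bound `x + γy ≤ K` is an invariant only when
  the interactions contain the shared-capacity term (strict-mode
  parameters); several benchmark sets violate the `αxy ≥ rx/Kx`
  bound, so the boundedness test uses a strict-mode-compliant set.
- Eq-form ambiguities are resolved toward the Jacobian and the
  nullcline solution for P4; printed per-point eigenvalue formulas
  serve only as cross-checks.
- Problem sizes in tests and the acceptance script (transients,
  renormalization counts, sample grids) are chosen as the smallest
  that leave a comfortable margin over the quantity's convergence
  scale, and are stated where used.

## Known limitations

- Two species only; no spatial structure, no treatment scheduling
  beyond the three modes, no pharmacokinetics mapping a drug
  concentration to the relative dose D.
- The second-order "particle in a viscous medium" form is used only
  for the unperturbed potential and Ω; forced dynamics are always
  simulated in first-order form.
- Chaos is excluded only numerically (negative maximum exponent over
  the searched region), not proven.
- The comparison growth model used in the original Ehrlich validation
  is not reimplemented here; its printed Hausdorff distance to the
  fitted curve is therefore not a reproducible target, and the
  fitting analysis validates curve recovery on synthetic data
  instead.
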