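# Methods

## Model

A network of `n` dependent and `m` independent metabolites coupled by `p`
processes is modeled with Generalized Mass Action (GMA) kinetics: process
rates are power laws `v_r = γ_r Π_j X_j^{f_rj}` over all `n+m` metabolites
and the mass balances are `Ẋ_i = Σ_r μ_ir v_r`. The kinetic order `f_rj` is
the local log-log sensitivity of rate `r` to metabolite `j`; its sign *is*
the regulatory annotation. Substrate orders are constrained positive;
metabolites outside a reaction's substrate/candidate-modifier sets have
orders fixed at zero. Independent metabolites are held at constant
concentration (1.0 by default) so their factors are absorbed into the rate
constants. Concentrations and times are unitless model units.

Power laws are undefined at zero concentration, so states carry a positivity
floor (1e-9 in simulation, 1e-6 inside the algebraic solver). Crossing the
floor during simulation is an error, never a silent clamp: clamping would
corrupt fits with spuriously flat trajectories.

## The benchmark system

The bundled reference is the four-metabolite branched pathway: X1 is
produced from the constant precursor X0 under feedback inhibition by X3
(f13 = −0.8), consumed along X1→X2→X3 and X1→X4; X4 activates X3
degradation (f54 = 0.2). Rate constants are γ = (12, 8, 3, 2, 5, 6) and
substrate orders (f21, f32, f41, f53, f64) = (0.5, 0.75, 0.5, 0.5, 0.8).

The in-silico experiment design is only partially documented in the
benchmark literature, so the generator fixes the open values as package
defaults:

- initial state (0.5, 0.5, 1.2, 0.5), with X3(0) the perturbed species
  (the printed perturbation set is {0.2, 1.2, 2.2} and 1.2 is its middle);
- horizon [0, 10], long enough for the post-perturbation transient to
  settle;
- 20 equispaced sampling times, endpoints included. This count is
  calibrated against the benchmark's printed residuals rather than chosen
  freely: with multiplicative Gaussian noise of relative SD σ the expected
  noise-only residual is σ²·ΣX², and with 20×4 points (ΣX² ≈ 187 under the
  defaults above) that gives ≈1.9 at σ = 10% and ≈4.7e-3 at σ = 0.5%,
  matching the reported single-experiment residuals (1.67–2.29 and
  0.0041–0.0057) as well as the three-experiment values. A 50-point design
  would put every noise level a factor ≈2.5 above the reported numbers.

Noise is multiplicative Gaussian, `X^exp = X^true·(1 + N(0, σ))`, applied
independently per point; non-positive draws are rejected and resampled
(rather than truncated) to keep strict positivity without a point mass at a
floor. Replicate `i` of a batch uses seed `base_seed + i`, so replicate 0
reproduces the single-experiment generator exactly and any experiment can be
regenerated bit-for-bit from its recorded seed.

What the generator does *not* emulate: measurement-correlated noise,
missing observations, unobserved species, and model mismatch (the fitted
model class always contains the generator). Passing tests therefore
demonstrate correctness of the machinery and behavior under the stated
noise model, not robustness to real experimental artifacts.

## Collocation transcription

The dynamic least-squares problem is transcribed into an algebraic system by
orthogonal collocation on finite elements. Within each element the state is
the Lagrange polynomial through the element's start value and K collocation
points; the GMA right-hand side is enforced at the collocation points, and
continuity ties consecutive elements. Model values at sampling times are
read from the element interpolant, which decouples the mesh from the data
grid. Radau points (right endpoint included; stable for stiff kinetics) are
the default; Gauss-Legendre points are available.

Default mesh: **20 elements × 4 Radau points with geometric grading 1.15**
(consecutive element lengths grow by 15%, concentrating resolution near
t = 0). The grading matters: the benchmark's perturbation experiments have
a fast initial transient, and an equispaced mesh of practical size leaves a
transcription bias orders of magnitude above the noise-free residuals the
fit should reach. Under the default mesh the transcribed trajectories agree
with an adaptive high-accuracy integrator (LSODA, rtol 1e-10) to better
than 1e-4 relative at all sampling times for every X3 perturbation, leaving
a noise-free residual floor ≈2e-7.

### Reduced-space solution

Because each element's collocation equations couple to the previous element
only through continuity, the full algebraic system is block-triangular and
can be solved *exactly* by marching: a damped Newton iteration per element
(tolerance 1e-12 on the residual norm). The estimation NLP is therefore
solved in reduced space — states are eliminated by the march, and only the
kinetic parameters are exposed to a bounded trust-region least-squares
solver. The residual Jacobian is exact: forward sensitivities of all node
states are obtained from the implicit-function theorem, reusing each
element's Newton factorization. This solves the same transcription as a
simultaneous NLP while keeping the optimizer's search space at 13–25
dimensions; the `TranscribedProblem` object still exposes the full-space
residuals, which the test suite uses to verify that solutions satisfy every
collocation and continuity constraint.

Failed integrations inside the optimizer (divergent dynamics at a trial
point) return a large constant residual, which the trust region rejects;
a start whose dynamics diverge on the horizon is first repaired by damping
the rate constants tenfold until the march succeeds.

## Estimation

- Bounds: kinetic orders in [−1, 1] (fitted orders in the benchmark
  saturate at 1, implying unit bounds), substrate orders ≥ 1e-3, rate
  constants in [1e-3, 50].
- Residuals are plain unweighted squared differences; no normalization.
- Multistart: start 0 is a deterministic default (γ = 1, orders
  mid-interval), further starts are uniform draws within bounds from a
  seeded generator. Ties within 1e-10 resolve to the lowest start index, so
  a fixed seed gives a bit-reproducible result. Starts that hit the
  evaluation cap count as non-converged and are used only if nothing
  converged.
- Profile sweeps (`profile_parameter`) fix one parameter, refit the rest,
  and warm-start consecutive values from the previous optimum.
- Initialization helpers mirror standard dynamic-optimization practice:
  `simulate_then_seed` integrates the ODE at a guess and samples it onto
  the collocation grid; `feasibility_restore` produces a point satisfying
  all collocation constraints (the exact march drives the constraint slack
  to zero whenever it converges) and reports — rather than raises —
  contradictory sign bounds.

## Topology search

Each candidate (reaction, metabolite) pair carries a ternary sign with
indicator binaries (y⁻, y, y⁺), exactly one active. The big-M rows

```
f ≤ −ε + M(1−y⁻),   −ε − M(1−y) ≤ f ≤ ε + M(1−y),   f ≥ ε − M(1−y⁺)
```

with ε = 1e-3 and M = (f_hi − f_lo) + 1 = 3 are equivalent, branch by
branch, to the sign intervals [f_lo, −ε] / {0} / [ε, f_hi] — the
equivalence is grid-verified in the tests. For the benchmark the full
encoding declares 3 × 6 × 4 = 72 indicator binaries. The AIC penalty counts
active kinetic-order indicators only (substrates included; rate constants
are always estimated and never penalized), `k` is the total residual count,
and the additive constant is set to zero, so AIC values are comparable only
within a run. The residual is floored at 1e-12 before the logarithm.

The solver is a nonlinear branch-and-bound over the sign triples:

- a node fixes a subset of signs; its bound is the AIC of a relaxed NLP in
  which undecided orders range over the full [f_lo, f_hi], plus 2 per
  already-active order;
- branching picks the undecided pair whose relaxed order lies farthest from
  the ±ε boundaries (lexicographic tie-break); best-bound node order;
- at every node a rounding heuristic thresholds the relaxed solution
  (keeping at most the allowed number of modifiers per reaction, largest
  magnitudes first) and fits the resulting fixed pattern, warm-started from
  the relaxed parameters, to supply incumbents early;
- a cardinality limit (default: one modifier per reaction beyond the
  substrate) is enforced by propagation — once a reaction is saturated its
  remaining candidates are fixed to zero;
- alternative topologies are enumerated by re-solving under no-good integer
  cuts; since cuts exclude only complete assignments, all node relaxations
  and leaf fits are cached and reused across iterations;
- node solves run under a deliberately cheap evaluation cap with a coarser
  mesh (12 elements × 3 points, grading 1.2 — its transcription bias is far
  below the noise level that dominates identification); every returned
  topology is then re-fitted to full convergence before reporting.

All node solves are local, so bounds are heuristic — as with any local
mixed-integer strategy, global optimality is not claimed. The search also
honors an explicit node budget (default 400 relaxation/fit evaluations per
solve; the bundled identification runs use 40) and returns the best
incumbent when the budget is exhausted. Because per-iteration AIC
monotonicity cannot be guaranteed with local solves, the final ranking is
sorted by AIC. On a two-reaction toy network with 15 admissible sign
assignments the iterative enumeration reproduces exhaustive brute-force
enumeration (per-assignment NLP, AIC order) exactly; this equivalence is a
standing test.

A one-shot `relax_and_round` strategy (solve the root relaxation, threshold,
fit) is available as a cheap alternative.

## Numerical choices and degenerate inputs

- Newton damping keeps element states above 1e-6; a non-convergent element
  raises rather than returning garbage.
- Default fit tolerances: ftol 1e-14, xtol 1e-12, gtol 1e-10, 3000
  evaluations; search-internal solves use ftol 1e-9 and a 120-evaluation
  cap with unit parameter scaling (terminal precision there only needs to
  resolve AIC differences ≥ 2).
- An empty sign interval (e.g. a substrate lower bound above the global
  upper bound) is reported as an infeasible pattern, not a solver crash.
- rss = 0 is rejected by `aic` (callers floor it), and `BigMConfig`
  validates ε > 0 and M > ε.

## Problem sizes used in the bundled runs

Noise-free recovery and the f32 sweep run on one 20-point experiment with
the default mesh (10 and 5 multistarts respectively). Identification runs
use 5 topologies, 2 leaf starts, and a 40-node budget per solve; the
three-experiment variant fits all three perturbations jointly (shared
parameters, per-experiment state blocks). These sizes reproduce the
benchmark's qualitative behavior in minutes on a single CPU.

## Known limitations

- Local optimization throughout; multistart mitigates but does not remove
  multimodality. Deterministic global methods are out of scope.
- The AIC bound of a node uses a locally solved relaxation; an optimistic
  local optimum can in principle prune the true optimum.
- The in-silico design (initial state, horizon, grid) fixes values the
  benchmark literature leaves unstated; residual-magnitude comparisons
  against reported figures are calibrated (see above) but inherently
  approximate, and at 0.5% noise the per-realization noise floor
  (σ²·ΣX² ≈ 4.7e-3 in expectation) bounds from below the residuals any
  search can reach on a given draw.
- No weighted or robust losses; no confidence intervals; no SBML import;
  no mechanistic (saturable) rate laws.
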