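# Methods

## Model and central assumption

A network consists of input elements (species with prescribed time
profiles), gene elements and bi-molecular reaction elements.  The engine
assumes that changes in molecule numbers are small within one
synchronization interval Δt, so that every element can be advanced in
isolation with the abundances and fluxes of all other elements frozen at
the previous synchronization point.  After each interval the species
abundances are updated from the elements' reported outputs and the summed
fluxes.  Elements never see intra-step updates of other elements, so the
trajectory is independent of the order in which elements are evaluated
within a step; this is verified by a test.  Fluxes computed during step
*q* act during step *q+1* (one-step lag) — they are genuinely unknown
until the elements have been advanced.

Splitting is first order in Δt: transients converge to the network-wide
ODE solution as Δt shrinks, while fixed points of the per-element maps are
fixed points of the global dynamics, so steady states are exact at any Δt
(for genes and for reaction elements; both are tested).  Two runtime
warnings flag step sizes that violate the underlying assumption: a gene
warning when the expected per-step production p_on·ν·Δt reaches 1, and a
flux warning when the change in a reaction's reported flux across a step,
|Δj|·Δt, reaches 1.

## Promoters

Each promoter is summarized by an effective telegraph (two-state) model.
With per-site on-rates λᵢ = λ₀ᵢ·n_TFᵢ (mass-action arrival) and off-rates
µᵢ:

* single activator: λ_eff = λ₀·n_TF, µ_eff = µ;
* AND logic: µ_eff = Σµᵢ, p_on = Π λᵢ/(λᵢ+µᵢ), λ_eff = p_on/(1−p_on)·µ_eff;
* OR logic: λ_eff = Σλᵢ, p_on = 1 − Π(1−p_on,i), µ_eff = λ_eff(1−p_on)/p_on;
* competitive repression rescales λ_eff by Π(1+K_R,i)⁻¹ with
  K_R = λ_R·n_R/µ_R, leaving µ_eff unchanged: a repressor blocks
  activation but does not abort an ongoing on-period.  Multiple repressors
  combine multiplicatively.

The stationary p_on of these effective models equals the stationary
on-probability of the exact multi-site promoter Markov chain (verified
against matrix null spaces for 2- and 3-site promoters and the 3-state
repressed/free/active chain); the two-state reduction approximates only
the *kinetics* of multi-site promoters.

Edge conventions: an OR promoter whose activators are all absent returns
λ_eff = 0 with µ_eff = Σµᵢ (the gene simply never activates).  A gene with
no activator sites is constitutive: with repressors it becomes the exact
free/blocked telegraph (λ_eff = µ_R, µ_eff = λ_R·n_R for one repressor),
without them its activity is pinned at 1.  TF copy numbers at promoters
are totals; sequestration of TFs by promoter binding is neglected, which
matters only at single-digit copy numbers.

## Gene dynamics

Scenario 1 advances the product by the exact solution of
dn/dt = p_on·ν − δ·n with p_on evaluated from the frozen levels.
Scenario 2 realizes promoter switching as exponential waiting times
(re-drawn at each step start from the current rates, valid by
memorylessness since rates are constant within a step) and propagates the
product deterministically per realized on/off interval.  Scenario 3
additionally draws, per on-interval, a Poisson number of births with mean
ν·τ_on, applies the deterministic decay of the pre-existing molecules
(stochastically rounded, floor plus Bernoulli, to keep counts integer with
the exact mean) and, per off-interval, a binomial survivor count with
probability e^(−δτ).  Degradation during on-intervals is deliberately
deterministic; the scheme therefore undercounts death noise in proportion
to the on-fraction, a bias that is negligible when on-periods are short
relative to off-periods (the common case for bursty genes) and visible for
permanently active genes, whose Fano factor approaches 1/2 rather than 1.
Tests assert the scheme's own properties and its agreement with exact
simulation in the bursty regimes, not the idealized Poisson limit.

Rate-limiting production stages β₁..β_N form the linear cascade
dc₁/dt = a·ν − β₁c₁, dcᵢ/dt = βᵢ₋₁cᵢ₋₁ − βᵢcᵢ, with the mature product as
final stage decaying at δ.  The cascade is always advanced
deterministically, by the exact matrix-exponential propagator per
piecewise-constant activity interval (cached per interval length); this is
equivalent to the partial-fraction convolution solution, which is also
provided (with its coefficients αᵢ = Πβₙ / Πₙ≠ᵢ(βₙ−βᵢ), defined for
pairwise-distinct rates; near-equal rates are rejected with advice to
perturb by ~10⁻⁶).  In scenario 3 the intermediate stages remain
deterministic and the output stage is stochastic: births are Poisson with
mean given by the trapezoidal integral of the last intermediate stage's
outflow, survival is binomial.  Fixed delays shift the *reported* output
by m synchronization steps through a ring buffer, so delays are multiples
of Δt.

## Reaction elements

With totals and complex inflow frozen, every bi-molecular element reduces
to the scalar ODE df/dt = λ(N₁−f)(N₂−f) − (δ₁+δ₂+µ)f + j_in whose fixed
points f₁ ≤ f₂ are the roots of the quadratic expansion (f₁ stable) and
whose solution is f(t) = f₁ + (f₂−f₁)·u/(1+u),
u = (f₀−f₁)/(f₂−f₀)·e^(−λ(f₂−f₁)t); a near-double root
(relative gap < 10⁻⁹) uses the exact algebraic limit
f₁ + (f₀−f₁)/(1+λ(f₀−f₁)t).  The time-averaged occupancy f̄ has a closed
form, giving closed-form consumed amounts Δf + δᵢ·f̄·Δt per substrate.
Homo-dimerization maps onto this solution via λ→4λ, N₁=N₂=N/2 (the
external inflow j_in is *not* rescaled — direct integration of the
homodimer rate law fixes this, and a test pins it); monomer fluxes are
doubled.  Enzymatic turnover substitutes δ₁→δ₁+ν for the complex and
advances the product by m(Δt) = m₀e^(−δ₃Δt) + (ν·f̄+j_in)/δ₃·(1−e^(−δ₃Δt)),
with the exact linear-growth limit at δ₃ = 0.

Bookkeeping conventions differ by element kind.  Dimer elements treat
their substrate columns as free pools (clamped inputs buffer their *free*
abundance) and report the net association flux.
Enzyme elements treat substrate and enzyme columns as *totals* (the
complex is internal bookkeeping): association merely relabels, only
catalysis (ν·f̄) consumes substrate, and in-complex substrate degradation
is covered by the owner's degradation acting on the total.  This is what
makes the steady state of coupled enzyme elements exactly Δt-independent;
free pools are recovered as total minus complex.  A closed, mass-conserving
reaction cycle retains a one-off in-flight offset from the flux lag in its
conserved total, so the shipped two-enzyme loop is driven by a constitutive
source gene with slow decay — an open system whose steady state the offset
cannot shift.

## Reference oracles

The Gillespie implementation is an independent direct-method simulator
over mass-action reactions with explicit promoter states (three-state
empty/activator-bound/repressor-bound promoters for the cascade; two-site
four-state promoters for the basally activated positive-feedback loop),
recording on a uniform grid.  `assemble_ode` independently builds the
network-wide mean-field right-hand side (instantaneous p_on, full reaction
rate equations, no freezing) for an adaptive solver.  Neither shares code
with the engine.

## Benchmark systems and parameter regimes

No external datasets are used; all study systems are generated in
`fixtures.py`.  Rate values are package-chosen (per-molecule association
rates in 1/(s·molecule), other rates in 1/s), selected once so the
documented phenomena manifest robustly at tractable simulation lengths:

* **Repressive cascade** (4 genes, shared constitutive activator, each
  link competitively repressed by the previous product).  The *slow*
  regime (λ_eff = 0.012, µ_a = 0.004 vs δ = 0.006) has bursty promoters
  slower than product turnover, but moderate levels (~10–20 molecules) so
  that the discrete birth/death contribution to the variance is measurable
  on top of switching noise.  The *fast* regime (λ_eff = 0.2, µ_a = 1.0 vs
  δ = 0.01) has short on-periods (on-fraction ≈ 0.1), where the
  deterministic-on-death simplification is accurate, and fast repressor
  binding, because the effective two-state reduction drops slow
  repressed-dwell correlations.  Levels are kept at tens of molecules so
  promoter sequestration (absent from the effective model) stays small.
* **Two-enzyme loop**: source gene (ν = 0.08, δ = 10⁻³) feeding
  N ⇄ M cycling by two enzyme pools of 20 and 30 copies.
* **Positive feedback**: self-activating gene (Hill-1 activation via
  K_A = 0.1 per molecule, fast switching) with a weak basal activation
  site and near-Michaelis–Menten enzymatic degradation (K_M ≈ 2,
  V_max = 0.015).  The mean-field system is *monostable* with one fixed
  point at ≈ 17 molecules, so the bimodality is genuinely noise-induced:
  discreteness traps trajectories near zero (with few product molecules
  the promoter rarely activates and occasional basal bursts must re-ignite
  the loop), creating a second mode that continuous scenario-2 dynamics —
  which drift deterministically to the fixed point and, with fast
  switching, stay there — cannot reach.  Scenario 3 and Gillespie are
  bimodal, scenario 2 unimodal.  The basal site is also required for a
  well-defined long-run histogram: without it the empty-promoter,
  zero-product state is absorbing.  Histogram comparisons use the total
  product pool (free + enzyme-bound) on both sides.
* **Negative feedback**: constitutive gene blocked by its own product,
  two maturation stages (β = 3·10⁻⁴ each) and near-saturated enzymatic
  degradation put the mean-field system just below a Hopf bifurcation
  (damping ratio ≈ 0.03, period ≈ 15 000 s).  Molecular noise sustains
  oscillations in scenario 3 and Gillespie (spectral peaks within one
  Welch bin of each other); scenario 2's weak switching noise leaves only
  a small residual ripple (tested as: resonance-band power < 1/3 of
  scenario 3's, late fluctuations < 10% of the mean).

Because these systems are synthetic and their parameters package-chosen,
passing tests demonstrate the internal consistency of the method (hybrid
vs exact simulation of *the same* system), not agreement with any
biological measurement.  The generator emulates bursty transcription,
regulatory logic and enzymatic degradation; it does not emulate cell
division, extrinsic noise, measurement noise, or promoter sequestration
effects beyond what the exact oracle includes.

## Inference: design choices

Trainable parameters are per-edge equilibrium constants K = λ/µ (µ fixed
at 1), since steady states carry no kinetic information; production and
degradation rates are held fixed.  Genes use OR-logic activation with
competitive repression, giving the closed form
p_on = (P_a−1)/(P_a−1+P_r) with P_a = (1+K_basal)·Π(1+K_act·xᵢ),
P_r = Π(1+K_rep·xᵢ).  Every gene carries a fixed basal activation constant
(K_basal = 0.1) because a pure OR network of mutually activating genes has
the all-zero state as attractor, which would make knockout data trivial.
Expression scale is ν/δ = 1000 so that K·x = O(1) over the sampled
constant range [10⁻³, 10⁻²] — regulation must move steady states
appreciably for the data to be informative.

Steady states during training iterate the scenario-1 engine update map
(relaxed fixed-point iteration; a damped Newton root solve is the
fallback), with convergence |Fᵢ| < 10⁻⁸·max(1, xᵢ).  Derivative formulas
for the Jacobian L and ∂F/∂K are re-derived from the OR/repression closed
form and validated against central finite differences to < 10⁻⁴ relative
error — the binding specification of the gradient.

The delta rule with a single backtracked step size is provided and tested,
but it is badly conditioned when levels span orders of magnitude, so the
default trainer keeps one adaptive step size per parameter (grown 1.2× on
consistent gradient signs, halved on flips), followed by a
Levenberg–Marquardt polish on the stacked condition residuals.  Constants
are projected to [0, 10] (beyond K = 10 every promoter in the study range
is saturated).  The stopping bound is b = 10⁻¹⁰·ΣT² by default — a
relative loss floor — with the iteration cap as secondary stop.

**Sign priors and identifiability.**  The benchmark trains one constant
per ordered gene pair, with each transcription factor's mode of action
(activator or repressor) taken as prior knowledge; absent pairs are given
an activating edge whose constant must vanish.  This keeps the parameter
count at N(N−1) ≤ N² measurements.  The alternative of instantiating both
roles per pair is implemented (`sign_known=False`) but demonstrably
unidentifiable from knockout data: the 2N(N−1) parameters exceed the N²
equations, activating and repressing edges of a pair compensate along an
exact-fit manifold, and trained networks retain large spurious constants
at any convergence depth.

**What recovery results show.**  Under these conditions — noise-free
targets, sign priors, determined parameter count, deep convergence — the
method recovers randomized 5-gene networks essentially exactly: all true
connections found, no spurious connections retained, constants to
≪ 1% relative error.  A nonzero spurious-connection rate appears only when
the targets carry noise or training stops early; we report the
deep-convergence result rather than degrading the estimator to match a
looser protocol.  Mean constant errors and spurious-edge counts under
noisy targets scale together with the noise level, so users applying the
method to experimental data should expect both to be finite and coupled.

## Numerical choices

* Per-element RNG streams are derived from (seed, element index), so
  adding an element does not perturb other elements' draws and identical
  configurations reproduce bit-identical trajectories.
* Degenerate cases: double-root dimer fixed points use the algebraic
  limit; zero-association reactions fall back to linear relaxation;
  constant series return autocorrelation 1 by convention.
* Stationary statistics discard the first 20% of a trajectory by default;
  histogram bins are unit-width for integer-valued samples and
  Freedman–Diaconis otherwise; bimodality smooths with a 5-bin moving
  average (edge-padded so boundary modes survive) and requires a dip to
  ≤ 80% of the lower of two peaks, each at least 10% of the tallest peak;
  spectra are Welch periodograms of mean-subtracted series.
* Statistical comparisons between stochastic runs use batch-means standard
  errors (20 batches), which absorb autocorrelation on scales shorter than
  a batch.

## Known limitations

* Transients (not steady states) degrade with Δt; the engine warns but
  does not adapt the step.
* Scenario 3 underestimates death noise for genes with long on-periods,
  and treats delay chains and all bi-molecular reactions deterministically;
  enzyme and maturation noise visible in exact simulations is therefore
  absent from hybrid runs (levels in the negative-feedback loop differ by
  ~30% from the exact simulation even though the oscillation frequency is
  reproduced).
* Promoter sequestration of TFs and repressors is neglected; deviations
  grow at single-digit copy numbers.
* Inference assumes the OR/competitive-repression steady-state response
  family, known signs of regulation, and measured levels for every gene;
  it infers equilibrium constants only, not kinetic rates.
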