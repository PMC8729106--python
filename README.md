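# grnsync

Hybrid stochastic–deterministic simulation of gene regulatory networks
(GRNs) by periodic element synchronization, with exact reference oracles
and a recurrent-network gradient method for inferring regulatory topology
and equilibrium constants from knockout steady states.

## Who this is for

Systems biologists and modellers who want to

* simulate GRNs that mix genes (bursty two-state promoters with
  single/AND/OR activation logic and competitive repression), signalling
  inputs, and bi-molecular reactions (hetero-/homo-dimerization, enzymatic
  turnover) at selectable levels of stochastic detail, much faster than an
  exact simulation;
* cross-check such simulations against an exact Gillespie direct-method
  simulator and the network-wide mean-field ODE;
* infer which genes regulate which — and how strongly — from steady-state
  expression levels measured under gene knockouts.

## The method

**Simulation.** The central assumption is that changes in molecule numbers
are small within a synchronization interval Δt.  Each network element is
then advanced over Δt *in isolation*, using the species abundances and
fluxes frozen at the last synchronization point, after which all abundances
and fluxes are exchanged network-wide.  Isolation admits local closed-form
solutions per element:

* a gene's promoter is summarized by an effective telegraph model with
  on/off rates (λ_eff, µ_eff) computed from its binding logic — e.g. for
  OR logic λ_eff = Σᵢ λᵢ and p_on = 1 − Πᵢ(1 − p_on,i), with a repressor
  rescaling λ_eff by 1/(1+K_R) — and its product follows
  dn/dt = a·ν − δ·n with activity *a* either the stationary p_on
  (scenario 1), a stochastically switching on/off indicator (scenario 2),
  or switching plus discrete Poisson births and binomial survival
  (scenario 3);
* rate-limiting maturation stages (elongation, splicing, translation) form
  a linear cascade advanced by its exact propagator; fixed delays are a
  queue of past outputs;
* dimerization and enzyme elements follow a scalar Riccati equation
  df/dt = λ(N₁−f)(N₂−f) − (δ₁+δ₂+µ)f + j_in with an exact logistic-form
  solution between its fixed points; consumed and produced amounts are
  reported as fluxes at synchronization.

**Inference.** Each gene is identified with a perceptron whose
steady-state response is p_on(x)·ν − δx.  Given target levels **T** under
different conditions, the loss W = ½‖x−T‖² is minimized over the per-edge
equilibrium constants K = λ/µ using the recurrent-network delta rule: one
adjoint solve Lᵀz = (x−T) with the steady-state Jacobian L yields the
gradient for *all* parameters, ΔK = η·z·∂F/∂K.  Connections whose inferred
constant falls below 10⁻⁴ are pruned.

## Worked example

`examples/01_cascade_scenarios.py` simulates a four-gene repressive cascade
(constant input of 100 repressor molecules) in all three scenarios and
compares gene 4 against the network-wide ODE:

```
ODE steady state of gene 4: 16.61 molecules
scenario 1: stationary mean   16.61   variance     0.00
scenario 2: stationary mean   17.43   variance    62.10
scenario 3: stationary mean   16.42   variance    76.61
```

Scenario 1 reproduces the deterministic mean exactly; adding stochastic
promoter switching (scenario 2) and discrete birth/death events
(scenario 3) leaves the mean near the ODE level while the stationary
variance grows — the hallmark of transcriptional bursting noise.

`examples/04_knockout_inference.py` generates a random 5-gene ground-truth
network, knocks out each gene in turn, and trains a fully connected
network on the 25 steady-state measurements:

```
ground truth: 12 of 20 possible connections present
training data: 5 knockouts x 5 measured genes
true connections recovered:     100%
spurious connections retained:  0%
mean relative error of constants on recovered edges: 0.0000%
```

The other examples demonstrate closed-form reaction elements whose steady
state is independent of Δt (`02_enzyme_loop.py`) and noise-induced
bistability/oscillations in autoregulatory loops that full stochasticity
(scenario 3, Gillespie) captures but partial stochasticity (scenario 2)
misses (`03_feedback_noise.py`).

A thin CLI mirrors the library: `grnsync simulate|oracle|infer|benchmark|stats`
(see `grnsync --help`).

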