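"""The synchronization main loop.

Per synchronization interval ``dt`` every network element is advanced in
isolation using species abundances and fluxes frozen at the previous
synchronization point; the network-wide state is then updated by collecting
each element's reported output and summing the reported fluxes.  Elements
never see intra-step updates of other elements, so the result is independent
of the order in which elements are evaluated within a step.

Scenario dispatch per gene: 1 = deterministic activity (stationary p_on
held constant over the step), 2 = stochastic promoter switching with
deterministic product kinetics, 3 = stochastic switching plus discrete
birth/death events.  Bi-molecular reactions are always advanced with their
deterministic closed-form solutions.  Fluxes computed during step ``q`` are
applied during step ``q+1``.
"""

from __future__ import annotations

import math

import numpy as np

from . import genedyn, reactions
from .genedyn import GeneState
from .model import GeneSpec, InputSpec, NetworkSpec, ReactionSpec, SimConfig, validate_network
from .promoter import EffectiveRates, effective_rates_for_gene
from .trajectory import Trajectory

__all__ = ["run", "evaluate_input"]

_MAX_WARNINGS = 1000


def evaluate_input(spec: InputSpec, t: float) -> float:
    """Evaluate an input profile at time ``t`` (clipped at zero)."""
    if t < 0:
        raise ValueError("t must be >= 0")
    if spec.profile == "constant":
        value = spec.amplitude
    elif spec.profile == "rectangular":
        phase_frac = (t / spec.period + spec.phase / (2.0 * math.pi)) % 1.0
        value = spec.baseline + (spec.amplitude if phase_frac < 0.5 else 0.0)
    else:  # sinusoidal
        value = spec.baseline + spec.amplitude * math.sin(
            2.0 * math.pi * t / spec.period + spec.phase
        )
    return max(0.0, value)


class _GeneRuntime:
    def __init__(self, gene: GeneSpec, rng: np.random.Generator, scenario: int):
        self.gene = gene
        self.rng = rng
        self.state = GeneState(n=gene.initial_level)
        self.has_chain = len(gene.rate_limiting_betas) > 0
        if self.has_chain:
            self.state.chain = np.zeros(len(gene.rate_limiting_betas) + 1)
            self.state.chain[-1] = gene.initial_level
            # intermediate-stage propagator (scenarios 2/3) and full-chain
            # propagator including the output stage (scenario 1)
            self.full_prop = genedyn.DelayChainPropagator(
                tuple(gene.rate_limiting_betas) + (gene.delta,), gene.nu
            )
            self.inter_prop = genedyn.DelayChainPropagator(
                gene.rate_limiting_betas, gene.nu
            )
        self.state.queue = [gene.initial_level] * gene.fixed_delay_steps

    def initialize_state(self, levels: dict[str, float], scenario: int) -> None:
        if scenario == 1:
            return
        init = self.gene.initial_state
        if init == "on":
            self.state.on = True
        elif init == "stationary":
            rates = effective_rates_for_gene(self.gene, levels)
            p_on = 1.0 if rates is None else rates.p_on
            self.state.on = bool(self.rng.random() < p_on)

    def advance(
        self,
        levels: dict[str, float],
        j_net: float,
        dt: float,
        scenario: int,
    ) -> tuple[float, str | None]:
        g = self.gene
        rates = effective_rates_for_gene(g, levels)
        if rates is None:  # constitutive, unrepressed: pinned on
            rates = EffectiveRates(1.0, 1e-300, 1.0)
            self.state.on = True
        warning = genedyn.check_step_criterion(rates.p_on, g.nu, dt)
        st = self.state
        # external flux contribution to the product stage (exact by linearity
        # of the product ODE; the product stage always decays with delta)
        j_term = j_net / g.delta * (1.0 - math.exp(-g.delta * dt)) if j_net else 0.0

        if scenario == 1:
            if self.has_chain:
                st.chain = self.full_prop.advance(st.chain, [(dt, rates.p_on)])
                st.chain[-1] = max(0.0, st.chain[-1] + j_term)
                st.n = st.chain[-1]
            else:
                st.n = max(
                    0.0,
                    genedyn.advance_deterministic(st.n, rates.p_on, g.nu, g.delta, dt)
                    + j_term,
                )
        elif scenario == 2:
            if self.has_chain:
                intervals, end_on = genedyn.realize_switch_intervals(
                    st.on, rates, dt, self.rng
                )
                acts = [(tau, 1.0 if on else 0.0) for tau, on in intervals]
                st.chain = self.full_prop.advance(st.chain, acts)
                st.chain[-1] = max(0.0, st.chain[-1] + j_term)
                st.n = st.chain[-1]
                st.on = end_on
            else:
                genedyn.advance_two_state(st, rates, g.nu, g.delta, dt, self.rng)
                st.n = max(0.0, st.n + j_term)
        else:  # scenario 3
            if self.has_chain:
                intervals, end_on = genedyn.realize_switch_intervals(
                    st.on, rates, dt, self.rng
                )
                acts = [(tau, 1.0 if on else 0.0) for tau, on in intervals]
                inter = st.chain[:-1]
                c_n0 = inter[-1]
                inter = self.inter_prop.advance(inter, acts)
                st.chain[:-1] = inter
                beta_n = g.rate_limiting_betas[-1]
                inflow = beta_n * 0.5 * (c_n0 + inter[-1]) * dt  # trapezoid mean
                n = int(round(st.chain[-1]))
                n = genedyn.sample_survivors(n, g.delta, dt, self.rng)
                n += int(self.rng.poisson(inflow)) if inflow > 0 else 0
                n += genedyn.stochastic_round(j_term, self.rng) if j_term else 0
                st.chain[-1] = max(0, n)
                st.n = st.chain[-1]
                st.on = end_on
            else:
                genedyn.advance_stochastic(st, rates, g.nu, g.delta, dt, self.rng)
                if j_term:
                    st.n += genedyn.stochastic_round(j_term, self.rng)
                st.n = max(0.0, st.n)

        reported = genedyn.delayed_output(st.queue, st.n)
        return reported, warning


class _ReactionRuntime:
    def __init__(
        self, rxn: ReactionSpec, input_names: set[str], gene_products: set[str]
    ):
        self.rxn = rxn
        self.f = 0.0
        self.m = rxn.product_initial
        self.prev_consumed_flux: float | None = None
        self._inputs = input_names
        # a gene-owned product receives the catalytic output as a flux
        # instead of being advanced by this element
        self.owns_product = (
            rxn.kind == "enzyme"
            and rxn.product is not None
            and rxn.product.name not in gene_products
        )

    def _total(self, name: str, levels: dict[str, float], bound: float) -> float:
        """Element-internal total for a dimer substrate.

        Species columns (and clamped inputs) carry the free pool, so the
        element's conserved total adds back its own bound molecules.
        """
        return levels[name] + bound

    def advance(
        self,
        levels: dict[str, float],
        flux_old: dict[str, float],
        flux_new: dict[str, float],
        dt: float,
    ) -> tuple[dict[str, float], str | None]:
        """Advance the element; returns new owned-species values and a warning."""
        r = self.rxn
        out: dict[str, float] = {}
        j_complex = flux_old.get(r.complex.name, 0.0)
        if r.kind == "hetero_dimer":
            s1, s2 = r.substrates
            n1 = self._total(s1.name, levels, self.f)
            n2 = self._total(s2.name, levels, self.f)
            d1, d2 = r.delta(0), r.delta(1)
            if r.lam > 0:
                fps = reactions.dimer_fixed_points(
                    n1, n2, r.lam, r.mu, d1, d2, j_complex
                )
                f_new = reactions.dimer_advance(self.f, dt, fps, r.lam)
                fbar = reactions.dimer_mean_occupancy(self.f, dt, fps, r.lam)
            else:
                rate = d1 + d2 + r.mu
                decay = math.exp(-rate * dt) if rate > 0 else 1.0
                target = j_complex / rate if rate > 0 else 0.0
                f_new = self.f * decay + target * (1.0 - decay)
                fbar = target + (self.f - target) * (1.0 - decay) / (rate * dt) if rate > 0 else self.f
            c1, c2 = reactions.dimer_fluxes(self.f, f_new, fbar, d1, d2, dt)
            flux_new[s1.name] = flux_new.get(s1.name, 0.0) - c1 / dt
            flux_new[s2.name] = flux_new.get(s2.name, 0.0) - c2 / dt
            self.f = max(0.0, f_new)
            out[r.complex.name] = self.f
            consumed_flux = (c1 + c2) / dt
        elif r.kind == "homo_dimer":
            (s1,) = r.substrates
            n_total = self._total(s1.name, levels, 2.0 * self.f)
            f_new, fbar, consumed = reactions.homodimer_advance(
                n_total, r.lam, r.mu, r.delta(0), j_complex, self.f, dt
            )
            flux_new[s1.name] = flux_new.get(s1.name, 0.0) - consumed / dt
            self.f = max(0.0, f_new)
            out[r.complex.name] = self.f
            consumed_flux = consumed / dt
        else:  # enzyme
            # total-pool bookkeeping: the substrate and enzyme columns are
            # totals (complexed molecules included), so association merely
            # relabels and only catalysis consumes substrate from the pool
            (s1,) = r.substrates
            sub_total = levels[s1.name]
            enz_total = levels[r.enzyme.name]
            d1, d2 = r.delta(0), r.delta(1)
            d3 = r.delta(2) if len(r.deltas) > 2 else 1.0
            j_prod = flux_old.get(r.product.name, 0.0)
            state = reactions.EnzymeState(f=self.f, m=self.m)
            state = reactions.enzyme_advance(
                state, sub_total, enz_total, r.lam, r.mu, r.nu, d1, d2, d3, j_prod, dt
            )
            catalyzed_flux = r.nu * state.mean_f
            flux_new[s1.name] = flux_new.get(s1.name, 0.0) - catalyzed_flux
            self.f = max(0.0, min(state.f, sub_total, enz_total))
            out[r.complex.name] = self.f
            if self.owns_product:
                self.m = max(0.0, state.m)
                out[r.product.name] = self.m
            else:
                flux_new[r.product.name] = (
                    flux_new.get(r.product.name, 0.0) + catalyzed_flux
                )
            consumed_flux = catalyzed_flux

        warning = None
        if self.prev_consumed_flux is not None:
            warning = reactions.check_flux_criterion(
                self.prev_consumed_flux, consumed_flux, dt
            )
        self.prev_consumed_flux = consumed_flux
        return out, warning


def run(
    spec: NetworkSpec, cfg: SimConfig, eval_order: list[int] | None = None
) -> Trajectory:
    """Simulate a network with the synchronization engine.

    ``eval_order`` optionally permutes the order in which gene elements are
    evaluated within a step (the trajectory is invariant under it; exposed
    for verification).
    """
    diags = validate_network(spec)
    if diags:
        raise ValueError("invalid network: " + "; ".join(diags))
    if cfg.scenario not in (1, 2, 3):
        raise ValueError("scenario must be 1, 2 or 3")

    species = list(spec.declared_species())
    idx = {name: i for i, name in enumerate(species)}
    x = np.zeros(len(species))

    # element rngs keyed by stable position in the spec, independent of
    # evaluation order
    gene_rngs = [
        np.random.Generator(np.random.PCG64(np.random.SeedSequence((cfg.seed, k))))
        for k in range(len(spec.genes))
    ]

    for inp in spec.inputs:
        x[idx[inp.species.name]] = evaluate_input(inp, 0.0)
    genes = [
        _GeneRuntime(g, gene_rngs[k], cfg.scenario) for k, g in enumerate(spec.genes)
    ]
    levels0 = {name: x[idx[name]] for name in species}
    for gr in genes:
        x[idx[gr.gene.product.name]] = gr.gene.initial_level
        gr.initialize_state(levels0, cfg.scenario)
    input_names = {i.species.name for i in spec.inputs}
    gene_products = {g.product.name for g in spec.genes}
    rxns = [_ReactionRuntime(r, input_names, gene_products) for r in spec.reactions]
    owned_names = input_names | gene_products
    for rr in rxns:
        owned_names.add(rr.rxn.complex.name)
        if rr.owns_product and rr.rxn.product is not None:
            owned_names.add(rr.rxn.product.name)
    for r in spec.reactions:
        if r.kind == "enzyme" and r.product is not None:
            x[idx[r.product.name]] = r.product_initial

    order = list(range(len(genes))) if eval_order is None else list(eval_order)

    n_steps = int(round(cfg.t_end / cfg.dt))
    rec_idx = range(0, n_steps + 1, cfg.record_every)
    times = np.array([q * cfg.dt for q in rec_idx])
    out = np.zeros((len(species), times.size))
    out[:, 0] = x
    warnings: list[tuple[float, str, str]] = []
    flux: dict[str, float] = {}

    rec_pos = 1
    for q in range(1, n_steps + 1):
        t1 = q * cfg.dt
        x_old = x.copy()
        levels = {name: x_old[idx[name]] for name in species}
        flux_old = flux
        flux = {}

        for inp in spec.inputs:
            x[idx[inp.species.name]] = evaluate_input(inp, t1)

        for k in order:
            gr = genes[k]
            name = gr.gene.product.name
            reported, warn = gr.advance(
                levels, flux_old.get(name, 0.0), cfg.dt, cfg.scenario
            )
            x[idx[name]] = reported
            if warn and len(warnings) < _MAX_WARNINGS:
                warnings.append((t1, name, warn))

        for rr in rxns:
            owned, warn = rr.advance(levels, flux_old, flux, cfg.dt)
            for name, val in owned.items():
                x[idx[name]] = val
            if warn and len(warnings) < _MAX_WARNINGS:
                warnings.append((t1, rr.rxn.complex.name, warn))

        # species not set by any element this step: plain flux bookkeeping
        for name in species:
            if name not in owned_names:
                x[idx[name]] = max(
                    0.0, x_old[idx[name]] + flux_old.get(name, 0.0) * cfg.dt
                )

        if not np.all(np.isfinite(x)):
            bad = species[int(np.argmin(np.isfinite(x)))]
            raise FloatingPointError(
                f"non-finite abundance for {bad!r} at t = {t1:.6g} s"
            )

        if q % cfg.record_every == 0:
            out[:, rec_pos] = x
            rec_pos += 1

    return Trajectory(times=times, species=species, abundances=out, warnings=warnings)
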