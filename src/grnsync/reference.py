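"""Independent oracles: exact Gillespie simulation and global ODE assembly.

These implementations share no code with the synchronization engine: the
Gillespie direct method simulates every molecule and promoter state as a
discrete Markov jump process, and :func:`assemble_ode` builds the global
mean-field right-hand side of a network for a standard adaptive ODE solver.
Both serve as ground truth in tests and benchmark comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .engine import evaluate_input
from .model import NetworkSpec
from .promoter import effective_rates_for_gene
from .trajectory import Trajectory

__all__ = [
    "Reaction",
    "ReactionSystem",
    "gillespie",
    "build_cascade_system",
    "build_feedback_system",
    "assemble_ode",
    "solve_ode",
]


@dataclass(frozen=True)
class Reaction:
    """Mass-action reaction: propensity ``k * prod(x[reactants])``.

    ``stoich`` maps species index to the integer change when the reaction
    fires.  Reactants are first-order in each listed species (list a species
    twice for a second-order self-interaction).
    """

    rate: float
    reactants: tuple[int, ...]
    stoich: dict[int, int]


@dataclass
class ReactionSystem:
    """A chemical reaction network over named integer-count species."""

    species: list[str]
    reactions: list[Reaction]

    def index(self, name: str) -> int:
        return self.species.index(name)


def gillespie(
    system: ReactionSystem,
    x0,
    t_end: float,
    seed: int,
    record_dt: float = 1.0,
) -> Trajectory:
    """Exact direct-method sample path, recorded on a uniform grid.

    Event times are drawn from the total propensity and the fired reaction
    from the relative propensities; if all propensities vanish the state is
    frozen to ``t_end``.
    """
    rng = np.random.Generator(np.random.PCG64(seed))
    ns = len(system.species)
    nr = len(system.reactions)
    x = np.zeros(ns + 1, dtype=np.int64)
    x[:-1] = np.asarray(x0, dtype=np.int64)
    if np.any(x[:-1] < 0):
        raise ValueError("initial counts must be non-negative")
    x[-1] = 1  # padding slot so all reactions index two "reactants"

    k = np.array([r.rate for r in system.reactions], dtype=float)
    r1 = np.full(nr, ns, dtype=np.intp)
    r2 = np.full(nr, ns, dtype=np.intp)
    for j, r in enumerate(system.reactions):
        if len(r.reactants) > 0:
            r1[j] = r.reactants[0]
        if len(r.reactants) > 1:
            r2[j] = r.reactants[1]
        if len(r.reactants) > 2:
            raise ValueError("at most bimolecular reactions are supported")
    stoich = [
        (np.fromiter(r.stoich.keys(), dtype=np.intp, count=len(r.stoich)),
         np.fromiter(r.stoich.values(), dtype=np.int64, count=len(r.stoich)))
        for r in system.reactions
    ]

    times = np.arange(0.0, t_end + 0.5 * record_dt, record_dt)
    out = np.zeros((ns, times.size))
    out[:, 0] = x[:-1]
    rec = 1

    t = 0.0
    while t < t_end:
        a = k * x[r1] * x[r2]
        a0 = a.sum()
        if a0 <= 0.0:
            break
        t += rng.exponential(1.0 / a0)
        while rec < times.size and times[rec] <= t:
            out[:, rec] = x[:-1]
            rec += 1
        if t >= t_end:
            break
        j = int(np.searchsorted(np.cumsum(a), rng.random() * a0))
        ids, delta = stoich[j]
        x[ids] += delta
    while rec < times.size:
        out[:, rec] = x[:-1]
        rec += 1
    return Trajectory(times=times, species=list(system.species), abundances=out)


# ---------------------------------------------------------------------------
# benchmark systems


def build_cascade_system(
    n_links: int = 4,
    lambda_a: float = 1e-4,
    mu_a: float = 1e-2,
    lambda_r: float = 1e-3,
    mu_r: float = 1e-2,
    nu: float = 1.0,
    delta: float = 1e-2,
) -> ReactionSystem:
    """Repressive gene cascade with explicit three-state promoters.

    Each link's promoter is empty, activator-bound (productive) or
    repressor-bound; link ``n`` is repressed by the product of link ``n-1``
    (link 1 by the constant-copy input ``R0``) and all links share the
    constitutive activator ``A``.  ``lambda_a``/``lambda_r`` are per-molecule
    association rates.
    """
    species: list[str] = ["A", "R0"]
    for n in range(1, n_links + 1):
        species += [f"P{n}", f"PA{n}", f"PR{n}", f"R{n}"]
    sys = ReactionSystem(species=species, reactions=[])
    si = sys.index
    for n in range(1, n_links + 1):
        p, pa, pr = si(f"P{n}"), si(f"PA{n}"), si(f"PR{n}")
        rep = si(f"R{n-1}") if n > 1 else si("R0")
        prod = si(f"R{n}")
        a = si("A")
        sys.reactions += [
            Reaction(lambda_a, (p, a), {p: -1, a: -1, pa: +1}),
            Reaction(mu_a, (pa,), {pa: -1, p: +1, a: +1}),
            Reaction(lambda_r, (p, rep), {p: -1, rep: -1, pr: +1}),
            Reaction(mu_r, (pr,), {pr: -1, p: +1, rep: +1}),
            Reaction(nu, (pa,), {prod: +1}),
            Reaction(delta, (prod,), {prod: -1}),
        ]
    return sys


def cascade_x0(system: ReactionSystem, activator_copies=100, input_copies=100):
    """Initial counts: free promoters, constant activator/input pools, no product."""
    x0 = np.zeros(len(system.species), dtype=int)
    x0[system.index("A")] = activator_copies
    x0[system.index("R0")] = input_copies
    for name in system.species:
        if name.startswith("P") and not name.startswith(("PA", "PR")):
            x0[system.index(name)] = 1
    return x0


def build_feedback_system(kind: str, params: dict) -> ReactionSystem:
    """Autoregulatory feedback loop with enzyme-mediated degradation.

    ``positive``: the gene is activated by its own product A (promoter
    binding sequesters one A); transcription yields RNA which matures to A
    with rate ``beta``; A decays spontaneously (``delta``) or via the enzyme
    E (association ``lambda_e``, dissociation ``mu_e``, turnover ``nu_e``).
    If ``lambda_b``/``mu_b`` are given, the promoter carries a second,
    independent site for a constant single-copy basal activator B (two-site
    OR promoter, four states); either occupied site drives transcription.

    ``negative``: the free promoter transcribes constitutively and is
    blocked by its own product R; otherwise identical layout.
    """
    p = params
    tf = "A" if kind == "positive" else "R"
    basal = kind == "positive" and p.get("lambda_b", 0.0) > 0.0
    if basal:
        species = ["P00", "P10", "P01", "P11", "B", "RNA", tf, "E", "EC"]
    else:
        species = ["P", "PB", "RNA", tf, "E", "EC"]
    sys = ReactionSystem(species=species, reactions=[])
    si = sys.index
    rna, x, e, ec = si("RNA"), si(tf), si("E"), si("EC")
    if kind == "positive" and basal:
        p00, p10, p01, p11, b = (si(s) for s in ("P00", "P10", "P01", "P11", "B"))
        la, ma, lb, mb = p["lambda_tf"], p["mu_tf"], p["lambda_b"], p["mu_b"]
        sys.reactions += [
            Reaction(la, (p00, x), {p00: -1, x: -1, p10: +1}),
            Reaction(ma, (p10,), {p10: -1, p00: +1, x: +1}),
            Reaction(la, (p01, x), {p01: -1, x: -1, p11: +1}),
            Reaction(ma, (p11,), {p11: -1, p01: +1, x: +1}),
            Reaction(lb, (p00, b), {p00: -1, b: -1, p01: +1}),
            Reaction(mb, (p01,), {p01: -1, p00: +1, b: +1}),
            Reaction(lb, (p10, b), {p10: -1, b: -1, p11: +1}),
            Reaction(mb, (p11,), {p11: -1, p10: +1, b: +1}),
            Reaction(p["nu"], (p10,), {rna: +1}),
            Reaction(p["nu"], (p01,), {rna: +1}),
            Reaction(p["nu"], (p11,), {rna: +1}),
        ]
    elif kind == "positive":
        pr, pb = si("P"), si("PB")
        sys.reactions += [
            Reaction(p["lambda_tf"], (pr, x), {pr: -1, x: -1, pb: +1}),
            Reaction(p["mu_tf"], (pb,), {pb: -1, pr: +1, x: +1}),
            Reaction(p["nu"], (pb,), {rna: +1}),
        ]
    elif kind == "negative":
        pr, pb = si("P"), si("PB")
        sys.reactions += [
            Reaction(p["lambda_tf"], (pr, x), {pr: -1, x: -1, pb: +1}),
            Reaction(p["mu_tf"], (pb,), {pb: -1, pr: +1, x: +1}),
            Reaction(p["nu"], (pr,), {rna: +1}),
        ]
    else:
        raise ValueError("kind must be 'positive' or 'negative'")
    if p.get("beta2"):
        sys.species.append("RNA2")
        rna2 = si("RNA2")
        sys.reactions += [
            Reaction(p["beta"], (rna,), {rna: -1, rna2: +1}),
            Reaction(p["beta2"], (rna2,), {rna2: -1, x: +1}),
        ]
    else:
        sys.reactions.append(Reaction(p["beta"], (rna,), {rna: -1, x: +1}))
    sys.reactions += [
        Reaction(p["lambda_e"], (e, x), {e: -1, x: -1, ec: +1}),
        Reaction(p["mu_e"], (ec,), {ec: -1, e: +1, x: +1}),
        Reaction(p["nu_e"], (ec,), {ec: -1, e: +1}),
        Reaction(p["delta"], (x,), {x: -1}),
    ]
    return sys


def feedback_x0(system: ReactionSystem, enzyme_copies: int, tf_copies: int = 0):
    x0 = np.zeros(len(system.species), dtype=int)
    free_promoter = "P00" if "P00" in system.species else "P"
    x0[system.index(free_promoter)] = 1
    if "B" in system.species:
        x0[system.index("B")] = 1
    x0[system.index("E")] = enzyme_copies
    tf = "A" if "A" in system.species else "R"
    x0[system.index(tf)] = tf_copies
    return x0


# ---------------------------------------------------------------------------
# global mean-field ODE


def assemble_ode(spec: NetworkSpec):
    """Global mean-field right-hand side of a network.

    Returns ``(rhs, state_names, y0)`` where the state collects gene
    products (with delay-chain stages as extra variables), reaction
    complexes and enzyme products; input species are evaluated from their
    profiles at time ``t``.  Gene activity enters as the instantaneous
    stationary on-probability ``p_on(x)``, reactions as their full
    rate equations -- no freezing, so the solution is the network-wide ODE
    reference the synchronization engine approximates.
    """
    state_names: list[str] = []
    chain_slices: dict[str, slice] = {}
    for g in spec.genes:
        nstage = len(g.rate_limiting_betas)
        if nstage:
            start = len(state_names)
            state_names += [f"{g.product.name}__c{i+1}" for i in range(nstage)]
            chain_slices[g.product.name] = slice(start, start + nstage)
        state_names.append(g.product.name)
    for r in spec.reactions:
        state_names.append(r.complex.name)
        if (
            r.kind == "enzyme"
            and r.product is not None
            and r.product.name not in state_names
            and all(g.product.name != r.product.name for g in spec.genes)
        ):
            state_names.append(r.product.name)
    pos = {n: i for i, n in enumerate(state_names)}
    input_specs = list(spec.inputs)

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        levels = {s.species.name: evaluate_input(s, t) for s in input_specs}
        for n, i in pos.items():
            levels[n] = max(y[i], 0.0)
        dy = np.zeros_like(y)
        for g in spec.genes:
            rates = effective_rates_for_gene(g, levels)
            a = 1.0 if rates is None else rates.p_on
            n_i = pos[g.product.name]
            if g.rate_limiting_betas:
                sl = chain_slices[g.product.name]
                betas = g.rate_limiting_betas
                prev = a * g.nu
                for j, beta in enumerate(betas):
                    dy[sl.start + j] = prev - beta * y[sl.start + j]
                    prev = beta * y[sl.start + j]
                dy[n_i] += prev - g.delta * y[n_i]
            else:
                dy[n_i] += a * g.nu - g.delta * y[n_i]
        for r in spec.reactions:
            f_i = pos[r.complex.name]
            f = levels[r.complex.name]
            if r.kind == "hetero_dimer":
                s1, s2 = (levels[s.name] for s in r.substrates)
                d1, d2 = r.delta(0), r.delta(1)
                assoc = r.lam * s1 * s2
                dy[f_i] += assoc - (d1 + d2 + r.mu) * f
                i1, i2 = (pos.get(s.name) for s in r.substrates)
                if i1 is not None:
                    dy[i1] += -assoc + (r.mu + d2) * f
                if i2 is not None:
                    dy[i2] += -assoc + (r.mu + d1) * f
            elif r.kind == "homo_dimer":
                s1 = levels[r.substrates[0].name]
                d1 = r.delta(0)
                assoc = r.lam * s1 * s1
                dy[f_i] += assoc - (2.0 * d1 + r.mu) * f
                i1 = pos.get(r.substrates[0].name)
                if i1 is not None:
                    dy[i1] += -2.0 * assoc + 2.0 * r.mu * f + 2.0 * d1 * f
            else:  # enzyme
                s1 = levels[r.substrates[0].name]
                e = levels.get(r.enzyme.name, 0.0)
                if r.enzyme.name not in pos:
                    # enzyme given as a total (input) pool: free = total - bound
                    e = max(e - f, 0.0)
                d1, d2 = r.delta(0), r.delta(1)
                d3 = r.delta(2) if len(r.deltas) > 2 else 1.0
                assoc = r.lam * s1 * e
                dy[f_i] += assoc - (d1 + r.nu + d2 + r.mu) * f
                i1 = pos.get(r.substrates[0].name)
                if i1 is not None:
                    dy[i1] += -assoc + r.mu * f
                ie = pos.get(r.enzyme.name)
                if ie is not None:
                    dy[ie] += -assoc + (r.mu + r.nu + d1) * f
                if r.product is not None and r.product.name in pos:
                    gene_owned = any(
                        g.product.name == r.product.name for g in spec.genes
                    )
                    dy[pos[r.product.name]] += r.nu * f - (
                        0.0 if gene_owned else d3 * levels[r.product.name]
                    )
        return dy

    y0 = np.zeros(len(state_names))
    for g in spec.genes:
        y0[pos[g.product.name]] = g.initial_level
    for r in spec.reactions:
        if r.kind == "enzyme" and r.product is not None and r.product.name in pos:
            y0[pos[r.product.name]] += r.product_initial
    return rhs, state_names, y0


def solve_ode(
    spec: NetworkSpec,
    t_end: float,
    t_eval=None,
    rtol: float = 1e-8,
    atol: float = 1e-8,
) -> Trajectory:
    """Integrate the global mean-field ODE of ``spec`` with an adaptive solver."""
    rhs, names, y0 = assemble_ode(spec)
    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, 501)
    sol = solve_ivp(
        rhs, (0.0, float(t_end)), y0, t_eval=np.asarray(t_eval, dtype=float),
        method="LSODA", rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE solver failed: {sol.message}")
    return Trajectory(times=sol.t, species=list(names), abundances=sol.y)
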