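"""Canonical benchmark networks and their parameter regimes.

These generators reproduce the in-silico study systems: a four-gene
repressive cascade (with slow- and fast-switching promoter regimes), an
exemplary biochemical reaction of two enzymes cycling each other's product,
and positive/negative autoregulatory feedback loops with enzyme-mediated
degradation.  Each simulator network has a structurally matching
reaction-level counterpart in :mod:`grnsync.reference` so that hybrid
simulations can be compared against exact Gillespie or global ODE
solutions of the same system.

Rate values are package-chosen regimes (per-molecule association rates in
1/(s*molecule), all other rates in 1/s) selected so that the documented
qualitative phenomena -- variance growth with stochastic detail,
noise-induced bistability and noise-induced oscillations -- manifest
robustly at tractable simulation lengths.
"""

from __future__ import annotations

from .model import (
    GeneSpec,
    InputSpec,
    NetworkSpec,
    ReactionSpec,
    SpeciesRef,
    TFBindingSpec,
)

__all__ = [
    "CASCADE_REGIMES",
    "repressive_cascade",
    "two_enzyme_loop",
    "FEEDBACK_PARAMS",
    "positive_feedback",
    "negative_feedback",
]

# promoter switching slow or fast relative to product turnover (delta)
CASCADE_REGIMES = {
    "slow": dict(
        activator_copies=100,
        lambda_a=1.2e-4,  # lambda_eff = 1.2e-2 with 100 activator copies
        mu_a=4e-3,        # on/off switching slower than product decay
        lambda_r=5e-3,    # K_R = 0.05 per repressor molecule, fast binding
        mu_r=0.1,
        nu=0.16,
        delta=6e-3,
    ),
    "fast": dict(
        activator_copies=100,
        lambda_a=2e-3,   # lambda_eff = 0.2 with 100 activator copies
        mu_a=1.0,        # short on-periods (on-fraction ~ 0.1)
        lambda_r=2e-2,   # K_R = 0.02 per repressor molecule, fast binding
        mu_r=1.0,
        nu=2.0,
        delta=1e-2,
    ),
}


def repressive_cascade(
    input_level: float = 100.0,
    regime: str = "slow",
    n_links: int = 4,
    initial_state: str = "off",
) -> NetworkSpec:
    """Four-gene repressive cascade driven by a constant input repressor.

    Every link is activated by a shared constitutive activator ``A`` and
    competitively repressed by the previous link's product (link 1 by the
    constant input ``R0``).
    """
    p = CASCADE_REGIMES[regime]
    inputs = (
        InputSpec(SpeciesRef("A", "input"), "constant", amplitude=p["activator_copies"]),
        InputSpec(SpeciesRef("R0", "input"), "constant", amplitude=input_level),
    )
    genes = []
    for n in range(1, n_links + 1):
        repressor = f"R{n-1}"
        genes.append(
            GeneSpec(
                product=SpeciesRef(f"R{n}"),
                logic="single",
                nu=p["nu"],
                delta=p["delta"],
                bindings=(
                    TFBindingSpec(SpeciesRef("A", "input"), p["lambda_a"], p["mu_a"]),
                    TFBindingSpec(
                        SpeciesRef(repressor), p["lambda_r"], p["mu_r"], "repressor"
                    ),
                ),
                initial_state=initial_state,
            )
        )
    return NetworkSpec(inputs=inputs, genes=tuple(genes))


def two_enzyme_loop(
    nu_src: float = 0.08,
    delta_n: float = 1e-3,
    delta_m: float = 1e-3,
    enzyme_f: float = 20.0,
    enzyme_g: float = 30.0,
) -> NetworkSpec:
    """Two enzymes mutually converting each other's product.

    A constitutive source gene supplies substrate ``N``; enzyme ``F`` turns
    ``N`` into ``M`` and enzyme ``G`` turns ``M`` back into ``N`` (reported
    as a production flux into the gene-owned pool), while both species decay
    slowly, so the loop relaxes to a genuine open-system steady state.
    """
    n_ref = SpeciesRef("N", "gene_product")
    m_ref = SpeciesRef("M", "reaction_product")
    src = GeneSpec(product=n_ref, logic="single", nu=nu_src, delta=delta_n)
    inputs = (
        InputSpec(SpeciesRef("F", "input"), "constant", amplitude=enzyme_f),
        InputSpec(SpeciesRef("G", "input"), "constant", amplitude=enzyme_g),
    )
    reactions = (
        ReactionSpec(
            kind="enzyme",
            substrates=(n_ref,),
            enzyme=SpeciesRef("F", "input"),
            complex=SpeciesRef("FN", "complex"),
            product=m_ref,
            lam=1e-3,
            mu=0.1,
            nu=0.05,
            deltas=(delta_n, 0.0, delta_m),
        ),
        ReactionSpec(
            kind="enzyme",
            substrates=(m_ref,),
            enzyme=SpeciesRef("G", "input"),
            complex=SpeciesRef("GM", "complex"),
            product=n_ref,
            lam=5e-4,
            mu=0.1,
            nu=0.08,
            deltas=(delta_m, 0.0, delta_n),
        ),
    )
    return NetworkSpec(inputs=inputs, genes=(src,), reactions=reactions)


FEEDBACK_PARAMS = {
    "positive": dict(
        lambda_tf=1e-2,   # self-activation arrival rate per molecule
        mu_tf=0.1,        # fast promoter switching
        lambda_b=1.05e-3, # weak basal site (constant single-copy activator)
        mu_b=0.02,        # basal bursts large enough to re-ignite the loop
        nu=0.06,          # transcription while active
        beta=0.05,        # fast RNA maturation
        delta=1.5e-3,     # spontaneous protein decay
        lambda_e=2.65e-2, # Michaelis-Menten-like degradation, Vmax=nu_e*E
        mu_e=5e-2,
        nu_e=3e-3,
        enzyme_copies=5,
        init_tf=0,
    ),
    "negative": dict(
        lambda_tf=1e-2,    # self-repression arrival rate per molecule
        mu_tf=0.4,         # fast promoter switching (K_R = 0.025)
        nu=0.2,            # constitutive transcription while unblocked
        beta=3e-4,         # two slow maturation stages set the loop delay
        beta2=3e-4,
        delta=5e-5,        # spontaneous decay; degradation mostly enzymatic
        lambda_e=5e-3,     # near-saturated enzyme: Vmax=0.1, KM=2
        mu_e=5e-3,
        nu_e=5e-3,
        enzyme_copies=20,
        init_tf=0,
    ),
}


def _enzyme_degradation(tf: SpeciesRef, p: dict) -> ReactionSpec:
    return ReactionSpec(
        kind="enzyme",
        substrates=(tf,),
        enzyme=SpeciesRef("E", "input"),
        complex=SpeciesRef("EC", "complex"),
        product=SpeciesRef("deg", "reaction_product"),
        lam=p["lambda_e"],
        mu=p["mu_e"],
        nu=p["nu_e"],
        deltas=(0.0, 0.0, 1.0),
    )


def positive_feedback(params: dict | None = None) -> NetworkSpec:
    """Gene activated by its own product, with enzyme-mediated degradation.

    Transcription passes through one rate-limiting RNA maturation stage
    (``beta``); the product A decays spontaneously and via the enzyme E.
    """
    p = {**FEEDBACK_PARAMS["positive"], **(params or {})}
    a = SpeciesRef("A")
    gene = GeneSpec(
        product=a,
        logic="or",
        nu=p["nu"],
        delta=p["delta"],
        bindings=(
            TFBindingSpec(a, p["lambda_tf"], p["mu_tf"], "activator"),
            TFBindingSpec(SpeciesRef("B", "input"), p["lambda_b"], p["mu_b"], "activator"),
        ),
        rate_limiting_betas=(p["beta"],),
        initial_level=p["init_tf"],
    )
    inputs = (
        InputSpec(SpeciesRef("E", "input"), "constant", amplitude=p["enzyme_copies"]),
        InputSpec(SpeciesRef("B", "input"), "constant", amplitude=1.0),
    )
    return NetworkSpec(inputs=inputs, genes=(gene,), reactions=(_enzyme_degradation(a, p),))


def negative_feedback(params: dict | None = None) -> NetworkSpec:
    """Constitutive gene blocked by its own product, with enzymatic degradation.

    Production passes through two slow maturation stages, giving the loop
    enough phase lag for a weakly damped oscillatory mode.
    """
    p = {**FEEDBACK_PARAMS["negative"], **(params or {})}
    r = SpeciesRef("R")
    gene = GeneSpec(
        product=r,
        logic="single",
        nu=p["nu"],
        delta=p["delta"],
        bindings=(TFBindingSpec(r, p["lambda_tf"], p["mu_tf"], "repressor"),),
        rate_limiting_betas=(p["beta"], p["beta2"]),
        initial_level=p["init_tf"],
    )
    inputs = (InputSpec(SpeciesRef("E", "input"), "constant", amplitude=p["enzyme_copies"]),)
    return NetworkSpec(inputs=inputs, genes=(gene,), reactions=(_enzyme_degradation(r, p),))


def feedback_gillespie_params(kind: str, params: dict | None = None) -> dict:
    """Parameter dict for :func:`grnsync.reference.build_feedback_system`."""
    p = {**FEEDBACK_PARAMS[kind], **(params or {})}
    keys = ["lambda_tf", "mu_tf", "nu", "beta", "lambda_e", "mu_e", "nu_e", "delta"]
    if kind == "positive":
        keys += ["lambda_b", "mu_b"]
    else:
        keys += ["beta2"]
    return {k: p[k] for k in keys}
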