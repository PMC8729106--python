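"""Declarative network model: species, genes, reactions, inputs.

A gene regulatory network (GRN) is described declaratively by a
:class:`NetworkSpec`: input species with prescribed time profiles, gene
elements (two-state promoters with single/AND/OR activation logic and
competitive repression, a production rate ``nu``, a degradation rate
``delta``, optional rate-limiting delay stages ``beta_i`` and an optional
fixed queue delay), and bi-molecular reaction elements (hetero-/homo-
dimerization and enzymatic turnover).

The spec stores kinetic rates only; derived quantities such as repressor
equilibrium constants ``K_R = lambda_R * n_R / mu_R`` are computed at run
time from current copy numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

__all__ = [
    "SpeciesRef",
    "InputSpec",
    "TFBindingSpec",
    "GeneSpec",
    "ReactionSpec",
    "NetworkSpec",
    "SimConfig",
    "KnockoutSpec",
    "validate_network",
    "apply_knockout",
]

SpeciesKind = Literal["input", "gene_product", "complex", "reaction_product"]


@dataclass(frozen=True)
class SpeciesRef:
    """Reference to a molecular species declared somewhere in the network."""

    name: str
    kind: SpeciesKind = "gene_product"


@dataclass(frozen=True)
class InputSpec:
    """An input species with a prescribed abundance profile.

    Profiles: ``constant`` (amplitude), ``rectangular`` (square wave between
    baseline and baseline+amplitude, duty cycle 0.5) and ``sinusoidal``
    (baseline + amplitude*sin(2*pi*t/period + phase)).  Evaluated profiles
    are clipped at zero.
    """

    species: SpeciesRef
    profile: Literal["constant", "rectangular", "sinusoidal"] = "constant"
    amplitude: float = 0.0
    period: float = 0.0
    phase: float = 0.0
    baseline: float = 0.0


@dataclass(frozen=True)
class TFBindingSpec:
    """A transcription-factor binding site at a promoter.

    ``lambda0`` is the per-molecule arrival rate (1/(s*molecule)) and ``mu``
    the dissociation rate (1/s); the effective on-rate contributed by the
    site is ``lambda0 * n_TF``.
    """

    tf: SpeciesRef
    lambda0: float
    mu: float
    role: Literal["activator", "repressor"] = "activator"


@dataclass(frozen=True)
class GeneSpec:
    """A two-state gene element.

    ``logic`` combines the activator sites (``single`` requires exactly one
    activator); repressors gate activation competitively under any logic.
    ``rate_limiting_betas`` are the rates of deterministic delay stages
    between production initiation and mature product; ``fixed_delay_steps``
    shifts the reported output by that many synchronization steps.
    """

    product: SpeciesRef
    nu: float
    delta: float
    logic: Literal["single", "and", "or"] = "single"
    bindings: tuple[TFBindingSpec, ...] = ()
    rate_limiting_betas: tuple[float, ...] = ()
    fixed_delay_steps: int = 0
    initial_level: float = 0.0
    initial_state: Literal["off", "on", "stationary"] = "off"

    def activators(self) -> tuple[TFBindingSpec, ...]:
        return tuple(b for b in self.bindings if b.role == "activator")

    def repressors(self) -> tuple[TFBindingSpec, ...]:
        return tuple(b for b in self.bindings if b.role == "repressor")


@dataclass(frozen=True)
class ReactionSpec:
    """A bi-molecular reaction element.

    ``hetero_dimer``: substrates (A, B) -> complex; ``homo_dimer``: substrate
    (A,) -> complex; ``enzyme``: substrates = (substrate,), enzyme species,
    catalytic rate ``nu`` producing ``product``.  ``deltas`` are the
    degradation rates of the monomers while bound in the complex (and, for
    enzymes, of the free product as the last entry).
    """

    kind: Literal["hetero_dimer", "homo_dimer", "enzyme"]
    substrates: tuple[SpeciesRef, ...]
    complex: SpeciesRef
    lam: float
    mu: float
    enzyme: SpeciesRef | None = None
    product: SpeciesRef | None = None
    nu: float = 0.0
    deltas: tuple[float, ...] = ()
    product_initial: float = 0.0

    def delta(self, i: int) -> float:
        return self.deltas[i] if i < len(self.deltas) else 0.0


@dataclass(frozen=True)
class NetworkSpec:
    """Full declarative description of a GRN."""

    inputs: tuple[InputSpec, ...] = ()
    genes: tuple[GeneSpec, ...] = ()
    reactions: tuple[ReactionSpec, ...] = ()

    def declared_species(self) -> dict[str, SpeciesRef]:
        out: dict[str, SpeciesRef] = {}
        for inp in self.inputs:
            out[inp.species.name] = inp.species
        for g in self.genes:
            out[g.product.name] = g.product
        for r in self.reactions:
            out[r.complex.name] = r.complex
            if r.product is not None:
                out[r.product.name] = r.product
        return out

    def gene(self, name: str) -> GeneSpec:
        for g in self.genes:
            if g.product.name == name:
                return g
        raise KeyError(f"no gene produces species {name!r}")


@dataclass(frozen=True)
class SimConfig:
    """Simulation configuration for the synchronization engine."""

    dt: float
    t_end: float
    scenario: Literal[1, 2, 3] = 1
    seed: int = 0
    record_every: int = 1


@dataclass(frozen=True)
class KnockoutSpec:
    """Knockout/knockdown of a gene: production rate set to ``residual_nu``."""

    gene: SpeciesRef
    residual_nu: float = 0.0


def validate_network(spec: NetworkSpec) -> list[str]:
    """Check all model invariants; return a list of diagnostics (empty if valid)."""
    diags: list[str] = []
    declared = spec.declared_species()

    gene_products = {g.product.name for g in spec.genes}
    names = [inp.species.name for inp in spec.inputs]
    names += [g.product.name for g in spec.genes]
    names += [r.complex.name for r in spec.reactions]
    # an enzyme product may coincide with a gene product (the catalytic
    # output then feeds the gene-owned pool as a flux)
    names += [
        r.product.name
        for r in spec.reactions
        if r.product is not None and r.product.name not in gene_products
    ]
    seen: set[str] = set()
    for n in names:
        if n in seen:
            diags.append(f"species {n!r}: name declared by more than one element")
        seen.add(n)

    produced: set[str] = set()
    for g in spec.genes:
        if g.product.name in produced:
            diags.append(f"gene {g.product.name!r}: species produced by two gene elements")
        produced.add(g.product.name)

    for inp in spec.inputs:
        if inp.amplitude < 0:
            diags.append(f"input {inp.species.name!r}: amplitude must be >= 0")
        if inp.profile in ("rectangular", "sinusoidal") and inp.period <= 0:
            diags.append(f"input {inp.species.name!r}: periodic profile requires period > 0")

    for g in spec.genes:
        gid = g.product.name
        if g.nu < 0:
            diags.append(f"gene {gid!r}: nu must be >= 0")
        if g.delta <= 0:
            diags.append(f"gene {gid!r}: delta must be > 0")
        acts = g.activators()
        if g.logic == "single" and len(acts) > 1:
            diags.append(f"gene {gid!r}: logic 'single' admits at most one activator")
        for b in g.bindings:
            if b.lambda0 <= 0:
                diags.append(f"gene {gid!r}: binding of {b.tf.name!r} needs lambda0 > 0")
            if b.mu <= 0:
                diags.append(f"gene {gid!r}: binding of {b.tf.name!r} needs mu > 0")
            if b.tf.name not in declared:
                diags.append(f"gene {gid!r}: unresolved species {b.tf.name!r}")
        for beta in g.rate_limiting_betas:
            if beta <= 0:
                diags.append(f"gene {gid!r}: all delay-chain rates beta must be > 0")
        if g.fixed_delay_steps < 0:
            diags.append(f"gene {gid!r}: fixed_delay_steps must be >= 0")

    for r in spec.reactions:
        rid = r.complex.name
        if r.lam < 0 or r.mu < 0 or r.nu < 0 or any(d < 0 for d in r.deltas):
            diags.append(f"reaction {rid!r}: all rates must be >= 0")
        expect = 1 if r.kind in ("homo_dimer", "enzyme") else 2
        if len(r.substrates) != expect:
            diags.append(f"reaction {rid!r}: kind {r.kind!r} requires {expect} substrate(s)")
        for s in r.substrates:
            if s.name not in declared:
                diags.append(f"reaction {rid!r}: unresolved species {s.name!r}")
        if r.kind == "enzyme":
            if r.enzyme is None:
                diags.append(f"reaction {rid!r}: enzyme reaction requires an enzyme species")
            elif r.enzyme.name not in declared:
                diags.append(f"reaction {rid!r}: unresolved species {r.enzyme.name!r}")
            if r.product is None:
                diags.append(f"reaction {rid!r}: enzyme reaction requires a product species")
            elif r.substrates and r.product.name == r.substrates[0].name:
                diags.append(f"reaction {rid!r}: product must be distinct from substrate")

    return diags


def apply_knockout(spec: NetworkSpec, ko: KnockoutSpec) -> NetworkSpec:
    """Return a copy of ``spec`` with the knocked-out gene's ``nu`` set to the residual.

    The original spec is unmodified.  Raises ``KeyError`` for an unknown gene
    and ``ValueError`` for a residual outside [0, nu].
    """
    target = spec.gene(ko.gene.name)  # KeyError if absent
    if ko.residual_nu < 0 or ko.residual_nu > target.nu:
        raise ValueError(
            f"residual_nu must lie in [0, {target.nu}] for gene {ko.gene.name!r}"
        )
    genes = tuple(
        replace(g, nu=ko.residual_nu) if g.product.name == ko.gene.name else g
        for g in spec.genes
    )
    return replace(spec, genes=genes)
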