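"""Effective two-state promoter rates for multi-site binding logics.

Every promoter structure (single activator, AND, OR, each optionally gated
by competitive repressors) is summarized by an equivalent two-state
telegraph model with effective switching rates ``lambda_eff`` (off -> on)
and ``mu_eff`` (on -> off) and stationary on-probability
``p_on = lambda_eff / (lambda_eff + mu_eff)``.

Conventions
-----------
* Site on-rates are already scaled by the transcription-factor copy number:
  ``lambda_i = lambda0_i * n_TFi``.
* AND logic: the promoter is on only while every activator is bound, so the
  effective off-rate is the sum of the site off-rates and ``p_on`` is the
  product of per-site bound probabilities.
* OR logic: any bound activator switches the promoter on, so the effective
  on-rate is the sum of the site on-rates and ``p_off`` is the product of
  per-site unbound probabilities.
* Competitive repression multiplies the effective on-rate by
  ``1/(1+K_R)`` per repressor, with ``K_R = lambda_R/mu_R`` (scaled by
  repressor copy number); the off-rate is unchanged because a repressor
  cannot abort an ongoing on-period.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "EffectiveRates",
    "rates_single",
    "rates_and",
    "rates_or",
    "apply_repression",
    "effective_rates_for_gene",
]


@dataclass(frozen=True)
class EffectiveRates:
    """Effective two-state promoter summary (lambda_eff, mu_eff, p_on)."""

    lambda_eff: float
    mu_eff: float
    p_on: float

    def __post_init__(self) -> None:
        if self.lambda_eff < 0:
            raise ValueError("lambda_eff must be >= 0")
        if self.mu_eff <= 0:
            raise ValueError("mu_eff must be > 0")


def _from_rates(lambda_eff: float, mu_eff: float) -> EffectiveRates:
    return EffectiveRates(lambda_eff, mu_eff, lambda_eff / (lambda_eff + mu_eff))


def rates_single(n_tf: float, lambda0: float, mu: float) -> EffectiveRates:
    """Single-activator promoter: on-rate is the TF arrival rate ``n_tf*lambda0``."""
    if n_tf < 0:
        raise ValueError("TF copy number must be >= 0")
    if lambda0 < 0 or mu <= 0:
        raise ValueError("need lambda0 >= 0 and mu > 0")
    return _from_rates(n_tf * lambda0, mu)


def rates_and(bindings: Sequence[tuple[float, float]]) -> EffectiveRates:
    """AND promoter from scaled per-site rates ``(lambda_i, mu_i)``.

    mu_eff = sum(mu_i); p_on = prod(lambda_i/(lambda_i+mu_i));
    lambda_eff = p_on/(1-p_on) * mu_eff.
    """
    if not bindings:
        raise ValueError("AND promoter needs at least one binding site")
    mu_eff = 0.0
    p_on = 1.0
    for lam, mu in bindings:
        if lam < 0 or mu <= 0:
            raise ValueError("need lambda_i >= 0 and mu_i > 0")
        mu_eff += mu
        p_on *= lam / (lam + mu)
    if p_on >= 1.0:
        raise ValueError("degenerate AND promoter with p_on = 1")
    lambda_eff = p_on / (1.0 - p_on) * mu_eff
    return EffectiveRates(lambda_eff, mu_eff, p_on)


def rates_or(bindings: Sequence[tuple[float, float]]) -> EffectiveRates:
    """OR promoter from scaled per-site rates ``(lambda_i, mu_i)``.

    lambda_eff = sum(lambda_i); p_on = 1 - prod(1 - p_on_i);
    mu_eff = lambda_eff*(1-p_on)/p_on.

    If every lambda_i is zero the promoter can never switch on; by
    convention the result is lambda_eff = 0 with mu_eff = sum(mu_i) and
    p_on = 0 (avoids the 0/0 in the mu_eff formula).
    """
    if not bindings:
        raise ValueError("OR promoter needs at least one binding site")
    lambda_eff = 0.0
    p_off = 1.0
    mu_sum = 0.0
    for lam, mu in bindings:
        if lam < 0 or mu <= 0:
            raise ValueError("need lambda_i >= 0 and mu_i > 0")
        lambda_eff += lam
        mu_sum += mu
        p_off *= mu / (lam + mu)
    if lambda_eff == 0.0:
        return EffectiveRates(0.0, mu_sum, 0.0)
    p_on = 1.0 - p_off
    mu_eff = lambda_eff * (1.0 - p_on) / p_on
    return EffectiveRates(lambda_eff, mu_eff, p_on)


def apply_repression(
    base: EffectiveRates, repressors: Sequence[tuple[float, float]]
) -> EffectiveRates:
    """Gate ``base`` by competitive repressors given as scaled ``(lambda_R, mu_R)``.

    Each repressor rescales the effective on-rate by ``1/(1+K_R)`` with
    ``K_R = lambda_R/mu_R``; multiple repressors combine multiplicatively.
    The off-rate is unchanged.
    """
    factor = 1.0
    for lam_r, mu_r in repressors:
        if lam_r < 0 or mu_r <= 0:
            raise ValueError("need lambda_R >= 0 and mu_R > 0")
        factor /= 1.0 + lam_r / mu_r
    if factor == 1.0:
        return base
    return _from_rates(base.lambda_eff * factor, base.mu_eff)


def constitutive_rates(repressors: Sequence[tuple[float, float]]) -> EffectiveRates | None:
    """Effective rates for an activator-free (constitutive) promoter.

    Without repressors the gene is permanently active; ``None`` signals the
    caller to hold activity at 1.  With repressors the promoter is a
    free/blocked telegraph: the off-rate is the total repressor arrival rate
    and the on-rate follows from the stationary unblocked probability
    ``prod 1/(1+K_R)`` (exact for a single repressor).
    """
    reps = [(lam, mu) for lam, mu in repressors if lam > 0]
    if not reps:
        return None
    mu_eff = sum(lam for lam, _ in reps)
    p_free = 1.0
    for lam_r, mu_r in reps:
        p_free /= 1.0 + lam_r / mu_r
    lambda_eff = mu_eff * p_free / (1.0 - p_free)
    return EffectiveRates(lambda_eff, mu_eff, p_free)


def effective_rates_for_gene(gene, levels: dict[str, float]) -> EffectiveRates | None:
    """Effective rates for a :class:`~grnsync.model.GeneSpec` at current TF levels.

    ``levels`` maps species names to copy numbers; activator site on-rates
    are scaled by the current copy number of their TF, repressor strengths
    by the current repressor copy number.  Returns ``None`` for a
    constitutive, unrepressed gene (activity pinned at 1).
    """
    reps = [(b.lambda0 * levels[b.tf.name], b.mu) for b in gene.repressors()]
    acts = gene.activators()
    if not acts:
        return constitutive_rates(reps)
    scaled = [(b.lambda0 * levels[b.tf.name], b.mu) for b in acts]
    if gene.logic == "single":
        (lam, mu), = scaled
        base = _from_rates(lam, mu)
    elif gene.logic == "and":
        base = rates_and(scaled)
    else:
        base = rates_or(scaled)
    return apply_repression(base, reps)
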