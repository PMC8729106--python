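"""Closed-form advancement of bi-molecular reaction elements.

Within one synchronization interval the totals of the participating species
and the external complex inflow ``j_in`` are frozen, which turns each
reaction element into a scalar Riccati-type ODE for its complex abundance

    df/dt = lam*(N1 - f)*(N2 - f) - (d1 + d2 + mu)*f + j_in

with an exact logistic-form solution between its two fixed points.  The
amounts of substrate consumed over the interval (the fluxes reported back to
the network at synchronization) follow in closed form from the time-averaged
complex occupancy.

Homo-dimerization maps onto the hetero-dimer solution via lam -> 4*lam,
N1 = N2 = N/2 (with monomer fluxes doubled); enzymatic turnover via the
substitution d1 -> d1 + nu, with the product following a linear ODE driven
by the mean complex occupancy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "DimerState",
    "EnzymeState",
    "dimer_fixed_points",
    "dimer_advance",
    "dimer_mean_occupancy",
    "dimer_fluxes",
    "homodimer_advance",
    "enzyme_advance",
    "check_flux_criterion",
]

_DEGENERATE_GAP = 1e-9


@dataclass
class DimerState:
    """Mutable state of a dimerization element."""

    f: float = 0.0
    j_in: float = 0.0
    consumed: tuple[float, float] = (0.0, 0.0)


@dataclass
class EnzymeState:
    """Mutable state of an enzyme-turnover element."""

    f: float = 0.0
    m: float = 0.0
    mean_f: float = 0.0
    consumed_substrate: float = 0.0


def dimer_fixed_points(
    n1: float, n2: float, lam: float, mu: float, d1: float, d2: float, j_in: float
) -> tuple[float, float]:
    """Fixed points ``f1 <= f2`` of the complex ODE; ``f1`` is the stable one.

    Roots of ``lam*f^2 - (lam*(N1+N2) + d1+d2+mu)*f + lam*N1*N2 + j_in = 0``,
    computed from the quadratic expansion of the rate equation.
    """
    if lam <= 0:
        raise ValueError("lam must be > 0")
    kinv = (d1 + d2 + mu) / lam
    b = n1 + n2 + kinv
    c = n1 * n2 + j_in / lam
    disc = b * b - 4.0 * c
    if disc < 0:
        if disc > -1e-12 * max(1.0, b * b):
            disc = 0.0
        else:
            raise ValueError("complex fixed points; check that j_in >= 0")
    s = math.sqrt(disc)
    return (b - s) / 2.0, (b + s) / 2.0


def dimer_advance(
    f0: float, dt: float, fixed_points: tuple[float, float], lam: float
) -> float:
    """Exact solution of ``df/dt = -lam*(f - f1)*(f - f2)`` from ``f0`` over ``dt``.

    For well-separated fixed points this is the logistic-form solution
    ``f = f1 + (f2 - f1)*u/(1+u)`` with
    ``u = (f0 - f1)/(f2 - f0) * exp(-lam*(f2 - f1)*t)``; a (near-)double
    root uses the exact algebraic limit ``f = f1 + (f0-f1)/(1 + lam*(f0-f1)*t)``.
    """
    f1, f2 = fixed_points
    if f0 == f2:
        return f2  # unstable equilibrium
    gap = f2 - f1
    if gap < _DEGENERATE_GAP * max(1.0, abs(f1), abs(f2)):
        return f1 + (f0 - f1) / (1.0 + lam * (f0 - f1) * dt)
    k = lam * gap
    u = (f0 - f1) / (f2 - f0) * math.exp(-k * dt)
    return f1 + gap * u / (1.0 + u)


def dimer_mean_occupancy(
    f0: float, dt: float, fixed_points: tuple[float, float], lam: float
) -> float:
    """Time-averaged complex abundance over [0, dt] of the exact solution.

    ``fbar = f1 + 1/(lam*dt) * log((1 + u0)/(1 + u0*exp(-k*dt)))`` with the
    same ``u0`` and ``k`` as :func:`dimer_advance`.
    """
    f1, f2 = fixed_points
    gap = f2 - f1
    if dt <= 0:
        return f0
    if f0 == f2:
        return f2
    if gap < _DEGENERATE_GAP * max(1.0, abs(f1), abs(f2)):
        # integral of the double-root solution
        x = lam * (f0 - f1) * dt
        return f1 + (math.log1p(x) / (lam * dt) if x > -1 else 0.0)
    k = lam * gap
    u0 = (f0 - f1) / (f2 - f0)
    val = math.log((1.0 + u0) / (1.0 + u0 * math.exp(-k * dt)))
    return f1 + val / (lam * dt)


def dimer_fluxes(
    f0: float,
    f_dt: float,
    fbar: float,
    d1: float,
    d2: float,
    dt: float,
) -> tuple[float, float]:
    """Substrate amounts consumed over the interval, from mean occupancy.

    Integrating the substrate balance with the complex trajectory gives the
    closed forms ``consumed_1 = (f(dt) - f0) + d1*fbar*dt`` and symmetrically
    for the second species: the net complex build-up plus the partner loss
    while bound (the external complex inflow cancels from the printed
    integrands).
    """
    dfl = f_dt - f0
    return dfl + d1 * fbar * dt, dfl + d2 * fbar * dt


def homodimer_advance(
    n_total: float,
    lam: float,
    mu: float,
    d1: float,
    j_in: float,
    f0: float,
    dt: float,
) -> tuple[float, float, float]:
    """Advance a homo-dimer element; returns ``(f(dt), fbar, consumed_monomers)``.

    Uses the hetero-dimer machinery under the mapping ``lam -> 4*lam``,
    ``N1 = N2 = N/2`` (same ``j_in``); each net complex consumes two
    monomers, so the reported monomer flux is doubled.
    """
    if lam <= 0:
        # linear relaxation df/dt = -(2*d1+mu) f + j_in
        rate = 2.0 * d1 + mu
        if rate <= 0:
            return f0 + j_in * dt, f0 + j_in * dt / 2.0, 0.0
        decay = math.exp(-rate * dt)
        f = f0 * decay + j_in / rate * (1.0 - decay)
        fbar = (f0 - j_in / rate) * (1.0 - decay) / (rate * dt) + j_in / rate
        return f, fbar, 0.0
    fps = dimer_fixed_points(n_total / 2.0, n_total / 2.0, 4.0 * lam, mu, d1, d1, j_in)
    f = dimer_advance(f0, dt, fps, 4.0 * lam)
    fbar = dimer_mean_occupancy(f0, dt, fps, 4.0 * lam)
    consumed = 2.0 * ((f - f0) + d1 * fbar * dt)
    return f, fbar, consumed


def enzyme_advance(
    state: EnzymeState,
    substrate_total: float,
    enzyme_total: float,
    lam: float,
    mu: float,
    nu: float,
    d1: float,
    d2: float,
    d3: float,
    j_in: float,
    dt: float,
) -> EnzymeState:
    """Advance an enzyme-turnover element over one interval.

    The enzyme-substrate complex follows the dimer solution with the
    substitution ``d1 -> d1 + nu`` (catalysis removes substrate from the
    complex); the product follows
    ``m(dt) = m0*exp(-d3*dt) + (nu*fbar + j_in)/d3 * (1 - exp(-d3*dt))``
    driven by the mean complex occupancy ``fbar``.  ``j_in`` here is the
    external inflow of product molecules.  A non-degrading product
    (``d3 = 0``, e.g. in a mass-conserving cycle) uses the exact limit
    ``m(dt) = m0 + (nu*fbar + j_in)*dt``.
    """
    if d3 < 0:
        raise ValueError("product degradation rate d3 must be >= 0")
    if lam > 0:
        fps = dimer_fixed_points(
            substrate_total, enzyme_total, lam, mu, d1 + nu, d2, 0.0
        )
        f = dimer_advance(state.f, dt, fps, lam)
        fbar = dimer_mean_occupancy(state.f, dt, fps, lam)
    else:
        rate = d1 + nu + d2 + mu
        decay = math.exp(-rate * dt) if rate > 0 else 1.0
        f = state.f * decay
        fbar = state.f * (1.0 - decay) / (rate * dt) if rate > 0 else state.f
    consumed = (f - state.f) + (d1 + nu) * fbar * dt
    if d3 > 0:
        decay3 = math.exp(-d3 * dt)
        m = state.m * decay3 + (nu * fbar + j_in) / d3 * (1.0 - decay3)
    else:
        m = state.m + (nu * fbar + j_in) * dt
    return EnzymeState(f=f, m=m, mean_f=fbar, consumed_substrate=consumed)


def check_flux_criterion(j_prev: float, j_now: float, dt: float) -> str | None:
    """Flux warning: the change in reported flux across a step should be small.

    Returns a warning string iff ``|j_now - j_prev| * dt >= 1``.
    """
    dj = abs(j_now - j_prev) * dt
    if dj >= 1.0:
        return f"flux change over step {dj:.3g} >= 1; reduce dt"
    return None
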