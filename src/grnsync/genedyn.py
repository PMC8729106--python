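"""Single-gene dynamics over one synchronization interval.

Three scenarios of increasing stochastic detail are supported, all under the
central assumption that effective promoter rates are constant within one
synchronization step ``dt``:

1. deterministic: the product follows ``dn/dt = a*nu - delta*n`` with the
   stationary on-probability ``a = p_on`` held constant over the step;
2. stochastic switching: the promoter toggles at exponentially distributed
   times within the step; the product evolves deterministically per realized
   on/off interval;
3. stochastic switching plus discrete birth/death: per on-interval the number
   of produced molecules is Poisson, degradation within on-intervals is
   applied deterministically (with stochastic rounding to keep counts
   integer), and per off-interval survivors are drawn binomially.

Delay chains (rate-limiting processing stages between production initiation
and mature product) are linear first-order cascades and are always advanced
deterministically, by the exact propagator of the cascade for
piecewise-constant promoter activity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .promoter import EffectiveRates

__all__ = [
    "GeneState",
    "advance_deterministic",
    "draw_switch_time",
    "advance_two_state",
    "sample_births",
    "sample_survivors",
    "advance_stochastic",
    "partial_fraction_coeffs",
    "DelayChainPropagator",
    "advance_delay_chain",
    "delayed_output",
    "check_step_criterion",
    "stochastic_round",
]


@dataclass
class GeneState:
    """Mutable per-gene state carried across synchronization steps."""

    n: float = 0.0
    on: bool = False
    chain: np.ndarray | None = None
    queue: list[float] = field(default_factory=list)


def advance_deterministic(
    n0: float, a: float, nu: float, delta: float, dt: float
) -> float:
    """Exact solution of ``dn/dt = a*nu - delta*n`` over ``dt`` with constant a."""
    if delta <= 0:
        raise ValueError("delta must be > 0")
    if not 0.0 <= a <= 1.0:
        raise ValueError("activity a must lie in [0, 1]")
    decay = math.exp(-delta * dt)
    return n0 * decay + a * nu / delta * (1.0 - decay)


def draw_switch_time(alpha: float, u: float) -> float:
    """Exponential waiting time ``-log(u)/alpha`` from a uniform(0,1] draw."""
    if alpha <= 0:
        raise ValueError("switching rate alpha must be > 0")
    return -math.log(u) / alpha


def realize_switch_intervals(
    on: bool, rates: EffectiveRates, dt: float, rng: np.random.Generator
) -> tuple[list[tuple[float, bool]], bool]:
    """Partition [0, dt] into realized promoter on/off intervals.

    The waiting time in the current state is re-drawn at the step start from
    the current rates (valid by memorylessness; rates are constant within the
    step by the central assumption).  Returns the interval list and the
    promoter state at the step end.  A zero exit rate pins the current state
    for the whole step.
    """
    intervals: list[tuple[float, bool]] = []
    t = 0.0
    state = on
    while t < dt:
        alpha = rates.mu_eff if state else rates.lambda_eff
        if alpha <= 0.0:
            intervals.append((dt - t, state))
            break
        tau = draw_switch_time(alpha, 1.0 - rng.random())  # uniform in (0, 1]
        if t + tau >= dt:
            intervals.append((dt - t, state))
            break
        intervals.append((tau, state))
        t += tau
        state = not state
    return intervals, state


def advance_two_state(
    state: GeneState,
    rates: EffectiveRates,
    nu: float,
    delta: float,
    dt: float,
    rng: np.random.Generator,
) -> tuple[GeneState, list[tuple[float, bool]]]:
    """Scenario 2: stochastic switching, deterministic product kinetics.

    The product follows ``dn/dt = nu - delta*n`` during on-intervals and pure
    decay during off-intervals.  Returns the updated state and the realized
    interval partition of [0, dt].
    """
    intervals, end_on = realize_switch_intervals(state.on, rates, dt, rng)
    n = state.n
    for tau, is_on in intervals:
        n = advance_deterministic(n, 1.0 if is_on else 0.0, nu, delta, tau)
    state.n = n
    state.on = end_on
    return state, intervals


def sample_births(nu: float, tau_on: float, rng: np.random.Generator) -> int:
    """Number of production events in an on-interval: Poisson(nu*tau_on)."""
    if tau_on < 0:
        raise ValueError("tau_on must be >= 0")
    mean = nu * tau_on
    return int(rng.poisson(mean)) if mean > 0 else 0


def sample_survivors(
    n: int, delta: float, tau_off: float, rng: np.random.Generator
) -> int:
    """Molecules surviving an interval without production: Binomial(n, e^(-delta*tau))."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return 0
    p = math.exp(-delta * tau_off)
    return int(rng.binomial(n, p))


def stochastic_round(x: float, rng: np.random.Generator) -> int:
    """Round to an integer preserving the mean (floor + Bernoulli on fraction)."""
    base = math.floor(x)
    frac = x - base
    return int(base + (1 if rng.random() < frac else 0))


def advance_stochastic(
    state: GeneState,
    rates: EffectiveRates,
    nu: float,
    delta: float,
    dt: float,
    rng: np.random.Generator,
) -> GeneState:
    """Scenario 3: stochastic switching and discrete birth/death events.

    Per on-interval, births are Poisson(nu*tau) and the pre-existing
    molecules decay deterministically (stochastically rounded to keep the
    count integer and the mean exact); per off-interval the survivor count
    is binomial.
    """
    intervals, end_on = realize_switch_intervals(state.on, rates, dt, rng)
    n = int(round(state.n))
    for tau, is_on in intervals:
        if is_on:
            survivors = stochastic_round(n * math.exp(-delta * tau), rng)
            n = survivors + sample_births(nu, tau, rng)
        else:
            n = sample_survivors(n, delta, tau, rng)
    state.n = float(n)
    state.on = end_on
    return state


# ---------------------------------------------------------------------------
# delay chains


def partial_fraction_coeffs(betas) -> np.ndarray:
    """Partial-fraction coefficients of the delay-chain transfer function.

    For a cascade with pairwise-distinct stage rates ``beta_1..beta_N`` the
    impulse response of the final stage is ``sum_i alpha_i exp(-beta_i t)``
    with ``alpha_i = prod_{n<N} beta_n / prod_{n != i} (beta_n - beta_i)``.

    Raises for non-positive or near-equal rates (relative gap < 1e-9);
    perturb near-equal rates by ~1e-6 relative before calling.
    """
    b = np.asarray(betas, dtype=float)
    if b.size == 0:
        raise ValueError("need at least one stage rate")
    if np.any(b <= 0):
        raise ValueError("all stage rates must be > 0")
    n = b.size
    for i in range(n):
        for j in range(i + 1, n):
            if abs(b[i] - b[j]) < 1e-9 * max(b[i], b[j]):
                raise ValueError(
                    "near-equal delay-chain rates are degenerate; perturb them "
                    "by ~1e-6 relative before building the chain"
                )
    num = np.prod(b[:-1]) if n > 1 else 1.0
    alphas = np.empty(n)
    for i in range(n):
        den = np.prod(np.delete(b, i) - b[i]) if n > 1 else 1.0
        alphas[i] = num / den
    return alphas


class DelayChainPropagator:
    """Exact propagator of the linear delay cascade for piecewise-constant input.

    The cascade is ``dc_1/dt = a(t)*nu - r_1*c_1``,
    ``dc_i/dt = r_{i-1}*c_{i-1} - r_i*c_i`` with stage rates ``r``; for a
    gene element ``r = (beta_1, .., beta_N, delta)`` so that the final stage
    is the mature product decaying with ``delta``.  Over an interval with
    constant activity ``a`` the update is ``c -> E(tau) c + a * w(tau)`` with
    ``E = expm(M tau)`` and ``w = M^{-1}(E - I) v``, both cached per tau.
    """

    def __init__(self, rates, nu: float):
        r = np.asarray(rates, dtype=float)
        if np.any(r <= 0):
            raise ValueError("all stage rates must be > 0")
        self.rates = r
        self.nu = float(nu)
        n = r.size
        m = np.diag(-r)
        for i in range(1, n):
            m[i, i - 1] = r[i - 1]
        self._m = m
        self._v = np.zeros(n)
        self._v[0] = self.nu
        self._cache: dict[float, tuple[np.ndarray, np.ndarray]] = {}

    def n_stages(self) -> int:
        return self.rates.size

    def _ops(self, tau: float) -> tuple[np.ndarray, np.ndarray]:
        ops = self._cache.get(tau)
        if ops is None:
            e = expm(self._m * tau)
            w = np.linalg.solve(self._m, (e - np.eye(self.rates.size)) @ self._v)
            ops = (e, w)
            if len(self._cache) < 64:
                self._cache[tau] = ops
        return ops

    def advance(self, chain: np.ndarray, intervals) -> np.ndarray:
        """Propagate stage abundances through (duration, activity) intervals."""
        c = np.asarray(chain, dtype=float)
        for tau, a in intervals:
            if tau <= 0:
                continue
            e, w = self._ops(tau)
            c = e @ c + float(a) * w
        return c


def advance_delay_chain(
    chain, a, nu: float, betas, delta: float, dt: float
) -> np.ndarray:
    """Advance a gene's delay chain (stages ``betas`` + output stage ``delta``).

    ``a`` is either a constant activity in [0, 1] or a list of
    ``(duration, activity)`` intervals partitioning [0, dt].
    """
    prop = DelayChainPropagator(tuple(betas) + (delta,), nu)
    intervals = [(dt, a)] if np.isscalar(a) else list(a)
    return prop.advance(np.asarray(chain, dtype=float), intervals)


def delayed_output(queue: list[float], current_output: float) -> float:
    """Fixed queue delay: report the value from ``len(queue)`` steps ago.

    Pushes ``current_output`` and pops the oldest entry.  An empty queue is a
    passthrough.
    """
    if not queue:
        return current_output
    queue.append(current_output)
    return queue.pop(0)


def check_step_criterion(p_on: float, nu: float, dt: float) -> str | None:
    """Step-size warning: the expected per-step production should stay below one.

    Returns a warning string iff ``p_on * nu * dt >= 1``.
    """
    change = p_on * nu * dt
    if change >= 1.0:
        return f"expected per-step production {change:.3g} >= 1; reduce dt"
    return None
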