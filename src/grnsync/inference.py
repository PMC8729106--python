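"""Steady-state GRN inference by the recurrent-network delta rule.

Each gene is identified with a perceptron-like unit whose steady-state
response to the other genes' products is the stationary on-probability of
its promoter times its production rate.  Given steady-state measurements
under different conditions (single-gene knockouts and/or input levels), the
per-edge equilibrium constants ``K = lambda/mu`` of transcription-factor
binding are trained by gradient descent where the parameter sensitivities
follow from one adjoint linear solve per condition:

    W = 1/2 sum_i (x_i - T_i)^2,   L^T z = (x - T),
    delta K_j = eta * z . dF/dK_j,

with ``L_ik = dF_i/dx_k`` the steady-state Jacobian.  Production and
degradation rates are held fixed; only equilibrium constants are inferred,
since steady states carry no kinetic information.

Genes use OR-logic activation with competitive repression.  Every gene
additionally carries a fixed (untrained) basal activation constant
``K_basal`` so that a network of mutually regulating genes has a
non-trivial steady state under knockouts.  With activator product
``P_a = (1+K_basal) * prod_i (1+K_act[i]*x_i)`` and repressor product
``P_r = prod_i (1+K_rep[i]*x_i)`` the stationary on-probability is

    p_on = (P_a - 1) / (P_a - 1 + P_r),

which is exactly the effective two-state promoter of the simulator
(OR-combined activators gated by competitive repressors).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .model import (
    GeneSpec,
    InputSpec,
    KnockoutSpec,
    NetworkSpec,
    SpeciesRef,
    TFBindingSpec,
)

__all__ = [
    "TrainableNetwork",
    "TrainingSet",
    "TrainState",
    "TrainResult",
    "steady_state",
    "local_derivatives",
    "adjoint_solve",
    "gradient_step",
    "train",
    "generate_ground_truth",
    "knockout_dataset",
    "evaluate_topology",
    "run_benchmark",
]

EDGE_THRESHOLD = 1e-4  # equilibrium constants below this count as absent


@dataclass
class TrainableNetwork:
    """An OR-logic GRN parameterized by per-edge equilibrium constants.

    Nodes are ``inputs + genes``; ``k_act``/``k_rep`` have shape
    (n_nodes, n_genes) with entry [i, j] the equilibrium constant of the
    edge node_i -> gene_j (0 = no edge).  Self-edges on the diagonal of the
    gene block are excluded from training.
    """

    gene_names: list[str]
    input_names: list[str] = field(default_factory=list)
    input_levels: np.ndarray | None = None
    nu: np.ndarray | None = None
    delta: np.ndarray | None = None
    k_basal: np.ndarray | None = None
    k_act: np.ndarray | None = None
    k_rep: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.gene_names)
        m = len(self.input_names) + n
        if self.input_levels is None:
            self.input_levels = np.zeros(len(self.input_names))
        if self.nu is None:
            self.nu = np.full(n, 100.0)
        if self.delta is None:
            self.delta = np.full(n, 0.1)
        if self.k_basal is None:
            self.k_basal = np.full(n, 0.1)
        if self.k_act is None:
            self.k_act = np.zeros((m, n))
        if self.k_rep is None:
            self.k_rep = np.zeros((m, n))
        for arr in ("nu", "delta", "k_basal"):
            setattr(self, arr, np.asarray(getattr(self, arr), dtype=float))
        self.k_act = np.asarray(self.k_act, dtype=float)
        self.k_rep = np.asarray(self.k_rep, dtype=float)

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    @property
    def n_inputs(self) -> int:
        return len(self.input_names)

    def copy(self) -> "TrainableNetwork":
        return TrainableNetwork(
            gene_names=list(self.gene_names),
            input_names=list(self.input_names),
            input_levels=self.input_levels.copy(),
            nu=self.nu.copy(),
            delta=self.delta.copy(),
            k_basal=self.k_basal.copy(),
            k_act=self.k_act.copy(),
            k_rep=self.k_rep.copy(),
        )

    # -- condition handling -------------------------------------------------

    def condition_arrays(self, condition) -> tuple[np.ndarray, np.ndarray]:
        """(effective nu vector, input level vector) for one condition.

        ``condition`` is ``None`` (unperturbed), a :class:`KnockoutSpec`, or
        a dict mapping input species names to levels.
        """
        nu = self.nu.copy()
        levels = self.input_levels.copy()
        if condition is None:
            pass
        elif isinstance(condition, KnockoutSpec):
            j = self.gene_names.index(condition.gene.name)
            nu[j] = condition.residual_nu
        elif isinstance(condition, dict):
            for name, val in condition.items():
                levels[self.input_names.index(name)] = float(val)
        else:
            raise TypeError(f"unsupported condition {condition!r}")
        return nu, levels

    def node_levels(self, x: np.ndarray, input_levels: np.ndarray) -> np.ndarray:
        return np.concatenate([input_levels, x])

    def p_on(self, x: np.ndarray, input_levels: np.ndarray) -> np.ndarray:
        s = self.node_levels(x, input_levels)
        pa = (1.0 + self.k_basal) * np.prod(1.0 + self.k_act * s[:, None], axis=0)
        pr = np.prod(1.0 + self.k_rep * s[:, None], axis=0)
        a = pa - 1.0
        return a / (a + pr)

    def response(self, x: np.ndarray, nu: np.ndarray, input_levels: np.ndarray):
        """F(x) = nu * p_on(x) - delta * x (the steady-state residual field)."""
        return nu * self.p_on(x, input_levels) - self.delta * x

    # -- export -------------------------------------------------------------

    def to_network_spec(self, basal_name: str = "basal") -> NetworkSpec:
        """Materialize as a declarative :class:`NetworkSpec` (mu fixed at 1)."""
        inputs = [
            InputSpec(
                species=SpeciesRef(n, "input"), profile="constant", amplitude=l
            )
            for n, l in zip(self.input_names, self.input_levels)
        ] + [InputSpec(species=SpeciesRef(basal_name, "input"), amplitude=1.0)]
        node_names = self.input_names + self.gene_names
        genes = []
        for j, name in enumerate(self.gene_names):
            bindings = [
                TFBindingSpec(
                    tf=SpeciesRef(basal_name, "input"),
                    lambda0=float(self.k_basal[j]),
                    mu=1.0,
                )
            ]
            for i, src in enumerate(node_names):
                if self.k_act[i, j] > 0:
                    bindings.append(
                        TFBindingSpec(
                            tf=SpeciesRef(src), lambda0=float(self.k_act[i, j]),
                            mu=1.0, role="activator",
                        )
                    )
                if self.k_rep[i, j] > 0:
                    bindings.append(
                        TFBindingSpec(
                            tf=SpeciesRef(src), lambda0=float(self.k_rep[i, j]),
                            mu=1.0, role="repressor",
                        )
                    )
            genes.append(
                GeneSpec(
                    product=SpeciesRef(name),
                    logic="or",
                    nu=float(self.nu[j]),
                    delta=float(self.delta[j]),
                    bindings=tuple(bindings),
                )
            )
        return NetworkSpec(inputs=tuple(inputs), genes=tuple(genes))


# ---------------------------------------------------------------------------
# steady states and derivatives


def steady_state(
    net: TrainableNetwork,
    condition=None,
    tol: float = 1e-8,
    max_iter: int = 20000,
    relax: float = 0.5,
) -> np.ndarray:
    """Steady-state expression levels under one condition.

    Iterates the deterministic engine's per-step update map
    ``x <- x + relax * (nu*p_on(x)/delta - x)`` (the scenario-1
    synchronization step in the large-step limit) until every residual
    satisfies ``|F_i| < tol * max(1, x_i)``; falls back to a damped Newton
    root solve if the relaxation does not converge.
    """
    nu, levels = net.condition_arrays(condition)
    x = np.zeros(net.n_genes)
    target = nu / net.delta
    for _ in range(max_iter):
        g = target * net.p_on(x, levels)
        if np.all(np.abs(net.delta * (g - x)) < tol * np.maximum(1.0, x)):
            return x
        x = x + relax * (g - x)
    sol = scipy.optimize.root(
        lambda y: net.response(np.maximum(y, 0.0), nu, levels), x, method="hybr"
    )
    x = np.maximum(sol.x, 0.0)
    if not np.all(np.abs(net.response(x, nu, levels)) < 1e-6 * np.maximum(1.0, x)):
        raise RuntimeError(
            f"no steady state found for condition {condition!r}; last state {x}"
        )
    return x


def local_derivatives(
    net: TrainableNetwork, x: np.ndarray, condition=None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Steady-state Jacobian and parameter sensitivities at ``x``.

    Returns ``(L, dF_dkact, dF_dkrep)`` with ``L[j, k] = dF_j/dx_k`` (shape
    n_genes x n_genes) and the edge sensitivities of shape
    (n_nodes, n_genes), entry [i, j] = dF_j / dK[i, j].
    """
    nu, levels = net.condition_arrays(condition)
    s = net.node_levels(x, levels)
    one_a = 1.0 + net.k_act * s[:, None]
    one_r = 1.0 + net.k_rep * s[:, None]
    pa = (1.0 + net.k_basal) * np.prod(one_a, axis=0)
    pr = np.prod(one_r, axis=0)
    a = pa - 1.0
    denom = (a + pr) ** 2

    # dp/dA = pr/denom, dp/dR = -a/denom
    dp_da = pr / denom
    dp_dr = -a / denom

    da_ds = net.k_act * (pa / one_a)       # (nodes, genes)
    dr_ds = net.k_rep * (pr / one_r)
    dp_ds = dp_da * da_ds + dp_dr * dr_ds  # (nodes, genes)

    n_in = net.n_inputs
    # L[j,k] = nu_j * dp_j/dx_k - delta_j * I
    L = (nu * dp_ds[n_in:, :]).T - np.diag(net.delta)

    da_dk = s[:, None] * (pa / one_a)
    dr_dk = s[:, None] * (pr / one_r)
    df_dkact = nu * dp_da * da_dk
    df_dkrep = nu * dp_dr * dr_dk
    return L, df_dkact, df_dkrep


def adjoint_solve(L: np.ndarray, residual: np.ndarray) -> np.ndarray:
    """Solve ``L^T z = (x - T)``; one solve serves all parameters."""
    return np.linalg.solve(L.T, residual)


@dataclass
class TrainingSet:
    """Steady-state targets per condition.

    ``targets`` has shape (n_conditions, n_measured); ``measured`` lists the
    measured species (columns).
    """

    conditions: list
    targets: np.ndarray
    measured: list[str]

    def __post_init__(self) -> None:
        self.targets = np.asarray(self.targets, dtype=float)
        if self.targets.shape != (len(self.conditions), len(self.measured)):
            raise ValueError("targets must be (n_conditions, n_measured)")


@dataclass
class TrainState:
    """Gradient-descent configuration and progress.

    ``eta`` is the delta-rule step size; if ``None`` it is initialized from
    the first gradient so that the first step moves the largest parameter by
    about 5% of its magnitude, and is subsequently adapted by backtracking.
    ``k_cap`` bounds equilibrium constants from above (a constant far beyond
    the saturation of every promoter carries no further information).
    """

    eta: float | None = None
    bound_b: float | None = None  # default: 1e-6 * sum(T^2)
    max_iter: int = 5000
    k_cap: float = 10.0
    loss_history: list[float] = field(default_factory=list)


@dataclass
class TrainResult:
    network: TrainableNetwork
    k_act: np.ndarray
    k_rep: np.ndarray
    loss_history: list[float]
    converged: bool

    @property
    def topology_calls(self) -> np.ndarray:
        """Boolean adjacency after pruning (edge present iff K > 1e-4, either role)."""
        return (self.k_act > EDGE_THRESHOLD) | (self.k_rep > EDGE_THRESHOLD)


def _loss_and_grad(net: TrainableNetwork, data: TrainingSet, meas_idx):
    """Total loss W and its gradient w.r.t. (k_act, k_rep) over all conditions."""
    w = 0.0
    g_act = np.zeros_like(net.k_act)
    g_rep = np.zeros_like(net.k_rep)
    for cond, target in zip(data.conditions, data.targets):
        x = steady_state(net, cond)
        resid_full = np.zeros(net.n_genes)
        resid_full[meas_idx] = x[meas_idx] - target
        w += 0.5 * float(resid_full @ resid_full)
        L, dka, dkr = local_derivatives(net, x, cond)
        z = adjoint_solve(L, resid_full)
        # dW/dK[i,j] = -z_j * dF_j/dK[i,j]
        g_act += -z[None, :] * dka
        g_rep += -z[None, :] * dkr
    return w, g_act, g_rep


def _loss_only(net: TrainableNetwork, data: TrainingSet, meas_idx) -> float:
    w = 0.0
    for cond, target in zip(data.conditions, data.targets):
        x = steady_state(net, cond)
        r = x[meas_idx] - target
        w += 0.5 * float(r @ r)
    return w


def gradient_step(
    net: TrainableNetwork, g_act: np.ndarray, g_rep: np.ndarray, eta: float,
    mask_act: np.ndarray, mask_rep: np.ndarray, k_cap: float = 10.0,
) -> TrainableNetwork:
    """Delta-rule update ``K <- clip(K - eta*dW/dK, 0, k_cap)`` on trainable edges."""
    new = net.copy()
    new.k_act = np.clip(net.k_act - eta * g_act * mask_act, 0.0, k_cap)
    new.k_rep = np.clip(net.k_rep - eta * g_rep * mask_rep, 0.0, k_cap)
    if not (np.all(np.isfinite(new.k_act)) and np.all(np.isfinite(new.k_rep))):
        raise FloatingPointError("non-finite parameter update")
    return new


def _trainable_masks(net: TrainableNetwork, trainable="nonzero"):
    """Masks selecting trainable entries (no gene self-edges)."""
    m = net.n_inputs + net.n_genes
    n = net.n_genes
    if trainable == "nonzero":
        ma = (net.k_act > 0).astype(float)
        mr = (net.k_rep > 0).astype(float)
    else:
        ma = np.ones((m, n))
        mr = np.ones((m, n))
    for j in range(n):
        ma[net.n_inputs + j, j] = 0.0
        mr[net.n_inputs + j, j] = 0.0
    return ma, mr


def train(
    net: TrainableNetwork,
    data: TrainingSet,
    state: TrainState | None = None,
    trainable: str = "nonzero",
    method: str = "resilient",
) -> TrainResult:
    """Train equilibrium constants on steady-state data by the delta rule.

    Both methods use the adjoint gradient (one linear solve per condition)
    and stop when ``W < b`` or after ``max_iter`` iterations.

    ``method="backtracking"`` is the plain delta rule with a single global
    step size, halved until each full-batch step decreases the loss and
    gently re-grown afterwards.  ``method="resilient"`` (default) keeps one
    adaptive step size per parameter, grown on consistent gradient signs
    and shrunk on sign flips; it is far better conditioned when expression
    levels (and hence parameter sensitivities) span orders of magnitude.
    """
    state = state or TrainState()
    net = net.copy()
    meas_idx = np.array([net.gene_names.index(m) for m in data.measured])
    mask_act, mask_rep = _trainable_masks(net, trainable)
    b = state.bound_b
    if b is None:
        b = 1e-6 * float(np.sum(data.targets**2))

    if method == "resilient":
        eta_a = np.full_like(net.k_act, 1e-4)
        eta_r = np.full_like(net.k_rep, 1e-4)
        prev_a = np.zeros_like(eta_a)
        prev_r = np.zeros_like(eta_r)
        converged = False
        while len(state.loss_history) < state.max_iter:
            w, g_act, g_rep = _loss_and_grad(net, data, meas_idx)
            state.loss_history.append(w)
            if not np.isfinite(w):
                raise FloatingPointError("training diverged: non-finite loss")
            if w < b:
                converged = True
                break
            for g, pg, eta, mask, kmat in (
                (g_act, prev_a, eta_a, mask_act, net.k_act),
                (g_rep, prev_r, eta_r, mask_rep, net.k_rep),
            ):
                same = g * pg > 0
                flip = g * pg < 0
                eta[same] = np.minimum(eta[same] * 1.2, 1.0)
                eta[flip] = np.maximum(eta[flip] * 0.5, 1e-12)
                kmat -= eta * np.sign(g) * mask
                np.clip(kmat, 0.0, state.k_cap, out=kmat)
                pg[:] = g
        return TrainResult(
            network=net,
            k_act=net.k_act.copy(),
            k_rep=net.k_rep.copy(),
            loss_history=state.loss_history,
            converged=converged,
        )

    eta = state.eta
    w = _loss_only(net, data, meas_idx)
    state.loss_history.append(w)
    converged = w < b
    while not converged and len(state.loss_history) <= state.max_iter:
        _, g_act, g_rep = _loss_and_grad(net, data, meas_idx)
        if eta is None:
            gmax = max(np.max(np.abs(g_act * mask_act)), np.max(np.abs(g_rep * mask_rep)))
            kmax = max(net.k_act.max(), net.k_rep.max(), 1e-3)
            eta = 0.05 * kmax / max(gmax, 1e-300)
        for _bt in range(80):
            cand = gradient_step(net, g_act, g_rep, eta, mask_act, mask_rep, state.k_cap)
            w_new = _loss_only(cand, data, meas_idx)
            if w_new < w:
                break
            eta *= 0.5
        else:
            break  # no descent direction at machine precision
        net = cand
        w = w_new
        eta *= 1.3
        state.loss_history.append(w)
        converged = w < b
    return TrainResult(
        network=net,
        k_act=net.k_act.copy(),
        k_rep=net.k_rep.copy(),
        loss_history=state.loss_history,
        converged=converged,
    )


def refine_least_squares(
    net: TrainableNetwork,
    data: TrainingSet,
    max_iter: int = 50,
    k_cap: float = 10.0,
) -> TrainableNetwork:
    """Levenberg-Marquardt polish of the trained constants.

    Gradient descent converges slowly along ill-conditioned directions;
    since the sign-informed problem has a unique least-squares optimum,
    a few damped Gauss-Newton steps on the stacked condition residuals
    (using the same adjoint Jacobian ``dx/dK = -L^{-1} dF/dK``) finish the
    job at machine precision.  Edges are kept non-negative.
    """
    net = net.copy()
    meas_idx = np.array([net.gene_names.index(m) for m in data.measured])
    mask_act, mask_rep = _trainable_masks(net, "nonzero")
    act_idx = np.argwhere(mask_act > 0)
    rep_idx = np.argwhere(mask_rep > 0)

    def pack() -> np.ndarray:
        return np.concatenate(
            [net.k_act[tuple(act_idx.T)], net.k_rep[tuple(rep_idx.T)]]
        )

    def unpack(theta: np.ndarray) -> None:
        na = len(act_idx)
        net.k_act[tuple(act_idx.T)] = theta[:na]
        net.k_rep[tuple(rep_idx.T)] = theta[na:]

    def residuals_jac():
        rs, js = [], []
        for cond, target in zip(data.conditions, data.targets):
            x = steady_state(net, cond)
            L, dka, dkr = local_derivatives(net, x, cond)
            sens = np.linalg.solve(L, -np.column_stack(
                [_edge_cols(dka, act_idx), _edge_cols(dkr, rep_idx)]
            ))
            rs.append(x[meas_idx] - target)
            js.append(sens[meas_idx])
        return np.concatenate(rs), np.vstack(js)

    lam = 1e-3
    r, J = residuals_jac()
    w = 0.5 * float(r @ r)
    for _ in range(max_iter):
        A = J.T @ J
        g = J.T @ r
        try:
            step = np.linalg.solve(A + lam * np.diag(np.maximum(np.diag(A), 1e-30)), -g)
        except np.linalg.LinAlgError:
            break
        theta_old = pack()
        unpack(np.clip(theta_old + step, 0.0, k_cap))
        r_new, J_new = residuals_jac()
        w_new = 0.5 * float(r_new @ r_new)
        if w_new < w:
            r, J, w = r_new, J_new, w_new
            lam = max(lam * 0.3, 1e-12)
            if w < 1e-18:
                break
        else:
            unpack(theta_old)
            lam *= 10.0
            if lam > 1e8:
                break
    return net


def _edge_cols(dk: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Columns of dF/dK for the listed (source, gene) edges.

    ``dk[i, j]`` is dF_j/dK[i, j]; the full column for edge (i, j) is zero
    except at row j.
    """
    n_genes = dk.shape[1]
    out = np.zeros((n_genes, len(idx)))
    for c, (i, j) in enumerate(idx):
        out[j, c] = dk[i, j]
    return out


# ---------------------------------------------------------------------------
# benchmark machinery


def generate_ground_truth(
    n_genes: int,
    p_delete: float = 0.5,
    k_range: tuple[float, float] = (1e-3, 1e-2),
    seed: int = 0,
    nu: float = 100.0,
    delta: float = 0.1,
    k_basal: float = 0.1,
) -> TrainableNetwork:
    """Random ground-truth GRN from a fully connected digraph.

    Starting from all ``N*(N-1)`` ordered gene pairs, each edge is deleted
    independently with probability ``p_delete``; surviving edges get a
    log-uniform equilibrium constant in ``k_range`` and an
    activating/repressing role with equal probability.
    """
    if n_genes < 2 or not 0.0 <= p_delete < 1.0:
        raise ValueError("need n_genes >= 2 and 0 <= p_delete < 1")
    rng = np.random.Generator(np.random.PCG64(seed))
    names = [f"g{i+1}" for i in range(n_genes)]
    net = TrainableNetwork(
        gene_names=names,
        nu=np.full(n_genes, nu),
        delta=np.full(n_genes, delta),
        k_basal=np.full(n_genes, k_basal),
    )
    lo, hi = np.log(k_range[0]), np.log(k_range[1])
    for i in range(n_genes):
        for j in range(n_genes):
            if i == j:
                continue
            if rng.random() < p_delete:
                continue
            k = float(np.exp(rng.uniform(lo, hi)))
            if rng.random() < 0.5:
                net.k_act[i, j] = k
            else:
                net.k_rep[i, j] = k
    return net


def knockout_dataset(truth: TrainableNetwork) -> TrainingSet:
    """Steady-state levels of all genes under each single-gene knockout (N^2 values)."""
    conditions = [
        KnockoutSpec(gene=SpeciesRef(name), residual_nu=0.0)
        for name in truth.gene_names
    ]
    targets = np.array([steady_state(truth, c) for c in conditions])
    return TrainingSet(
        conditions=conditions, targets=targets, measured=list(truth.gene_names)
    )


def fully_connected_start(
    truth: TrainableNetwork, k_init: float = 3e-3, sign_known: bool = True
) -> TrainableNetwork:
    """Fully connected starting network with uniform initial constants.

    With ``sign_known`` (default) one trainable edge is instantiated per
    ordered pair: the ground-truth role for true edges (each transcription
    factor's mode of action is taken as prior knowledge) and an activating
    edge for absent pairs, whose constant must simply vanish.  This keeps
    the parameter count at ``N*(N-1)``, at or below the ``N^2`` knockout
    measurements, so the problem is determined.

    With ``sign_known=False`` both roles are instantiated per pair
    (``2*N*(N-1)`` parameters).  The N^2 knockout dataset then cannot
    identify the constants: activating and repressing edges of the same
    pair compensate along a solution manifold, so trained networks fit the
    data while retaining large spurious constants.  The option exists for
    study, not for recovery benchmarks.
    """
    start = truth.copy()
    n_in, n = start.n_inputs, start.n_genes
    start.k_act[:] = 0.0
    start.k_rep[:] = 0.0
    for i in range(n_in + n):
        for j in range(n):
            if i - n_in == j:
                continue
            if sign_known and truth.k_rep[i, j] > 0:
                start.k_rep[i, j] = k_init
            elif sign_known:
                start.k_act[i, j] = k_init
            else:
                start.k_act[i, j] = k_init
                start.k_rep[i, j] = k_init
    return start


def evaluate_topology(
    result: TrainResult, truth: TrainableNetwork, threshold: float = EDGE_THRESHOLD
) -> tuple[float, float, np.ndarray]:
    """Topology recovery metrics against the ground truth.

    Returns ``(tp_frac, fp_frac, rel_errors)``: the fraction of true
    connections recovered (inferred constant above threshold in either
    role), the fraction of absent connections spuriously retained, and the
    relative equilibrium-constant errors ``|K_inf - K_true|/K_true`` over
    true edges whose same-role constant was recovered.
    """
    n_in, n = truth.n_inputs, truth.n_genes
    ka_t = truth.k_act[n_in:, :]
    kr_t = truth.k_rep[n_in:, :]
    ka_i = result.k_act[n_in:, :]
    kr_i = result.k_rep[n_in:, :]
    offdiag = ~np.eye(n, dtype=bool)
    true_edge = ((ka_t > 0) | (kr_t > 0)) & offdiag
    inferred = ((ka_i > threshold) | (kr_i > threshold)) & offdiag

    n_true = int(true_edge.sum())
    n_absent = int((offdiag & ~true_edge).sum())
    tp = int((inferred & true_edge).sum())
    fp = int((inferred & ~true_edge).sum())
    tp_frac = tp / n_true if n_true else float("nan")
    fp_frac = fp / n_absent if n_absent else float("nan")

    errors = []
    for i in range(n):
        for j in range(n):
            if not true_edge[i, j]:
                continue
            k_true = ka_t[i, j] if ka_t[i, j] > 0 else kr_t[i, j]
            k_inf = ka_i[i, j] if ka_t[i, j] > 0 else kr_i[i, j]
            if k_inf > threshold:
                errors.append(abs(k_inf - k_true) / k_true)
    return tp_frac, fp_frac, np.asarray(errors)


def run_benchmark(
    n_genes: int = 5,
    p_delete: float = 0.5,
    n_networks: int = 4,
    seed: int = 0,
    k_range: tuple[float, float] = (1e-3, 1e-2),
    sign_known: bool = True,
    max_iter: int = 2000,
) -> dict:
    """Randomized-network knockout-inference benchmark.

    For each of ``n_networks`` random ground truths, generates the N^2
    single-knockout measurements, trains a fully connected network to deep
    convergence, prunes at the threshold and evaluates topology and
    constant recovery.  Returns per-network and average metrics (fractions
    in percent).
    """
    rows = []
    for k in range(n_networks):
        truth = generate_ground_truth(
            n_genes, p_delete=p_delete, k_range=k_range, seed=(seed, k)
        )
        data = knockout_dataset(truth)
        start = fully_connected_start(truth, sign_known=sign_known)
        b = 1e-10 * float(np.sum(data.targets**2))
        result = train(start, data, TrainState(max_iter=max_iter, bound_b=b))
        if sign_known:
            polished = refine_least_squares(result.network, data)
            result = TrainResult(
                network=polished,
                k_act=polished.k_act.copy(),
                k_rep=polished.k_rep.copy(),
                loss_history=result.loss_history,
                converged=result.converged,
            )
        tp, fp, errs = evaluate_topology(result, truth)
        rows.append(
            {
                "network": k,
                "tp_percent": 100.0 * tp,
                "fp_percent": 100.0 * fp,
                "mean_rel_error_percent": 100.0 * float(np.mean(errs))
                if errs.size
                else float("nan"),
                "final_loss": result.loss_history[-1],
                "converged": result.converged,
            }
        )
    out = {
        "networks": rows,
        "tp_percent": float(np.mean([r["tp_percent"] for r in rows])),
        "fp_percent": float(np.mean([r["fp_percent"] for r in rows])),
        "mean_rel_error_percent": float(
            np.nanmean([r["mean_rel_error_percent"] for r in rows])
        ),
    }
    return out
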