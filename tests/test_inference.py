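import numpy as np
import pytest

from grnsync import KnockoutSpec, SimConfig, SpeciesRef, run
from grnsync.inference import (
    TrainableNetwork,
    TrainingSet,
    TrainState,
    adjoint_solve,
    evaluate_topology,
    fully_connected_start,
    generate_ground_truth,
    knockout_dataset,
    local_derivatives,
    refine_least_squares,
    steady_state,
    train,
    TrainResult,
)


@pytest.fixture
def two_gene_net():
    """Input -> gene1 -> gene2 with one repressive back-edge."""
    net = TrainableNetwork(
        gene_names=["g1", "g2"],
        input_names=["I"],
        input_levels=np.array([50.0]),
    )
    net.k_act[0, 0] = 5e-3   # input activates g1
    net.k_act[1, 1] = 4e-3   # g1 activates g2
    net.k_rep[2, 0] = 2e-3   # g2 represses g1
    return net


class TestSteadyState:
    def test_basal_only_gene(self):
        net = TrainableNetwork(gene_names=["g"])
        x = steady_state(net)
        kb = net.k_basal[0]
        p_on = kb / (kb + 1.0)
        assert x[0] == pytest.approx(p_on * net.nu[0] / net.delta[0], rel=1e-6)

    def test_matches_engine_scenario1_fixed_point(self, two_gene_net):
        x = steady_state(two_gene_net)
        spec = two_gene_net.to_network_spec()
        traj = run(spec, SimConfig(dt=50.0, t_end=500_000.0, scenario=1, seed=0))
        for j, name in enumerate(two_gene_net.gene_names):
            assert traj.series(name)[-1] == pytest.approx(x[j], rel=1e-5)

    def test_knockout_zeroes_the_gene(self, two_gene_net):
        x = steady_state(two_gene_net, KnockoutSpec(SpeciesRef("g1"), 0.0))
        assert x[0] == pytest.approx(0.0, abs=1e-9)
        assert x[1] < steady_state(two_gene_net)[1]


class TestDerivatives:
    def test_jacobian_and_sensitivities_match_finite_differences(self):
        net = generate_ground_truth(5, p_delete=0.3, seed=7)
        x = steady_state(net)
        nu, levels = net.condition_arrays(None)
        L, dka, dkr = local_derivatives(net, x)
        eps = 1e-6
        for k in range(net.n_genes):
            h = eps * max(1.0, x[k])
            xp, xm = x.copy(), x.copy()
            xp[k] += h
            xm[k] -= h
            fd = (net.response(xp, nu, levels) - net.response(xm, nu, levels)) / (2 * h)
            assert np.allclose(fd, L[:, k], rtol=1e-4, atol=1e-9)
        for i, j in [(0, 1), (2, 3), (4, 0)]:
            h = 1e-7
            for mat, dk in (("k_act", dka), ("k_rep", dkr)):
                netp, netm = net.copy(), net.copy()
                getattr(netp, mat)[i, j] += h
                getattr(netm, mat)[i, j] -= h
                fd = (
                    netp.response(x, nu, levels) - netm.response(x, nu, levels)
                ) / (2 * h)
                assert fd[j] == pytest.approx(dk[i, j], rel=1e-4, abs=1e-12)

    def test_unregulated_gene_reduces_to_linear_decay(self):
        net = TrainableNetwork(gene_names=["g"])
        x = steady_state(net)
        L, _, _ = local_derivatives(net, x)
        assert L[0, 0] == pytest.approx(-net.delta[0])


class TestAdjoint:
    def test_diagonal_system(self):
        L = np.diag([-2.0, -4.0])
        z = adjoint_solve(L, np.array([1.0, 2.0]))
        assert z == pytest.approx([-0.5, -0.5])

    def test_zero_residual_gives_zero_adjoint(self):
        L = np.array([[-1.0, 0.3], [0.2, -2.0]])
        assert adjoint_solve(L, np.zeros(2)) == pytest.approx(np.zeros(2))

    def test_random_system_residual(self, rng):
        L = rng.standard_normal((5, 5)) - 5 * np.eye(5)
        r = rng.standard_normal(5)
        z = adjoint_solve(L, r)
        assert np.linalg.norm(L.T @ z - r) < 1e-10


class TestTraining:
    def test_truth_initialized_training_terminates_immediately(self):
        truth = generate_ground_truth(4, p_delete=0.5, seed=3)
        data = knockout_dataset(truth)
        res = train(truth, data, TrainState(max_iter=50))
        assert res.converged and len(res.loss_history) == 1

    def test_two_gene_constants_recovered_from_misspecified_start(self, two_gene_net):
        # two input conditions, start with every constant a factor 10 off
        conditions = [{"I": 20.0}, {"I": 200.0}]
        targets = np.array([steady_state(two_gene_net, c) for c in conditions])
        data = TrainingSet(conditions=conditions, targets=targets,
                           measured=["g1", "g2"])
        start = two_gene_net.copy()
        start.k_act[start.k_act > 0] *= 10.0
        start.k_rep[start.k_rep > 0] /= 10.0
        res = train(start, data, TrainState(max_iter=4000))
        polished = refine_least_squares(res.network, data)
        for mat in ("k_act", "k_rep"):
            t = getattr(two_gene_net, mat)
            got = getattr(polished, mat)
            mask = t > 0
            assert np.all(np.abs(got[mask] - t[mask]) / t[mask] < 0.05)

    def test_loss_decreases_under_backtracking_delta_rule(self):
        truth = generate_ground_truth(3, p_delete=0.4, seed=5)
        data = knockout_dataset(truth)
        start = fully_connected_start(truth)
        res = train(start, data, TrainState(max_iter=40), method="backtracking")
        assert res.loss_history[-1] < res.loss_history[0]
        assert all(np.diff(res.loss_history) <= 1e-12)


class TestGroundTruthGeneration:
    def test_no_deletion_keeps_full_digraph(self):
        net = generate_ground_truth(4, p_delete=0.0, seed=1)
        edges = ((net.k_act > 0) | (net.k_rep > 0)).sum()
        assert edges == 4 * 3

    def test_deletion_probability_thins_edges(self):
        counts = [
            ((generate_ground_truth(6, p_delete=0.8, seed=s).k_act > 0)
             | (generate_ground_truth(6, p_delete=0.8, seed=s).k_rep > 0)).sum()
            for s in range(20)
        ]
        mean = np.mean(counts)
        expected = 30 * 0.2
        assert abs(mean - expected) < 3 * np.sqrt(30 * 0.2 * 0.8 / 20)

    def test_constants_within_sampling_range(self):
        net = generate_ground_truth(6, p_delete=0.3, seed=2, k_range=(1e-3, 1e-2))
        ks = np.concatenate([net.k_act[net.k_act > 0], net.k_rep[net.k_rep > 0]])
        assert np.all((ks >= 1e-3) & (ks <= 1e-2))

    def test_dataset_shape_and_determinism(self):
        truth = generate_ground_truth(3, p_delete=0.5, seed=9)
        d1 = knockout_dataset(truth)
        d2 = knockout_dataset(truth)
        assert d1.targets.shape == (3, 3)
        assert np.array_equal(d1.targets, d2.targets)
        for i, cond in enumerate(d1.conditions):
            j = truth.gene_names.index(cond.gene.name)
            assert d1.targets[i, j] == pytest.approx(0.0, abs=1e-9)


class TestTopologyEvaluation:
    def test_perfect_recovery(self):
        truth = generate_ground_truth(4, p_delete=0.5, seed=4)
        res = TrainResult(
            network=truth, k_act=truth.k_act.copy(), k_rep=truth.k_rep.copy(),
            loss_history=[0.0], converged=True,
        )
        tp, fp, errs = evaluate_topology(res, truth)
        assert tp == 1.0 and fp == 0.0
        assert np.all(errs == 0.0)

    def test_empty_inference(self):
        truth = generate_ground_truth(4, p_delete=0.5, seed=4)
        empty = truth.copy()
        empty.k_act[:] = 0.0
        empty.k_rep[:] = 0.0
        res = TrainResult(
            network=empty, k_act=empty.k_act, k_rep=empty.k_rep,
            loss_history=[1.0], converged=False,
        )
        tp, fp, errs = evaluate_topology(res, truth)
        assert tp == 0.0 and fp == 0.0 and errs.size == 0
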