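import math

import numpy as np
import pytest

from grnsync import InputSpec, SimConfig, SpeciesRef, run
from grnsync.engine import evaluate_input
from grnsync.fixtures import repressive_cascade, two_enzyme_loop
from grnsync.model import GeneSpec, NetworkSpec, TFBindingSpec


class TestEvaluateInput:
    def test_constant(self):
        inp = InputSpec(SpeciesRef("A", "input"), "constant", amplitude=100.0)
        assert evaluate_input(inp, 0.0) == 100.0
        assert evaluate_input(inp, 12345.6) == 100.0

    def test_sinusoidal_clipped_at_zero(self):
        inp = InputSpec(
            SpeciesRef("A", "input"), "sinusoidal",
            amplitude=20.0, baseline=10.0, period=100.0,
        )
        assert evaluate_input(inp, 75.0) == 0.0  # trough: 10 - 20
        assert evaluate_input(inp, 25.0) == pytest.approx(30.0)

    def test_rectangular_duty_cycle(self):
        inp = InputSpec(
            SpeciesRef("A", "input"), "rectangular",
            amplitude=50.0, baseline=5.0, period=200.0,
        )
        assert evaluate_input(inp, 10.0) == 55.0   # on half
        assert evaluate_input(inp, 150.0) == 5.0   # off half


class TestScenario1:
    def test_constitutive_gene_matches_closed_form(self, constitutive_gene_network):
        cfg = SimConfig(dt=10.0, t_end=5000.0, scenario=1, seed=0)
        traj = run(constitutive_gene_network, cfg)
        nu, delta = 0.05, 1e-3
        expected = nu / delta * (1.0 - np.exp(-delta * traj.times))
        assert np.allclose(traj.series("P"), expected, rtol=1e-12, atol=1e-12)

    def test_activated_gene_reaches_promoter_limited_level(
        self, single_activated_gene_network
    ):
        cfg = SimConfig(dt=10.0, t_end=50_000.0, scenario=1, seed=0)
        traj = run(single_activated_gene_network, cfg)
        p_on = 0.01 / (0.01 + 0.01)
        assert traj.series("P")[-1] == pytest.approx(p_on * 0.05 / 1e-3, rel=1e-6)


class TestDeterminismAndIsolation:
    def test_identical_seed_bitwise_identical(self):
        spec = repressive_cascade(100.0, "slow")
        cfg = SimConfig(dt=5.0, t_end=5000.0, scenario=3, seed=42)
        a = run(spec, cfg)
        b = run(spec, cfg)
        assert np.array_equal(a.abundances, b.abundances)

    def test_different_seed_differs(self):
        spec = repressive_cascade(100.0, "slow")
        a = run(spec, SimConfig(dt=5.0, t_end=5000.0, scenario=3, seed=1))
        b = run(spec, SimConfig(dt=5.0, t_end=5000.0, scenario=3, seed=2))
        assert not np.array_equal(a.abundances, b.abundances)

    @pytest.mark.parametrize("scenario", [1, 2, 3])
    def test_element_evaluation_order_is_irrelevant(self, scenario):
        spec = repressive_cascade(100.0, "slow")
        cfg = SimConfig(dt=5.0, t_end=5000.0, scenario=scenario, seed=7)
        a = run(spec, cfg)
        b = run(spec, cfg, eval_order=[3, 1, 0, 2])
        assert np.array_equal(a.abundances, b.abundances)


class TestWarnings:
    def test_step_criterion_fires_on_violating_config(self):
        gene = GeneSpec(product=SpeciesRef("P"), nu=5.0, delta=0.01)
        spec = NetworkSpec(genes=(gene,))
        traj = run(spec, SimConfig(dt=1.0, t_end=100.0, scenario=1, seed=0))
        assert any("per-step production" in w[2] for w in traj.warnings)

    def test_compliant_config_is_silent(self):
        # p_on * nu * dt stays below 1 for every gene at this step size
        spec = repressive_cascade(100.0, "slow")
        traj = run(spec, SimConfig(dt=5.0, t_end=10_000.0, scenario=1, seed=0))
        assert traj.warnings == []

    def test_flux_criterion_fires_on_abrupt_flux_change(self):
        spec = two_enzyme_loop(nu_src=0.8)
        traj = run(spec, SimConfig(dt=500.0, t_end=20_000.0, scenario=1, seed=0))
        assert any("flux change" in w[2] for w in traj.warnings)


class TestDelaysInNetwork:
    def test_fixed_queue_shifts_reported_output(self):
        gene = GeneSpec(
            product=SpeciesRef("P"), nu=0.05, delta=1e-3, fixed_delay_steps=5
        )
        spec = NetworkSpec(genes=(gene,))
        delayed = run(spec, SimConfig(dt=10.0, t_end=2000.0, scenario=1, seed=0))
        plain = run(
            NetworkSpec(genes=(GeneSpec(product=SpeciesRef("P"), nu=0.05, delta=1e-3),)),
            SimConfig(dt=10.0, t_end=2000.0, scenario=1, seed=0),
        )
        assert np.allclose(delayed.series("P")[6:], plain.series("P")[1:-5])
        assert np.all(delayed.series("P")[:5] == 0.0)

    def test_rate_limiting_chain_delays_but_preserves_steady_state(self):
        base = GeneSpec(product=SpeciesRef("P"), nu=0.05, delta=1e-3)
        chain = GeneSpec(
            product=SpeciesRef("P"), nu=0.05, delta=1e-3,
            rate_limiting_betas=(5e-3,),
        )
        cfg = SimConfig(dt=10.0, t_end=40_000.0, scenario=1, seed=0)
        t_base = run(NetworkSpec(genes=(base,)), cfg)
        t_chain = run(NetworkSpec(genes=(chain,)), cfg)
        # same steady state, slower rise
        assert t_chain.series("P")[-1] == pytest.approx(
            t_base.series("P")[-1], rel=1e-3
        )
        mid = t_base.times.size // 8
        assert t_chain.series("P")[mid] < t_base.series("P")[mid]


class TestDimerElements:
    def _hetero_spec(self):
        from grnsync.model import ReactionSpec

        a = SpeciesRef("A")
        b = SpeciesRef("B", "input")
        gene = GeneSpec(product=a, nu=0.05, delta=1e-3)
        dim = ReactionSpec(
            kind="hetero_dimer", substrates=(a, b),
            complex=SpeciesRef("D", "complex"),
            lam=1e-4, mu=5e-3, deltas=(1e-3, 0.0),
        )
        return NetworkSpec(
            inputs=(InputSpec(b, "constant", amplitude=30.0),),
            genes=(gene,), reactions=(dim,),
        )

    def test_hetero_dimer_steady_state_matches_global_ode(self):
        from grnsync.reference import solve_ode

        spec = self._hetero_spec()
        ode = solve_ode(spec, 40_000.0, t_eval=[0.0, 40_000.0],
                        rtol=1e-10, atol=1e-10)
        for dt in (2.0, 10.0):
            tr = run(spec, SimConfig(dt=dt, t_end=40_000.0, scenario=1, seed=0,
                                     record_every=100))
            assert tr.series("A")[-1] == pytest.approx(ode.series("A")[-1], rel=1e-4)
            assert tr.series("D")[-1] == pytest.approx(ode.series("D")[-1], rel=1e-4)

    def test_homodimer_steady_state_matches_global_ode(self):
        from grnsync.model import ReactionSpec
        from grnsync.reference import solve_ode

        a = SpeciesRef("A")
        gene = GeneSpec(product=a, nu=0.05, delta=1e-3)
        homo = ReactionSpec(
            kind="homo_dimer", substrates=(a,),
            complex=SpeciesRef("D2", "complex"),
            lam=2e-5, mu=5e-3, deltas=(1e-3,),
        )
        spec = NetworkSpec(genes=(gene,), reactions=(homo,))
        ode = solve_ode(spec, 40_000.0, t_eval=[0.0, 40_000.0],
                        rtol=1e-10, atol=1e-10)
        tr = run(spec, SimConfig(dt=2.0, t_end=40_000.0, scenario=1, seed=0,
                                 record_every=100))
        assert tr.series("A")[-1] == pytest.approx(ode.series("A")[-1], rel=1e-4)
        assert tr.series("D2")[-1] == pytest.approx(ode.series("D2")[-1], rel=1e-4)


def test_abort_on_nonfinite_abundance():
    gene = GeneSpec(
        product=SpeciesRef("P"), nu=1e-3, delta=1e-3,
        bindings=(TFBindingSpec(SpeciesRef("A", "input"), 1e-4, 1e-2),),
    )
    inp = InputSpec(SpeciesRef("A", "input"), "constant", amplitude=float("inf"))
    spec = NetworkSpec(inputs=(inp,), genes=(gene,))
    with pytest.raises((FloatingPointError, ValueError)):
        run(spec, SimConfig(dt=10.0, t_end=100.0, scenario=1, seed=0))


def test_trajectory_tsv_round_trip(tmp_path):
    spec = repressive_cascade(100.0, "slow")
    traj = run(spec, SimConfig(dt=10.0, t_end=2000.0, scenario=1, seed=0))
    traj.to_tsv(tmp_path / "t.tsv")
    from grnsync.trajectory import Trajectory

    back = Trajectory.from_tsv(tmp_path / "t.tsv")
    assert back.species == traj.species
    assert np.allclose(back.abundances, traj.abundances)
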