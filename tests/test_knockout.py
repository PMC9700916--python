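"""Link-knockout attribution, mutant rollouts, pruning and majority voting."""

import numpy as np
import pytest

import grnlink as gl
from grnlink.knockout import VoteTable, knockout_deltas


class ConstantModel:
    """Stub synthesis model whose output ignores the state entirely."""

    def __init__(self, n=3):
        self.gene_names = [f"G{i}" for i in range(n)]
        self.clamped_genes = frozenset()
        self.lam, self.dt = 1.0, 1.0

    @property
    def n_genes(self):
        return len(self.gene_names)

    def synthesis(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.full((X.shape[0], self.n_genes), 0.5)


class TestDeltas:
    def test_mu_one_is_exactly_zero(self, table1):
        oracle = gl.HillSynthesisOracle(table1)
        states = np.random.default_rng(0).uniform(0.1, 2.0, size=(20, 3))
        for i in range(3):
            for j in (1, 2):
                assert gl.link_knockout_delta(oracle, states, i, j, mu=1.0) == 0.0

    def test_independent_input_gives_zero(self, iffl_topology):
        m = gl.sample_hill_parameters(iffl_topology, rng_seed=3)
        oracle = gl.HillSynthesisOracle(m)
        states = np.random.default_rng(1).uniform(0.1, 2.0, size=(15, 3))
        # the intermediate (gene 1) does not regulate itself
        assert gl.link_knockout_delta(oracle, states, 1, 1, mu=0.0) == pytest.approx(0.0, abs=1e-15)

    def test_activator_delta_matches_closed_form(self, table1):
        oracle = gl.HillSynthesisOracle(table1)
        states = np.random.default_rng(2).uniform(0.2, 1.5, size=(25, 3))
        got = gl.link_knockout_delta(oracle, states, 0, 2, mu=0.0)
        # knocking the input out of f_3 removes its activation term only
        expected = np.mean(
            gl.hill_activation(states[:, 0], 4.242, 1.198, 2)
            * gl.hill_inhibition(states[:, 2], 0.231, 2)
        )
        assert got == pytest.approx(expected, rel=1e-12)

    def test_full_knockout_dominates_partial_discounts(self, table1):
        oracle = gl.HillSynthesisOracle(table1)
        states = np.random.default_rng(3).uniform(0.2, 1.5, size=(25, 3))
        for i, j, _ in table1.edges():
            mags = [
                abs(gl.link_knockout_delta(oracle, states, i, j, mu=mu))
                for mu in (0.0, 0.3, 0.7)
            ]
            assert mags[0] >= mags[1] >= mags[2]

    def test_sign_recovery_on_random_hill_models(self):
        rng = np.random.default_rng(0)
        for seed in range(5):
            cfg = gl.GeneratorConfig(seed=seed, n_genes=8, n_tfs=8, target_density=0.25)
            model, _ = gl.generate_random_grn(cfg)
            oracle = gl.HillSynthesisOracle(model)
            states = rng.uniform(0.1, 2.0, size=(30, 8))
            kd = knockout_deltas(oracle, states, mu=0.0)
            for i, j, sign in model.edges():
                assert np.sign(kd.delta[i, j]) == sign

    def test_invalid_mu(self, table1):
        oracle = gl.HillSynthesisOracle(table1)
        with pytest.raises(ValueError):
            gl.link_knockout_delta(oracle, np.ones((2, 3)), 0, 1, mu=1.5)


class TestInferNetwork:
    def test_oracle_recovers_reference_edges(self, table1):
        oracle = gl.HillSynthesisOracle(table1)
        ts = gl.simulate(
            table1, np.zeros(3), 30.0, dt_int=0.01,
            inputs={0: lambda t: 1.5 if t < 15 else 0.5}, sample_dt=0.25,
        )
        net = gl.infer_network(oracle, ts)
        assert net.signs[0, 2] == 1  # input activates the output
        assert net.signs[2, 2] == -1  # output self-inhibition
        assert np.all(net.signs[:, 0] == 0)  # nothing targets the clamped input

    def test_constant_model_yields_empty_network(self):
        ts = gl.ExpressionTimeSeries(
            ["G0", "G1", "G2"], np.arange(10.0),
            np.random.default_rng(0).uniform(0.1, 0.9, (3, 10)),
        )
        net = gl.infer_network(ConstantModel(), ts)
        assert net.n_edges == 0
        assert np.all(net.weights == 0.0)

    def test_candidate_ranking_covers_unclamped_targets(self, table1_fit):
        _, model, _, scaled = table1_fit
        net = gl.infer_network(model, scaled)
        targets = [j for j in range(3) if j not in model.clamped_genes]
        ranked = net.ranked_candidates(targets)
        assert len(ranked) == 3 * 2  # regulators x non-clamped targets

    def test_top_k_keeps_exactly_k(self, table1_fit):
        _, model, _, scaled = table1_fit
        net = gl.infer_network(model, scaled, top_k=4)
        assert net.n_edges == 4


class TestMutants:
    def test_mu_one_equals_wild_type(self, table1_fit):
        _, model, _, scaled = table1_fit
        g0 = scaled[0].values[:, 0]
        inputs = {0: scaled[0].values[0, :21]}
        wt = gl.rollout(model, g0, 20, inputs=inputs)
        mut = gl.simulate_mutant(model, (2, 1), 1.0, g0, 20 * model.dt, inputs=inputs)
        assert np.array_equal(wt.values, mut.values)

    def test_removing_repression_raises_the_target(self, table1_fit):
        hill, model, _, scaled = table1_fit
        g0 = scaled[0].values[:, 0]
        inputs = {0: scaled[0].values[0, :21]}
        wt = gl.rollout(model, g0, 20, inputs=inputs)
        mut = gl.simulate_mutant(model, (2, 1), 0.0, g0, 20 * model.dt, inputs=inputs)
        # the output gene represses the intermediate: cut the brake, g2 rises
        assert mut.values[1].mean() > wt.values[1].mean() + 0.05

    def test_nn_mutant_tracks_fine_hill_mutant(self, table1_fit):
        hill, model, _, scaled = table1_fit
        sc = model.scaler
        dt = model.dt
        lo_raw, hi_raw = 0.5, 1.25
        base_raw = gl.simulate(
            hill, np.zeros(3), 15.0, inputs={0: lambda t: lo_raw}, sample_dt=15.0
        ).values[:, -1]
        g0 = sc.transform_states(base_raw)
        n_steps = 40
        inp_norm = np.full(n_steps + 1, sc.transform_states(np.array([lo_raw, 0, 0]))[0])
        inp_norm[:20] = sc.transform_states(np.array([hi_raw, 0, 0]))[0]
        # knock the weak intermediate->output activation; dynamics stay in range
        mut_nn = gl.simulate_mutant(model, (1, 2), 0.0, g0, n_steps * dt, inputs={0: inp_norm})
        mask = np.ones((3, 3))
        mask[1, 2] = 0.0
        mut_hill = gl.simulate(
            hill, base_raw, n_steps * dt, dt_int=0.01,
            inputs={0: lambda t: hi_raw if t / dt < 20 - 1e-9 else lo_raw},
            sample_dt=dt, input_mask=mask,
        )
        diff = np.abs(mut_nn.values - sc.transform_series(mut_hill).values)
        # the learned map folds within-step dynamics of the intact circuit
        # into f, so a small systematic gap beyond fit error is expected
        assert diff.max() <= 0.2


class TestStructureRecovery:
    def test_minimal_iffl_recovered_across_seeds(self, iffl_topology):
        """Networks trained on the minimal adapting feed-forward circuit
        place its three true edges, correctly signed, at the top of the
        knockout ranking in nearly every seed."""
        hill = gl.make_preset_circuit("adapting_ifl")
        hits = 0
        for seed in range(10):
            cfg = gl.GeneratorConfig(seed=100 + seed, preset="adapting_ifl")
            series = gl.generate_timeseries(hill, cfg)
            model, _, scaled = gl.fit_dynamics(series, epochs=2000, rng_seed=seed)
            net = gl.infer_network(model, scaled, top_k=3)
            hits += np.array_equal(net.signs, iffl_topology)
        assert hits >= 8


class TestPruning:
    def test_already_minimal_network_is_a_fixed_point(self):
        hill = gl.make_preset_circuit("adapting_ifl")
        cfg = gl.GeneratorConfig(seed=5, preset="adapting_ifl")
        series = gl.generate_timeseries(hill, cfg)
        scaler = gl.fit_scaler(series)
        scaled = [scaler.transform_series(s) for s in series]
        oracle = gl.HillSynthesisOracle(hill, scaler)
        oracle.dt = 0.25
        lo = scaler.transform_states(np.array([0.5, 0, 0]))[0]
        hi = scaler.transform_states(np.array([1.5, 0, 0]))[0]
        spec = gl.FunctionSpec(0, 2, baseline=lo, step=hi - lo, t_pre=15.0, t_post=30.0)
        history = gl.prune_network(oracle, scaled, spec)
        assert len(history) == 1
        assert history[0][0].edge_set() == {(0, 1), (0, 2), (1, 2)}

    def test_missing_function_raises(self, table1_fit):
        # the reference circuit does not adapt to a sustained step
        _, model, _, scaled = table1_fit
        sc = model.scaler
        lo = sc.transform_states(np.array([0.5, 0, 0]))[0]
        hi = sc.transform_states(np.array([1.5, 0, 0]))[0]
        spec = gl.FunctionSpec(0, 2, baseline=lo, step=hi - lo)
        with pytest.raises(gl.PruningError):
            gl.prune_network(model, scaled, spec)


class TestVoting:
    def test_counts_partition_and_plurality(self):
        counts = np.zeros((2, 2, 3), dtype=int)
        counts[0, 1] = (39, 0, 1)
        counts[1, 0] = (1, 3, 36)
        counts[0, 0] = (0, 40, 0)
        counts[1, 1] = (20, 0, 20)  # ambiguous -> null
        table = VoteTable(["A", "B"], counts, 40)
        net = table.plurality_network()
        assert net.signs[0, 1] == 1
        assert net.signs[1, 0] == -1
        assert net.signs[0, 0] == 0
        assert net.signs[1, 1] == 0

    def test_injected_models_vote_unanimously(self, table1):
        oracle = gl.HillSynthesisOracle(table1)
        ts = gl.simulate(
            table1, np.zeros(3), 20.0, dt_int=0.01,
            inputs={0: lambda t: 1.2 if t < 10 else 0.5}, sample_dt=0.5,
        )
        table, majority = gl.repeated_vote(ts, n_repeats=4, models=[oracle] * 4)
        assert np.all(table.counts.sum(axis=2) == 4)
        assert set(np.unique(table.counts)) <= {0, 4}
        assert majority.signs[0, 2] == 1
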