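"""Hill kinetics, Euler integration, parameter sampling and adaptation scoring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import grnlink as gl
from grnlink.hill import AdaptationScreen


class TestHillTerms:
    @pytest.mark.parametrize(
        "g,b,K,n,expected",
        [
            (0.0, 4.242, 1.198, 2, 0.0),  # no regulator, no synthesis
            (1.198, 4.242, 1.198, 2, 4.242 / 2),  # half-saturation
            (0.664, 0.496, 0.664, 3, 0.496 / 2),
            (2.0, 1.0, 1.0, 2, 0.8),
        ],
    )
    def test_activation_values(self, g, b, K, n, expected):
        assert gl.hill_activation(g, b, K, n) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "g,K,n,expected",
        [
            (0.0, 0.166, 2, 1.0),
            (0.166, 0.166, 2, 0.5),
            (1e9, 0.231, 2, 0.0),
        ],
    )
    def test_inhibition_values(self, g, K, n, expected):
        assert gl.hill_inhibition(g, K, n) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "call",
        [
            lambda: gl.hill_activation(-0.1, 1.0, 1.0),
            lambda: gl.hill_activation(1.0, 0.0, 1.0),
            lambda: gl.hill_activation(1.0, 1.0, -2.0),
            lambda: gl.hill_inhibition(-1.0, 1.0),
            lambda: gl.hill_inhibition(1.0, 0.0),
        ],
    )
    def test_domain_errors(self, call):
        with pytest.raises(ValueError):
            call()

    @given(
        g1=st.floats(0, 50),
        g2=st.floats(0, 50),
        b=st.floats(0.01, 10),
        K=st.floats(0.01, 10),
    )
    @settings(derandomize=True, max_examples=80, deadline=None)
    def test_monotone_and_bounded(self, g1, g2, b, K):
        lo, hi = sorted((g1, g2))
        a_lo, a_hi = gl.hill_activation(lo, b, K), gl.hill_activation(hi, b, K)
        assert 0.0 <= a_lo <= a_hi < b or a_lo == a_hi
        i_lo, i_hi = gl.hill_inhibition(lo, K), gl.hill_inhibition(hi, K)
        assert 1.0 >= i_lo >= i_hi > 0.0


class TestSynthesisRate:
    def test_table1_direct_evaluation(self, table1):
        # f_3 at state (1,0,0): only the input->output activation contributes
        f = gl.synthesis_rate(table1, np.array([1.0, 0.0, 0.0]))
        expected = 4.242 * 1.0 / (1.198**2 + 1.0)
        assert f[2] == pytest.approx(expected, rel=1e-12)
        assert f[2] == pytest.approx(1.742, abs=5e-4)

    def test_single_activator_reduces_to_hill_term(self):
        adj = np.zeros((2, 2), dtype=int)
        adj[0, 1] = 1
        b = np.ones((2, 2)) * 1.7
        K = np.ones((2, 2)) * 0.9
        m = gl.HillModel(["A", "B"], adj, b, K, n=2)
        state = np.array([1.3, 0.4])
        assert m.synthesis(state)[1] == pytest.approx(
            gl.hill_activation(1.3, 1.7, 0.9, 2), rel=1e-12
        )

    def test_inhibitor_saturation_annihilates(self, table1):
        f = table1.synthesis(np.array([1.0, 1.0, 1e6]))
        assert f[2] == pytest.approx(0.0, abs=1e-9)

    def test_no_activator_means_no_synthesis(self, iffl_topology):
        m = gl.sample_hill_parameters(iffl_topology, rng_seed=0)
        # gene 0 (the input) has no incoming activation at all
        assert m.synthesis(np.array([1.0, 1.0, 1.0]))[0] == 0.0

    def test_dimension_mismatch(self, table1):
        with pytest.raises(ValueError):
            table1.synthesis(np.array([1.0, 2.0]))

    @given(state=st.lists(st.floats(0, 10), min_size=3, max_size=3))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_saturation_bound(self, table1, state):
        f = table1.synthesis(np.array(state))
        act = table1.adjacency == 1
        bound = np.where(act, table1.b, 0.0).sum(axis=0)
        assert np.all(f >= 0.0) and np.all(f <= bound + 1e-12)


class TestSimulate:
    def _decay_model(self):
        adj = np.zeros((2, 2), dtype=int)
        return gl.HillModel(["A", "B"], adj, np.ones((2, 2)), np.ones((2, 2)), lam=1.0)

    def test_pure_decay_matches_closed_form(self):
        m = self._decay_model()
        ts = gl.simulate(m, np.array([1.0, 1.0]), 1.0, dt_int=0.001)
        assert ts.values[0, -1] == pytest.approx(np.e**-1, abs=1e-3)

    def test_decay_error_halves_with_dt(self):
        m = self._decay_model()
        errs = []
        for dt in (0.02, 0.01):
            ts = gl.simulate(m, np.array([1.0, 1.0]), 1.0, dt_int=dt)
            errs.append(abs(ts.values[0, -1] - np.e**-1))
        ratio = errs[0] / errs[1]
        assert 1.6 <= ratio <= 2.4

    def test_steady_state_equals_synthesis_over_lambda(self):
        adj = np.zeros((2, 2), dtype=int)
        adj[0, 1] = 1
        m = gl.HillModel(
            ["in", "out"], adj, np.ones((2, 2)), np.ones((2, 2)),
            n=2, lam=1.0, clamped_genes=frozenset({0}),
        )
        ts = gl.simulate(m, np.zeros(2), 25.0, dt_int=0.01, inputs={0: lambda t: 2.0})
        assert ts.values[1, -1] == pytest.approx(0.8, abs=1e-3)  # 1*4/(1+4)

    def test_all_clamped_returns_imposed_trajectories(self):
        adj = np.zeros((2, 2), dtype=int)
        m = gl.HillModel(
            ["A", "B"], adj, np.ones((2, 2)), np.ones((2, 2)),
            clamped_genes=frozenset({0, 1}),
        )
        ts = gl.simulate(
            m, np.zeros(2), 1.0, dt_int=0.1,
            inputs={0: lambda t: 1 + t, 1: lambda t: 2.0},
        )
        assert np.allclose(ts.values[0], 1 + ts.times)
        assert np.allclose(ts.values[1], 2.0)

    def test_non_finite_state_names_the_step(self):
        adj = np.zeros((2, 2), dtype=int)
        m = gl.HillModel(
            ["A", "B"], adj, np.ones((2, 2)), np.ones((2, 2)),
            clamped_genes=frozenset({0}),
        )
        with pytest.raises(gl.IntegrationError, match="gene A at step"):
            gl.simulate(
                m, np.zeros(2), 1.0, dt_int=0.1,
                inputs={0: lambda t: np.nan if t > 0.5 else 1.0},
            )


class TestParameterSampling:
    def test_unit_exponential_mean(self):
        adj = np.ones((100, 100), dtype=int)
        np.fill_diagonal(adj, 0)
        m = gl.sample_hill_parameters(adj, rng_seed=42)
        ks = m.K[adj != 0]
        n = ks.size
        assert ks.mean() == pytest.approx(1.0, abs=3.0 / np.sqrt(n))
        assert np.all(ks > 0) and np.all(m.b[adj == 1] > 0)

    def test_seed_determinism(self, iffl_topology):
        m1 = gl.sample_hill_parameters(iffl_topology, rng_seed=7)
        m2 = gl.sample_hill_parameters(iffl_topology, rng_seed=7)
        assert np.array_equal(m1.b, m2.b) and np.array_equal(m1.K, m2.K)


class TestAdaptationScoring:
    def test_constant_trajectory(self):
        ts = gl.ExpressionTimeSeries(["a", "b"], np.arange(20.0), np.full((2, 20), 0.7))
        m = gl.score_adaptation(ts, "b", 5.0)
        assert m.sensitivity == 0.0 and m.adaptation_error == 0.0

    def test_constructed_peak_and_offset(self):
        times = np.arange(101.0)
        trace = np.full(101, 1.0)
        trace[20:] = 1.2 + (3.0 - 1.2) * np.exp(-(times[20:] - 20) / 5.0)
        trace[20] = 3.0
        ts = gl.ExpressionTimeSeries(["out"], times, trace[None, :].repeat(1, axis=0))
        m = gl.score_adaptation(ts, "out", 19.0)
        assert m.baseline == pytest.approx(1.0)
        assert m.sensitivity == pytest.approx(2.0, abs=1e-9)
        assert m.adaptation_error == pytest.approx(0.2, abs=1e-6)
        assert m.peak_time == pytest.approx(20.0)

    def test_invariant_to_constant_extra_gene(self):
        times = np.arange(50.0)
        trace = 1.0 + np.exp(-((times - 10) ** 2) / 4.0)
        ts1 = gl.ExpressionTimeSeries(["out"], times, trace[None, :])
        ts2 = gl.ExpressionTimeSeries(
            ["out", "const"], times, np.vstack([trace, np.full(50, 0.3)])
        )
        m1 = gl.score_adaptation(ts1, "out", 5.0)
        m2 = gl.score_adaptation(ts2, "out", 5.0)
        assert (m1.sensitivity, m1.adaptation_error) == (m2.sensitivity, m2.adaptation_error)

    def test_unknown_gene_and_unsettled_flag(self):
        times = np.arange(30.0)
        ts = gl.ExpressionTimeSeries(["out"], times, (0.1 * times)[None, :])
        with pytest.raises(KeyError):
            gl.score_adaptation(ts, "nope", 5.0)
        assert not gl.score_adaptation(ts, "out", 5.0).settled


class TestTopologyScreen:
    def test_isolated_output_never_responds(self):
        topo = np.zeros((3, 3), dtype=int)
        topo[0, 1] = 1  # input drives only the intermediate; output is isolated
        assert gl.topology_success_count(topo, 2000, rng_seed=1) == 0

    def test_screen_is_seed_deterministic(self, iffl_topology):
        c1 = gl.topology_success_count(iffl_topology, 3000, rng_seed=9)
        c2 = gl.topology_success_count(iffl_topology, 3000, rng_seed=9)
        assert c1 == c2

    def test_scaled_run_consistent_with_reference_rate(self, iffl_topology):
        """A small screen's count is binomially consistent with a larger one."""
        big_n, small_n = 20000, 4000
        big = gl.topology_success_count(iffl_topology, big_n, rng_seed=11)
        small = gl.topology_success_count(iffl_topology, small_n, rng_seed=12)
        rate = big / big_n
        sd = np.sqrt(small_n * rate * (1 - rate))
        assert abs(small - small_n * rate) <= 4 * sd + 1

    def test_screen_thresholds_object(self):
        s = AdaptationScreen(step=2.0)
        assert s.passes(sensitivity=0.5, adaptation_error=0.04)
        assert not s.passes(sensitivity=0.3, adaptation_error=0.04)  # peak too small
        assert not s.passes(sensitivity=0.5, adaptation_error=0.06)  # poor precision
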