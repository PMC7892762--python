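"""Simulation tests: LIF dynamics, delays, and the modular/monolithic
equivalence that underpins divide-and-conquer scheduling."""

import numpy as np
import pytest
import scipy.sparse as sp

from modlsm import (
    LIFParams,
    ModuleGraph,
    Network,
    NetworkState,
    NeuronMeta,
    SimulationResult,
    SynapseSet,
    extract_features,
    lif_step,
    ms_to_steps,
    simulate_modular,
    simulate_monolithic,
)
from conftest import make_chain_network


def make_input(n_pix, n_steps, seed=0, density=0.05):
    rng = np.random.default_rng(seed)
    return (rng.random((n_pix, n_steps)) < density).astype(np.float64)


def single_neuron_net():
    meta = NeuronMeta(np.array([True]), np.array([1]))
    graph = ModuleGraph([1], {1: 1}, [], input_modules=(1,))
    return Network(meta, {1: 1}, [], graph)


class TestLifStep:
    def test_rest_is_fixed_point(self):
        p = LIFParams()
        state = NetworkState(np.array([p.v_rest]), np.array([0]))
        state, spikes = lif_step(state, np.array([0.0]), p, dt=0.4)
        assert state.v[0] == p.v_rest
        assert not spikes[0]

    def test_zero_input_decay_matches_closed_form(self):
        # V(t) = V_rest + (V0 - V_rest) exp(-t/tau); 30 ms = 75 steps of 0.4
        p = LIFParams()
        state = NetworkState(np.array([14.5]), np.array([0]))
        for _ in range(75):
            state, _ = lif_step(state, np.array([0.0]), p, dt=0.4)
        expected = 13.5 + 1.0 * np.exp(-1.0)
        assert abs(state.v[0] - expected) < 1e-9

    def test_threshold_crossing_spikes_and_resets(self):
        p = LIFParams()
        state = NetworkState(np.array([14.9]), np.array([0]))
        state, spikes = lif_step(state, np.array([500.0]), p, dt=0.4)
        assert spikes[0]
        assert state.v[0] == p.v_reset
        assert state.refractory[0] == ms_to_steps(p.refractory_ex_ms, 0.4) == 13

    def test_refractory_neuron_ignores_input(self):
        p = LIFParams()
        state = NetworkState(np.array([13.5]), np.array([5]))
        state, spikes = lif_step(state, np.array([500.0]), p, dt=0.4)
        assert not spikes[0]
        assert state.v[0] == 13.5
        assert state.refractory[0] == 4

    def test_non_finite_current_rejected(self):
        state = NetworkState(np.array([13.5]), np.array([0]))
        with pytest.raises(ValueError):
            lif_step(state, np.array([np.nan]), LIFParams(), dt=0.4)

    def test_forward_euler_available(self):
        p = LIFParams()
        state = NetworkState(np.array([14.5]), np.array([0]))
        state, _ = lif_step(state, np.array([0.0]), p, 0.4, integration="forward")
        assert state.v[0] == pytest.approx(14.5 - (0.4 / 30.0), abs=1e-12)


class TestDelaysAndRefractoriness:
    def test_excitatory_spike_arrives_after_ex_ex_delay(self):
        # 1.5 ms at 0.4 ms steps -> 4 steps; input delayed 1 step
        meta = NeuronMeta(np.array([True, True]), np.array([1, 2]))
        graph = ModuleGraph([1, 2], {1: 1, 2: 1}, [(1, 2)], input_modules=(1,))
        inter = SynapseSet([0], [0], [500.0], [4], 1, 1, "m1", "m2")
        net = Network(meta, {1: 1, 2: 1}, [inter], graph)
        inp = SynapseSet([0], [0], [500.0], [1], 1, 1, "input", "m1")
        x = np.zeros((1, 20))
        x[0, 0] = 1.0  # input spike at presentation step 0
        res = simulate_monolithic(net, [inp], x, settle_steps=5, dt=0.4)
        t1 = np.flatnonzero(res.spikes[0, 0])
        t2 = np.flatnonzero(res.spikes[0, 1])
        assert t1[0] == 5 + 0 + 1  # settle + input step + input delay
        assert t2[0] == t1[0] + 4  # ex-ex conduction delay

    def test_refractory_period_bounds_firing(self):
        # constant suprathreshold drive: ISI = refractory + 1
        net = single_neuron_net()
        inp = SynapseSet([0], [0], [500.0], [1], 1, 1, "input", "m1")
        x = np.ones((1, 100))
        res = simulate_monolithic(net, [inp], x, settle_steps=0, dt=0.4)
        times = np.flatnonzero(res.spikes[0, 0])
        assert len(times) > 2
        assert (np.diff(times) == 14).all()  # 13 refractory steps + 1

    def test_zero_input_network_stays_silent(self, chain_network):
        x = np.zeros((16, 50))
        inp = SynapseSet(np.arange(9), np.arange(9), 20.0, 2, 16, 9, "input", "m1")
        res = simulate_monolithic(chain_network, [inp], x, settle_steps=10, dt=0.4)
        assert res.spikes.sum() == 0


class TestModularEqualsMonolithic:
    @staticmethod
    def run_both(net, inputs, x, **kw):
        a = simulate_monolithic(net, inputs, x, **kw)
        b = simulate_modular(net, inputs, x, **kw)
        return a, b

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_three_module_chain_bit_identical(self, seed):
        net = make_chain_network(seed=seed)
        inp = SynapseSet(np.arange(16), np.arange(16) % 9, 20.0, 2, 16, 9,
                         "input", "m1")
        x = make_input(16, 120, seed=seed, density=0.08)
        a, b = self.run_both(net, [inp], x, settle_steps=20, dt=0.4)
        np.testing.assert_array_equal(a.spikes, b.spikes)
        assert a.spikes.sum() > 0  # non-trivial activity

    def test_single_module_trivially_identical(self):
        net = make_chain_network(n_modules=1)
        inp = SynapseSet(np.arange(16), np.arange(16) % 9, 20.0, 2, 16, 9,
                         "input", "m1")
        x = make_input(16, 80, seed=5, density=0.1)
        a, b = self.run_both(net, [inp], x, settle_steps=10, dt=0.4)
        np.testing.assert_array_equal(a.spikes, b.spikes)

    def test_batched_trials_match_single_runs(self):
        net = make_chain_network(seed=4)
        inp = SynapseSet(np.arange(16), np.arange(16) % 9, 20.0, 2, 16, 9,
                         "input", "m1")
        batch = np.stack([make_input(16, 60, seed=s, density=0.1) for s in range(3)])
        res = simulate_modular(net, [inp], batch, settle_steps=10, dt=0.4)
        assert not res.single
        for s in range(3):
            solo = simulate_modular(net, [inp], batch[s], settle_steps=10, dt=0.4)
            np.testing.assert_array_equal(res.spikes[s], solo.spikes[0])

    def test_sparse_matvec_column_order_is_deterministic(self):
        # the bit-identity contract relies on CSR mat-vec treating each
        # column of a dense RHS exactly like a standalone mat-vec
        rng = np.random.default_rng(0)
        w = sp.random(40, 60, density=0.2, random_state=1, format="csr")
        w.sort_indices()
        x = rng.standard_normal((60, 17))
        prod = w @ x
        for j in range(17):
            np.testing.assert_array_equal(prod[:, j], w @ x[:, j])
        # and the time-flattened layout used for exogenous drive
        flat = (w @ x.reshape(60, -1)).reshape(40, 17)
        np.testing.assert_array_equal(flat, prod)

    def test_rerun_bit_identical(self, chain_network):
        inp = SynapseSet(np.arange(16), np.arange(16) % 9, 20.0, 2, 16, 9,
                         "input", "m1")
        x = make_input(16, 60, seed=9, density=0.1)
        a = simulate_monolithic(chain_network, [inp], x, settle_steps=10, dt=0.4)
        b = simulate_monolithic(chain_network, [inp], x, settle_steps=10, dt=0.4)
        np.testing.assert_array_equal(a.spikes, b.spikes)

    def test_cycle_in_module_graph_rejected(self):
        net = make_chain_network(n_modules=2)
        back = SynapseSet([0], [1], [20.0], [2], 9, 9, "m2", "m1")
        with pytest.raises(ValueError, match="input module"):
            # a back-edge into the input module is caught by graph validation
            ModuleGraph([1, 2], {1: 9, 2: 9}, [(1, 2), (2, 1)], input_modules=(1,))


class TestSpikingInvariants:
    def test_refractory_neurons_never_spike(self):
        net = make_chain_network(seed=2)
        inp = SynapseSet(np.arange(16), np.arange(16) % 9, 25.0, 1, 16, 9,
                         "input", "m1")
        x = make_input(16, 150, seed=2, density=0.3)
        res = simulate_monolithic(net, [inp], x, settle_steps=10, dt=0.4)
        refr = np.where(net.meta.excitatory, 13, 5)
        for i in range(net.n_neurons):
            times = np.flatnonzero(res.spikes[0, i])
            if len(times) > 1:
                assert np.diff(times).min() >= refr[i] + 1

    def test_removing_excitatory_synapse_cannot_add_spikes(self):
        # purely excitatory fixture: spike counts are monotone in synapses
        net = make_chain_network(seed=7, exc_fraction=1.0)
        inp = SynapseSet(np.arange(16), np.arange(16) % 9, 20.0, 2, 16, 9,
                         "input", "m1")
        x = make_input(16, 100, seed=7, density=0.15)
        base = simulate_monolithic(net, [inp], x, settle_steps=10, dt=0.4).spikes.sum()
        for k in (0, len(net.projections) - 1):
            lesioned = Network(net.meta, net.module_sizes,
                               [s.copy() for s in net.projections], net.graph)
            lesioned.projections[k].alive[:: 3] = False
            total = simulate_monolithic(lesioned, [inp], x,
                                        settle_steps=10, dt=0.4).spikes.sum()
            assert total <= base


class TestExtractFeatures:
    @staticmethod
    def result_from(spikes, dt=0.4, settle=0):
        spikes = np.asarray(spikes, dtype=np.uint8)[None]
        return SimulationResult(spikes, dt, settle, {1: slice(0, spikes.shape[1])})

    def test_silent_raster_gives_zero_vector(self):
        rates = extract_features(self.result_from(np.zeros((5, 100))))
        np.testing.assert_array_equal(rates, np.zeros(5))

    def test_every_step_spiking_is_inverse_dt(self):
        rates = extract_features(self.result_from(np.ones((1, 1600))))
        assert rates[0] == pytest.approx(2500.0)  # 1 / 0.4 ms

    def test_160_spikes_in_640_ms_is_250_hz(self):
        spikes = np.zeros((1, 1600))
        spikes[0, :160] = 1
        assert extract_features(self.result_from(spikes))[0] == pytest.approx(250.0)

    def test_settle_phase_excluded(self):
        spikes = np.zeros((1, 200))
        spikes[0, :50] = 1  # spikes only during settle
        rates = extract_features(self.result_from(spikes, settle=50))
        assert rates[0] == 0.0
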