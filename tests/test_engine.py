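"""Simulation loop: routing, causality, partition invariance, determinism."""

import numpy as np
import pytest

from gridwave.engine import (
    CausalityError,
    ConstructionError,
    Network,
    SpikeRecord,
    build_routing,
    count_equivalent_events,
    partition,
    run,
)
from gridwave.network import (
    ConnectivityKernel,
    EfficacyMatrix,
    GridSpec,
    SynapseTable,
    assign_delays,
    assign_weights,
    make_grid_spec,
    sample_synapses,
)
from gridwave.neuron import (
    NeuronParams,
    NeuronState,
    SynapticEvent,
    apply_event,
    draw_external_events,
)

SMALL = dict(K_F=6, K_B=18, K_I=6)
EXC = NeuronParams(tau_m=20.0, E=0.0, V_theta=20.0, V_r=5.0, tau_arp=2.0,
                   g_c=0.05, alpha_c=1.0, tau_c=120.0)
INH = NeuronParams(tau_m=10.0, E=0.0, V_theta=20.0, V_r=5.0, tau_arp=1.0,
                   inhibitory=True)
PARAMS = {"F": EXC, "B": EXC, "I": INH}


def toy_network(rows=3, cols=3, lam=0.5, seed=1, nu_ext=2500.0, J=0.9):
    spec = make_grid_spec(rows, cols, SMALL)
    kern = ConnectivityKernel(lambda_imd=lam, in_degree_fraction=0.5)
    row = (J, J / 3, 2 * J)
    eff = EfficacyMatrix(J=(row, row, row), cv=0.25, J_ext=0.6,
                         delta_J_ext=0.15, nu_ext_hz=nu_ext)
    tab = sample_synapses(spec, kern, seed=seed)
    tab = assign_weights(tab, eff, seed=seed)
    tab = assign_delays(tab, "uniform", value_ms=1)
    return Network(spec=spec, table=tab, eff=eff, params=PARAMS)


class TestPartition:
    def test_single_partition(self):
        spec = make_grid_spec(4, 4, SMALL)
        pm = partition(spec, 1)
        assert np.all(pm.neuron_to_partition == 0)
        assert np.all(pm.module_to_partition == 0)

    def test_24x24_four_blocks(self):
        spec = make_grid_spec(24, 24)
        pm = partition(spec, 4)
        m2p = pm.module_to_partition.reshape(24, 24)
        assert np.all(m2p[:12, :12] == m2p[0, 0])
        assert np.all(m2p[:12, 12:] == m2p[0, 12])
        assert np.all(m2p[12:, :12] == m2p[12, 0])
        assert np.all(m2p[12:, 12:] == m2p[12, 12])
        assert len(np.unique(m2p)) == 4
        # each block is 12x12
        assert np.bincount(pm.module_to_partition).tolist() == [144] * 4

    def test_split_single_module_into_halves(self):
        spec = make_grid_spec(1, 1)  # one 1250-neuron module
        pm = partition(spec, 2)
        assert pm.module_to_partition is None
        sizes = np.bincount(pm.neuron_to_partition)
        assert sizes.tolist() == [625, 625]

    def test_too_many_partitions_rejected(self):
        spec = make_grid_spec(1, 1, SMALL)
        with pytest.raises(ConstructionError):
            partition(spec, spec.n_neurons + 1)

    def test_deterministic(self):
        spec = make_grid_spec(5, 3, SMALL)
        a = partition(spec, 3)
        b = partition(spec, 3)
        assert np.array_equal(a.neuron_to_partition, b.neuron_to_partition)


class TestRouting:
    def test_single_partition_holds_all_synapses(self):
        net = toy_network()
        rt = build_routing(net.table, partition(net.spec, 1))
        assert rt.n_synapses == net.table.n_synapses

    @pytest.mark.parametrize("n_parts", [2, 3, 4])
    def test_synapse_conservation_across_partitions(self, n_parts):
        net = toy_network()
        rt = build_routing(net.table, partition(net.spec, n_parts))
        assert rt.n_synapses == net.table.n_synapses
        # every synapse lives with its target
        for pr in rt.partitions:
            owned = set(pr.neuron_gids.tolist())
            for d, (usrc, indptr, tgt, w) in pr.by_delay.items():
                assert set(np.unique(tgt)).issubset(owned)

    def test_double_ordering(self):
        net = toy_network()
        rt = build_routing(net.table, partition(net.spec, 2))
        for pr in rt.partitions:
            for usrc, indptr, tgt, w in pr.by_delay.values():
                assert np.all(np.diff(usrc) > 0)
                assert indptr[0] == 0 and indptr[-1] == tgt.size

    def test_no_cross_partition_synapses_no_channels(self):
        # inhibitory-only connectivity is module-local: with one partition
        # per module there is no inter-partition traffic
        spec = make_grid_spec(2, 2, SMALL)
        kern = ConnectivityKernel(lambda_imd=0.5, in_degree_fraction=0.5)
        tab = sample_synapses(spec, kern, seed=1)
        keep = spec.neuron_population(tab.source) == 2
        tab = SynapseTable(spec=spec, source=tab.source[keep],
                          target=tab.target[keep], weight=tab.weight[keep],
                          delay_ms=tab.delay_ms[keep], kind=tab.kind[keep])
        rt = build_routing(tab, partition(spec, 4))
        for src, dsts in rt.channels.items():
            assert dsts == [src]


class TestRun:
    def test_silent_network_empty_record(self):
        net = toy_network(nu_ext=0.0)
        rec = run(net, 50.0, seed=1, init="rest")
        assert rec.n_spikes == 0

    def test_causality_guard(self):
        net = toy_network()
        with pytest.raises(CausalityError):
            run(net, 10.0, comm_step_ms=2.0, seed=1)

    def test_determinism(self):
        net = toy_network()
        a = run(net, 150.0, seed=5)
        b = run(net, 150.0, seed=5)
        assert np.array_equal(a.neuron, b.neuron)
        assert np.array_equal(a.time_ms, b.time_ms)

    @pytest.mark.parametrize("n_parts", [2, 4])
    def test_partition_invariance_bit_identical(self, n_parts):
        net = toy_network()
        ref = run(net, 200.0, seed=3)
        assert ref.n_spikes > 100  # the comparison must be non-trivial
        other = run(net, 200.0, seed=3, n_partitions=n_parts)
        assert np.array_equal(ref.neuron, other.neuron)
        assert np.array_equal(ref.time_ms, other.time_ms)

    def test_single_neuron_path_matches_event_driven_oracle(self):
        """The engine's update of an input-less neuron must equal stepping
        neuron.apply_event over the same keyed external event stream."""
        net = toy_network(nu_ext=3500.0)
        # neuron 0 is an F neuron; remove all its recurrent inputs so its
        # trajectory depends only on the external stream
        tab = net.table
        keep = tab.target != 0
        net.table = SynapseTable(spec=tab.spec, source=tab.source[keep],
                                 target=tab.target[keep], weight=tab.weight[keep],
                                 delay_ms=tab.delay_ms[keep], kind=tab.kind[keep])
        T = 300.0
        rec = run(net, T, seed=8, init="rest")
        engine_spikes = rec.time_ms[rec.neuron == 0]
        events = draw_external_events(3500.0, (0.0, T), net.eff.J_ext,
                                      net.eff.delta_J_ext, seed=8, neuron_id=0)
        st = NeuronState(V=EXC.E, c=0.0)
        oracle = []
        for ev in events:
            st, sp = apply_event(st, EXC, ev)
            if sp is not None:
                oracle.append(sp)
        assert len(oracle) > 3
        np.testing.assert_allclose(engine_spikes, oracle, rtol=0, atol=1e-12)

    def test_delay_contract(self):
        """A presynaptic spike at t produces a synaptic event exactly at
        t + delay: with a supra-threshold weight the target fires then."""
        # neuron 0 is F (externally driven), neuron 1 is B (no external
        # drive): neuron 1 can only fire through the single synapse
        spec = make_grid_spec(1, 1, dict(K_F=1, K_B=1, K_I=0))
        # single synapse 0 -> 1, 25 mV, delay 3 ms
        tab = SynapseTable(
            spec=spec,
            source=np.array([0], np.uint32),
            target=np.array([1], np.uint32),
            weight=np.array([25.0]),
            delay_ms=np.array([3], np.uint8),
            kind=np.array([0], np.uint8),
        )
        eff = EfficacyMatrix(J=((0.0,) * 3,) * 3, J_ext=0.7, delta_J_ext=0.0,
                             nu_ext_hz=(1600.0, 0.0, 0.0))  # F gets drive only
        net = Network(spec=spec, table=tab, eff=eff, params=PARAMS)
        rec = run(net, 400.0, seed=2, init="rest")
        t0 = rec.time_ms[rec.neuron == 0]
        t1 = rec.time_ms[rec.neuron == 1]
        assert t0.size > 3
        # neuron 1 spikes exactly 3 ms after each driving spike, except those
        # falling in its refractory period or after the run end
        expected = []
        last = -np.inf
        for t in t0:
            if t + 3.0 >= 400.0:
                continue
            if t + 3.0 >= last + EXC.tau_arp:
                expected.append(t + 3.0)
                last = t + 3.0
        np.testing.assert_allclose(t1, expected, atol=1e-12)

    def test_delivery_conservation(self):
        """Delivered recurrent events equal the summed out-degree of spikes
        whose delivery step falls inside the run."""
        net = toy_network()
        T = 120.0
        rec = run(net, T, seed=4)
        outdeg = net.table.out_degree()
        # uniform 1 ms delays: spikes in the last step are never delivered
        deliverable = rec.time_ms < (T - 1.0)
        expected = outdeg[rec.neuron[deliverable]].sum()
        assert rec.meta["n_recurrent_events"] == expected

    def test_spread_init_partition_invariant(self):
        net = toy_network()
        a = run(net, 80.0, seed=6, init="spread")
        b = run(net, 80.0, seed=6, init="spread", n_partitions=3)
        assert np.array_equal(a.neuron, b.neuron)
        assert np.array_equal(a.time_ms, b.time_ms)


class TestEquivalentEvents:
    def test_empty_record(self):
        net = toy_network()
        rec = SpikeRecord(np.array([], np.int64), np.array([]), 10.0,
                          net.spec.n_neurons, 0)
        assert count_equivalent_events(rec, net.table, 0) == 0

    def test_direct_arithmetic(self):
        net = toy_network()
        outdeg = net.table.out_degree()
        neurons = np.array([0, 5, 11], np.int64)
        rec = SpikeRecord(neurons, np.array([1.0, 2.0, 3.0]), 10.0,
                          net.spec.n_neurons, 0)
        assert (count_equivalent_events(rec, net.table, 4000)
                == outdeg[neurons].sum() + 4000)

    def test_run_tally_matches_instrumentation(self):
        net = toy_network()
        rec = run(net, 100.0, seed=9)
        expected = (net.table.out_degree()[rec.neuron].sum()
                    + rec.meta["n_external_events"])
        assert rec.meta["equivalent_synaptic_events"] == expected


class TestSpikeRecordIO:
    def test_tsv_round_trip(self, tmp_path):
        net = toy_network()
        rec = run(net, 60.0, seed=1)
        assert rec.n_spikes > 0
        path = tmp_path / "spikes.tsv"
        rec.save(path)
        back = SpikeRecord.load(path)
        assert np.array_equal(back.neuron, rec.neuron)
        np.testing.assert_allclose(back.time_ms, rec.time_ms, atol=5e-4)
        assert back.duration_ms == rec.duration_ms
        assert back.seed == rec.seed
        assert back.meta["config_digest"] == rec.meta["config_digest"]
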