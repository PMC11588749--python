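import numpy as np
import pytest

from cablehh.channels import CHANNEL_PRESETS, build_rate_table, table_index
from cablehh.engine import (
    Network,
    NeuronModel,
    Simulation,
    SimulationConfig,
    StimulusPulse,
    count_spikes,
    run,
)
from cablehh.morphology import Section
from cablehh.synapses import SynapseSpec


def passive_neuron(name="p0", nseg=1, g_pas=1e-4, v=-70.0):
    return NeuronModel(name, [Section("soma", 20.0, 10.0, nseg=nseg,
                                      channel_densities={"pas": g_pas},
                                      reversal_potentials={"pas": v})],
                       v_rest=v)


def squid_neuron(name="s0", nseg=1):
    return NeuronModel(name, [Section(
        "soma", 30.0, 30.0, nseg=nseg,
        channel_densities={"squid_na": 0.12, "squid_k": 0.036,
                           "squid_leak": 3e-4})], v_rest=-65.0)


def fs_neuron(name="f0", nseg=8):
    return NeuronModel(name, [Section(
        "soma", 70.0, 9.0, nseg=nseg,
        channel_densities={"fs_na": 0.05, "fs_kd": 0.005, "fs_m": 1e-5,
                           "fs_leak": 3.8e-5})], v_rest=-70.4)


class TestInitialization:
    def test_leak_only_at_reversal_is_fixed(self):
        cfg = SimulationConfig(duration=50.0, dt=0.03125)
        tr = run(Network([passive_neuron()]), cfg)
        assert np.abs(tr.voltages + 70.0).max() < 1e-9

    def test_hh_rest_has_small_drift_without_stimulus(self):
        # steady-state initialization: 1e4 steps, no spontaneous spike
        cfg = SimulationConfig(duration=1e4 * 0.03125, dt=0.03125,
                               record_period=None)
        tr = run(Network([squid_neuron()]), cfg)
        v = tr.voltages[:, 0]
        assert count_spikes(tr.time, v) == 0
        assert np.abs(v - v[0]).max() < 0.5

    def test_gates_initialized_at_table_fixed_points(self):
        sim = Simulation(Network([squid_neuron()]),
                         SimulationConfig(duration=1.0))
        for grp in sim._groups:
            v0 = np.full(len(grp.nodes), -65.0)
            for gate, table, x in zip(grp.gates, grp.tables, grp.x):
                idx = table_index(v0, table.vmin, table.vmax, table.nbins)
                fixed = table.r2[idx] / (1.0 - table.r1[idx])
                # direct steady state vs the table's implied fixed point:
                # agree to within table discretization error
                np.testing.assert_allclose(x, fixed, atol=2e-3)

    def test_v_init_override(self):
        sim = Simulation(Network([passive_neuron(v=-70.0)]),
                         SimulationConfig(duration=1.0, v_init=-55.0))
        assert np.all(sim.V == -55.0)


class TestStep:
    def test_zero_channel_network_voltage_invariant(self):
        nm = NeuronModel("bare", [Section("soma", 20.0, 10.0, nseg=4)],
                         v_rest=-61.5)
        sim = Simulation(Network([nm]), SimulationConfig(duration=1.0))
        v0 = sim.V.copy()
        for _ in range(200):
            sim.step()
        # invariant up to elimination round-off on the coupled chain
        assert np.abs(sim.V - v0).max() < 1e-9

    def test_suprathreshold_spikes_subthreshold_does_not(self):
        counts = {}
        for amp in (0.01, 0.5):
            cfg = SimulationConfig(duration=60.0, dt=0.025, record_period=None)
            tr = run(Network([squid_neuron()]), cfg,
                     [StimulusPulse(0, 0, 5.0, 50.0, amp)])
            counts[amp] = count_spikes(tr.time, tr.voltages[:, 0])
        assert counts[0.01] == 0
        assert counts[0.5] >= 2

    def test_nan_abort_names_step(self):
        sim = Simulation(Network([passive_neuron()]),
                         SimulationConfig(duration=1.0),
                         [StimulusPulse(0, 0, 0.0, 1.0, 1e308)])
        with pytest.raises(FloatingPointError, match="step"):
            for _ in range(10):
                sim.step()

    def test_gabaa_input_dips_postsynaptic_trace(self):
        # inhibitory connection: postsynaptic trace falls below its
        # unconnected control once the presynaptic cell fires
        stim = [StimulusPulse(0, 0, 5.0, 90.0, 0.3)]
        cfg = SimulationConfig(duration=100.0, dt=0.03125, record_period=None)
        syn = [SynapseSpec((0, 4), (1, 4), "GABA_A", weight=128.0)]
        ctrl = run(Network([fs_neuron("a"), fs_neuron("b")]), cfg, stim)
        conn = run(Network([fs_neuron("a"), fs_neuron("b")], syn), cfg, stim)
        post = [i for i, lab in enumerate(ctrl.labels) if lab.startswith("neuron1")]
        late = ctrl.time >= 30.0
        assert (conn.voltages[late][:, post].min()
                < ctrl.voltages[late][:, post].min() - 0.5)


class TestRunContract:
    def test_zero_duration_single_sample(self):
        tr = run(Network([passive_neuron()]), SimulationConfig(duration=0.0))
        assert tr.voltages.shape[0] == 1 and tr.time.tolist() == [0.0]

    def test_row_count_matches_record_period(self):
        cfg = SimulationConfig(duration=1000.0, dt=0.5, record_period=1.0)
        tr = run(Network([passive_neuron(nseg=64)]), cfg)
        assert tr.voltages.shape == (1001, 64)
        assert tr.time[-1] == pytest.approx(1000.0)

    def test_determinism_bit_identical(self):
        for mode in ("reference-64bit", "hardware-32bit"):
            cfg = SimulationConfig(duration=25.0, dt=0.03125, mode=mode,
                                   record_period=None)
            stim = [StimulusPulse(0, 0, 2.0, 20.0, 0.3)]
            a = run(Network([fs_neuron()]), cfg, stim)
            b = run(Network([fs_neuron()]), cfg, stim)
            np.testing.assert_array_equal(a.voltages, b.voltages)

    def test_network_decoupling_with_zero_weights(self):
        stim = [StimulusPulse(0, 0, 2.0, 30.0, 0.3)]
        cfg = SimulationConfig(duration=40.0, dt=0.03125, record_period=None)
        single = run(Network([fs_neuron("a")]), cfg, stim)
        syn = [SynapseSpec((0, 3), (1, 3), "AMPA", weight=0.0)]
        paired = run(Network([fs_neuron("a"), fs_neuron("b")], syn), cfg, stim)
        n0 = [i for i, lab in enumerate(paired.labels) if lab.startswith("neuron0")]
        np.testing.assert_array_equal(paired.voltages[:, n0], single.voltages)

    def test_passive_linearity_in_injection(self):
        cfg = SimulationConfig(duration=80.0, dt=0.05, record_period=None)
        defl = {}
        for amp in (0.05, 0.1):
            tr = run(Network([passive_neuron(nseg=8)]), cfg,
                     [StimulusPulse(0, 0, 0.0, 80.0, amp)])
            defl[amp] = tr.voltages[-1] + 70.0
        np.testing.assert_allclose(defl[0.1], 2.0 * defl[0.05], rtol=1e-9)

    def test_settle_period_runs_and_resets_clock(self):
        cfg = SimulationConfig(duration=5.0, dt=0.05, settle=10.0)
        tr = run(Network([squid_neuron()]), cfg)
        assert tr.time[0] == 0.0 and np.isfinite(tr.voltages).all()

    def test_staggered_gate_option_close_to_default(self):
        stim = [StimulusPulse(0, 0, 2.0, 20.0, 0.3)]
        out = {}
        for stag in (False, True):
            cfg = SimulationConfig(duration=25.0, dt=0.03125, record_period=None,
                                   staggered_gates=stag)
            out[stag] = run(Network([fs_neuron()]), cfg, stim).voltages
        assert not np.array_equal(out[False], out[True])
        assert (count_spikes(np.arange(len(out[False])) * 0.03125, out[False][:, 0])
                == count_spikes(np.arange(len(out[True])) * 0.03125, out[True][:, 0]))


class TestNumericsModes:
    def test_hardware_state_is_float32_representable(self):
        cfg = SimulationConfig(duration=5.0, dt=0.03125, mode="hardware-32bit")
        sim = Simulation(Network([fs_neuron()]), cfg,
                         [StimulusPulse(0, 0, 1.0, 4.0, 0.3)])
        for _ in range(100):
            sim.step()
        np.testing.assert_array_equal(sim.V, sim.V.astype(np.float32))
        for grp in sim._groups:
            for x in grp.x:
                np.testing.assert_array_equal(x, x.astype(np.float32))

    def test_mode_divergence_bounded_spike_counts_equal(self):
        # 32- vs 64-bit divergence grows but stays bounded on a pulse
        # response; spike counts agree
        stim = [StimulusPulse(0, 0, 10.0, 15.0, 0.3)]
        out = {}
        for mode in ("reference-64bit", "hardware-32bit"):
            cfg = SimulationConfig(duration=200.0, dt=0.03125, mode=mode,
                                   record_period=None)
            out[mode] = run(Network([fs_neuron()]), cfg, stim)
        a, b = out["reference-64bit"], out["hardware-32bit"]
        d = np.abs(a.voltages - b.voltages)
        assert np.isfinite(d).all() and d.max() < 150.0
        assert (count_spikes(a.time, a.voltages[:, 0])
                == count_spikes(b.time, b.voltages[:, 0]))

    def test_fixed18_synapse_quantization_small(self):
        stim = [StimulusPulse(0, 0, 5.0, 40.0, 0.3)]
        syn = [SynapseSpec((0, 4), (1, 4), "AMPA", weight=128.0)]
        out = {}
        for prec in ("reference", "fixed-18bit"):
            cfg = SimulationConfig(duration=50.0, dt=0.03125,
                                   synapse_precision=prec, record_period=None)
            out[prec] = run(Network([fs_neuron("a"), fs_neuron("b")], syn),
                            cfg, stim)
        d = np.abs(out["reference"].voltages - out["fixed-18bit"].voltages)
        assert d.max() < 1.0  # quantized at 2^-18 per step, small effect

    def test_time_reversal_of_passive_step(self):
        sim = Simulation(Network([passive_neuron()]),
                         SimulationConfig(duration=1.0, dt=0.1, v_init=-50.0))
        v0 = sim.V.copy()
        sim.step()
        sim.step(dt_override=-0.1)
        np.testing.assert_allclose(sim.V, v0, atol=1e-12)


class TestSpikeCounting:
    def test_refractory_lockout_merges_crossings(self):
        t = np.arange(0, 10, 0.1)
        v = np.full_like(t, -65.0)
        v[10:12] = 10.0
        v[13:15] = 10.0   # second crossing 0.3 ms later: locked out
        v[60:62] = 10.0   # 5 ms later: counted
        assert count_spikes(t, v, refractory=1.0) == 2
        assert count_spikes(t, v, refractory=0.0) == 3
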