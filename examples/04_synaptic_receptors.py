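"""Fast/slow excitation and inhibition through the four receptor types.

A stimulated fast-spiking neuron drives a quiet partner through a single
synapse; the postsynaptic peak voltage (after the presynaptic train is
established) is compared against the unconnected control.
"""

from cablehh import (
    Network, NeuronModel, Section, SimulationConfig, StimulusPulse,
    SynapseSpec, run,
)

GMAX = {"AMPA": 0.0875, "NMDA": 0.45, "GABA_A": 0.15, "GABA_B": 1.5}  # nS


def fs_neuron(name):
    return NeuronModel(name, [Section(
        "soma", 70.0, 9.0, nseg=64, Ra=150.0,
        channel_densities={"fs_na": 0.05, "fs_kd": 0.005, "fs_m": 1e-5,
                           "fs_leak": 3.8e-5})], v_rest=-70.4)


def postsynaptic_peak(receptor=None):
    synapses = []
    if receptor:
        synapses = [SynapseSpec((0, 32), (1, 32), receptor, weight=128.0,
                                gmax=GMAX[receptor])]
    config = SimulationConfig(duration=300.0, dt=0.03125, record=[(1, 32)],
                              record_period=None)
    trace = run(Network([fs_neuron("pre"), fs_neuron("post")], synapses),
                config, [StimulusPulse(0, 32, 5.0, 295.0, 0.3)])
    return float(trace.voltages[trace.time >= 30.0, 0].max())


control = postsynaptic_peak()
print(f"unconnected control peak : {control:+.2f} mV")
for receptor in ("AMPA", "NMDA", "GABA_A", "GABA_B"):
    peak = postsynaptic_peak(receptor)
    kind = "excites" if peak > control else "inhibits"
    print(f"{receptor:<7} peak {peak:+8.2f} mV  (shift {peak - control:+8.2f} mV, {kind})")
# AMPA/NMDA depolarize (here enough to fire the quiet cell); GABA_A and the
# slow second-messenger GABA_B hyperpolarize below the control's rest.
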