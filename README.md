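# cablehh

Multicompartment Hodgkin–Huxley simulation on branched cables, built the way
fixed-precision real-time neural emulators compute it: Crank–Nicolson
half-step integration, the Hines parent-vector tree solver, premultiplied
voltage-indexed rate tables for channel gating, fully configurable
conductance-based kinetic synapses (AMPA, NMDA, GABA_A, GABA_B), and a
hardware-faithful 32-bit numerics mode alongside the double-precision
reference.

It is written for computational neuroscientists and neuromorphic-hardware
engineers who want a small, transparent, testable model of this computation
pipeline — to prototype morphologies and channel kinetics, to predict what a
single-precision datapath will do to their model, or to use as a software
reference when validating an accelerator.

## The model

A neuron is a tree of unbranched cylinders ("sections"), each subdivided into
`nseg` compartments. Each compartment obeys the discretized cable equation

    Cm dV_i/dt = L_i (V_{i-1} - V_i) + U_i (V_{i+1} - V_i)
                 - sum_k g_k(t) (V_i - E_k) + I_inj/area

with axial couplings pi·a²_{i±1/2}/(Ra·dx) built from the interface radii,
sealed ends carrying zero axial current, and conductances g_k = gbar·∏x^p
driven by first-order gating variables. Time stepping solves the implicit
half-step system

    A V^{n+1/2} = (2Cm/dt) V^n + sum_k g_k E_k + I_inj,
    V^{n+1} = 2 V^{n+1/2} - V^n

where A is tridiagonal except at branch points. With compartments numbered
so every parent precedes its children, A is stored as a diagonal D, one
off-diagonal U and a parent vector p, and solved exactly in O(n) by one
backward and one forward sweep (the Hines algorithm).

Gating variables update by a single multiply–add per step from premultiplied
tables indexed by the previous voltage:

    x_{n+1} = r1(V_n)·x_n + r2(V_n)
    r1 = 1 - dt(α+β),  r2 = dt·α      (α/β form)
    r1 = 1 - dt/τ,     r2 = dt·x_inf/τ (τ/x_inf form)

Synapses connect any compartment to any other with independent weights:
two-state transmitter binding r' = α[T](1-r) - βr advanced by exact
exponential updates, a voltage-dependent magnesium block for NMDA, and a
G-protein second-messenger cascade with Hill activation for GABA_B.

## Worked example

```sh
python examples/01_single_compartment_spike.py
```

prints

```
spikes in 80 ms of 0.3 nA drive : 6
peak voltage                    : 40.9 mV
resting voltage before stimulus : -65.0 mV
```

— a 30×30 µm squid-kinetics compartment rests at −65 mV, and a 0.3 nA step
elicits a regular train of six overshooting action potentials: gate tables,
current accumulation, and the implicit solver working end to end. The other
examples cover cable-theory attenuation (`02`, profile error ~1e−6 against
cosh((ℓ−x)/λ)), branched-tree solving against a dense factorization (`03`,
agreement to 1e−13 mV), the four synaptic receptor types (`04`, AMPA/NMDA
shift the postsynaptic peak by ≈+106/+114 mV, GABA_A/GABA_B by ≈−9/−14 mV),
and 32-bit versus 64-bit fidelity (`05`, RMS ≈ 0.006 mV on the reduced
motor-neuron demonstration).

The same functionality is scriptable from a shell:

```sh
cablehh fixture --name fs_soma_64 --out fs.yaml
cablehh validate fs.yaml
cablehh run --config fs.yaml --out trace.h5
cablehh run --config fs.yaml --out trace32.h5 --mode hardware-32bit
cablehh compare trace.h5 trace32.h5
```

Configurations are plain YAML/JSON documents (sections, channels, synapses,
stimuli, simulation settings) with schema validation and a content digest;
traces are tab-separated text or HDF5.

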