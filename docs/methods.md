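# Methods

## Model and discretization

Neurons are trees of unbranched cylindrical sections; each section is split
into `nseg` compartments of width dx = L/nseg with the membrane potential
evaluated at compartment centres, positions (k+0.5)/nseg. The sealed-end
boundary (zero axial current) is realized by omitting couplings beyond
terminal compartments, which is equivalent to mirrored virtual points.
Tapered sections interpolate the diameter linearly, so the interface radii
a_{i±1/2} entering the axial coefficients differ from the centre radius.

A child section's first compartment attaches to the parent compartment
nearest the declared attachment end (`distal` → parent's last node,
`proximal` → its first). Compartments are numbered section by section,
parents before children, which guarantees the Hines ordering p[i] < i.

**Units.** All user-facing quantities use the conventional mix: µm for
lengths, S/cm² for conductance densities, µF/cm² for specific capacitance,
Ω·cm for axial resistivity, mV, nA, ms. Internally every per-area quantity
is multiplied once, at compile time, by the compartment's lateral area
2π·a·dx, giving per-node capacitance in nF, conductance in µS and current
in nA (µS·mV = nA, nF/ms = µS). This makes the system matrix symmetric (see
below) and keeps coefficient magnitudes well scaled for 32-bit arithmetic.

## The half-step system and its solver

Crank–Nicolson is applied as a backward-Euler solve to t+dt/2 followed by
extrapolation V^{n+1} = 2V^{n+1/2} − V^n. The assembled rows are

    D_i = Σ incident axial couplings + 2c_i/dt + g_tot,i
    U_i = −(coupling between i and parent(i))
    B_i = (2c_i/dt)·V^n_i + Σ_k g_k E_k + I_inj,i

Two normalization choices are deliberate. First, the per-area form of the
row is multiplied by the compartment's lateral area, which makes the axial
couplings symmetric, π·a²_iface/(Ra·dx) in µS, so the matrix can be stored
as (D, U, p) with a single off-diagonal vector; point injections in nA then
enter B directly (the area scaling cancels the 1/(2πa·dx) of the per-area
formulation). Second, the whole row is assembled in its positive-definite
orientation (positive D, negative U), giving positive pivots throughout the
elimination. Both are pure row scalings: the solution is unchanged, and
correctness is pinned to a dense-factorization oracle in the tests rather
than to any sign convention. Across a junction with unequal dx (or Ra) the
coupling uses the series resistance of the two half-compartments,
which reduces to π·a²/(Ra·dx) on uniform grids and preserves reciprocity.

The solver performs backward elimination in strictly descending node order
(valid for any Hines ordering, including forests of several independent
neurons solved as one system) and forward substitution in ascending order.
A pivot is declared singular below 1e−300; for dt > 0 the 2c/dt term makes
the system strictly diagonally dominant, so this is unreachable in
practice. `assemble_system` accepts negative dt (rejecting only dt = 0):
the negated-dt step is the time-reversed half-step used by the
Crank–Nicolson reversibility check on passive models, not a user-facing
mode. The two sweeps are the only sequential loops in the package and are
JIT-compiled with numba when available, with an identical pure-Python
fallback.

## Rate tables

Gate tables are built at bin-centre voltages on [−100, +50] mV with 4096
bins by default; out-of-range voltages saturate to the end bins, as a
finite hardware table would. Lookup is nearest-bin
(floor((V−vmin)/binwidth), clamped); reference mode can optionally
interpolate linearly. At bin centres the table update is bit-identical to
evaluating the underlying formula, which the tests assert exactly. The
builder raises on non-finite rate evaluations (naming the offending
voltage) and warns when |r1| ≥ 1 anywhere on the grid — the per-bin
stability guard dt < 2/(α+β), resp. dt < 2τ.

Rate functions are small arithmetic expressions in `v` with named
parameters, supporting `exp`, `log` and the guarded removable singularity
`vtrap(x, y) = x/(exp(x/y) − 1)` (series-evaluated for |x/y| < 1e−6). Two
preset families ship: the textbook squid-axon Na/K/Leak set (rest near
−65 mV), and a fast-spiking cortical set in the Pospischil style
(Na, Kd, slow-potassium M, leak; threshold shift VT = −58 mV, M time
constant τ_max = 600 ms, leak reversal −70.4 mV). The FS parameters are
representative stand-ins chosen once for the demonstration fixtures, not
fitted values; anything can be overridden or replaced from configuration.

Gates advance from the previous step's voltage, and the resulting values
are used directly as the g^{n+1/2} of the half-step system (the literal
pipeline ordering). A staggered variant — advancing gates by dt/2 once at
initialization so they sit at n+1/2 thereafter — is available and off by
default; on the demonstration models it changes voltages by well under a
spike width and leaves spike counts unchanged.

## Synapses

Receptor kinetics follow the classic kinetic-model family: two-state
binding r' = α[T](1−r) − βr for AMPA, NMDA and GABA_A; NMDA multiplied by
the magnesium unblock factor 1/(1 + exp(−0.062V)·[Mg]/3.57); GABA_B through
a cascade r → s (s' = k3·r − k4·s) with Hill activation sⁿ/(sⁿ + Kd),
n = 4. Default constants (α = 1.1 mM⁻¹ms⁻¹, β = 0.19 ms⁻¹ for AMPA;
0.072/0.0066 for NMDA; 5/0.18 for GABA_A; k1..k4 = 0.52, 0.0013, 0.098,
0.033, Kd = 100 for GABA_B; E_syn = 0, 0, −80, −95 mV) live in
`src/cablehh/data/receptors.yaml` and are overridable per synapse.

Transmitter is a rectangular pulse (1 mM, 1 ms by default) triggered when
the presynaptic voltage crosses 0 mV upward, retriggerable after the pulse
ends. The release clock counts whole steps (an integer timer) so pulse
lengths never drift by floating-point accumulation. States advance by the
exact exponential update with per-dt factors precomputed at compile time —
the software analogue of tabulated exponential rates — which keeps
r ∈ [0, 1] unconditionally.

Synaptic conductances read voltages of the last completed step (explicit
coupling between neurons), so each neuron's implicit solve stays
independent; within-neuron dynamics remain fully implicit. Point
conductances in nS are divided by the postsynaptic compartment's area via
the same area scaling as everything else (1 nS = 1e−3 µS added to the
node). Autapses and duplicate connections are allowed; connectivity is
stored sparsely, with a dense weight-matrix configuration form accepted for
small demonstrations.

## Initialization, stimulation, recording

Voltages start at each neuron's configured resting potential (a global
`v_init` can override); gates start at their analytic steady state
α/(α+β) or x_inf, falling back to the table fixed point r2/(1−r1) where
the rates vanish; synapse states start at zero. An optional settling period
runs and discards an initial stretch for users matching other simulators.
Stimuli are rectangular current pulses in nA delivered to single
compartments; the CLI logs the equivalent current density for transparency.
Recording keeps every k-th step with k = round(record_period/dt)
(default 1 ms; validation runs record every step), labelled
`neuron<k>/<section>[<index>]`. Spike counts, used only for reporting,
are upward 0 mV crossings with a 1 ms refractory lockout (both
configurable).

## Numerics modes

`reference-64bit` computes everything in double precision.
`hardware-32bit` emulates a single-precision datapath: stored model
parameters, table entries, and each pipeline stage's *output* — gate
states, the accumulated D/B coefficient contributions, the solved and
extrapolated voltages — are rounded to 32-bit floating point, while
arithmetic inside a stage runs in double precision. Gate clamping to [0, 1]
defaults on in this mode (off in reference mode). Independently,
`synapse_precision: fixed-18bit` quantizes synaptic state to 18 fractional
bits each step, bounding its per-step deviation from reference by 2⁻¹⁹ per
quantized variable.

**Where single precision holds, and where it fails.** On realistic
morphologies (the reduced motor-neuron demonstration: thin axon/dendrite
sections, dx of tens of µm) the 32-bit mode tracks the reference to
≈0.006 mV RMS over 100 ms with identical spike counts. The failure regime
is very fine grids on thick processes: a 70×9 µm soma cut into 64 slabs has
axial couplings of ~39 µS per interface against a per-node membrane
conductance of ~1.2e−5 µS — a ratio of 3×10⁶, within a factor of ~2.5 of
float32's mantissa resolution (8.4×10⁶). Rounding D to 32 bits then
quantizes the membrane term with ~65% relative error, and because every
interior compartment of a uniform section shares the same D, the residual
is systematic rather than averaging: the effective leak shifts by tens of
percent and the resting potential by ~10 mV (measured −61.0 vs −70.5 mV on
that configuration, per-node RMS ≈ 9.2 mV over 1 s, spike counts still
identical). This is a property of any faithful float32 D/B pipeline, not of
this implementation — the same cell as a single compartment, or any model
with dx chosen sensibly for its electrotonic length, stays in the
sub-0.01 mV regime. Practical guidance: keep the axial/membrane
conductance ratio a couple of orders below 8×10⁶ when the 32-bit mode
matters, i.e. don't over-discretize electrically compact structures.

A related, much smaller effect exists in double precision: elimination
round-off on that same pathological geometry perturbs the resting fixed
point at the 1e−8 mV scale, against ~1e−13 mV for ordinary passive cables.

## Demonstration fixtures

`fs_soma_64` is a fast-spiking soma (70 µm × 9 µm, 64 compartments, FS
preset) driven by a 15 ms, 0.3 nA pulse at 10 ms — the pulse-response
validation protocol; 0.3 nA is also the drive used in the receptor
demonstrations. `motoneuron_like_64` is a *synthetic* stand-in for a
reduced embryonic motor neuron: soma, active axon initial segment, axon and
branched dendrites totalling exactly 64 compartments, sodium confined to
the axonal sections; its lengths, diameters and densities are plausible
placeholders, not published measurements, so it exercises topology and
section-wise channel placement, not a specific cell. `squid_axon_chain`
(16 compartments, squid kinetics) supports the excitability tests, and
`random_tree` generates seeded random passive trees (≤128 nodes) for solver
property tests. What passing tests on these fixtures shows is that the
numerics are right — oracle equivalence, convergence orders, sign and
stability properties; they do not validate any biological parameter set
against recordings.

## Validation problem sizes and choices

The shipped validation (tests and `scripts/acceptance.py`) uses: 500 random
trees up to 128 nodes for solver–oracle equivalence (max relative error
~4e−12); four dt levels 0.05→0.00625 ms for temporal order (error ratios
4.00 per halving); nseg 32→256 on a λ-long cable for spatial order (ratios
3.98, profile error 3e−7 at nseg = 256); 10⁴ steps at dt = 0.03125 ms for
resting drift (6e−14 mV); seven preset gates for table fidelity; a
12-step bisection plus 10-point f–I sweep for excitability; 300 ms
two-neuron runs per receptor type; two 1000 ms runs for mode fidelity; and
a 16-neuron × 64-compartment network with 10⁴ random synapses for the
scale contract (~20 s wall time for 32,000 steps on one CPU).

Two measurement choices deserve note. The squid-kinetics chain is type-II
excitable: one onset spike at rheobase, repetitive firing at higher drive,
and depolarization block above ≈0.5 nA into this geometry — the f–I sweep
therefore spans 0.5× to 8× rheobase, the physiological range below block.
The receptor-type comparison uses an unstimulated postsynaptic cell and
takes the peak over t ≥ 30 ms (after the presynaptic train is
established): with the post cell otherwise at rest, "excitatory raises /
inhibitory lowers the peak" is a strict ordering, which it would not be if
the post cell were itself spiking.

## Limitations

No calcium dynamics (fixed reversals throughout), no temperature/Q10
scaling, no stochastic gating, no short-term plasticity or explicit axonal
delays (conduction delay emerges from multicompartment axons), no
variable-step integration, no SWC/NeuroML import, and no attempt at
byte-compatibility with any accelerator's configuration files. The
connectivity scale tested is 10⁴ synapses; the engine is vectorized NumPy
plus two JIT sweeps, adequate for desk-scale exploration rather than
large-network production runs.
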