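"""Simulation engine: the per-step pipeline over a network of neurons.

Each time step runs, per neuron (all neurons batched into one forest):

1. gate update from the previous step's voltages (premultiplied tables);
2. synapse update from previous-step presynaptic voltages;
3. accumulation of membrane + synaptic conductances into g_tot and g*E sums;
4. assembly and Hines solve of the half-step system;
5. Crank-Nicolson extrapolation to the full step.

Neurons are mutually independent within a step except through the synaptic
terms of (2), which read voltages of the last completed step -- the explicit
coupling that lets every neuron's implicit solve stay independent.

Two numerics modes are provided: ``reference-64bit`` (double precision,
optional interpolated table lookup) and ``hardware-32bit``, which rounds
every persistent quantity -- stored parameters, table entries and each
pipeline stage's output -- through 32-bit floating point with nearest-bin
lookup, mirroring a single-precision datapath; synapse state can
additionally be quantized to 18 fractional bits each step
(``fixed-18bit``).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np

from . import channels as _ch
from . import solver as _solver
from .channels import ChannelSpec, GateSpec, build_rate_table, table_index
from .morphology import CompartmentGrid, Section, build_grid
from .synapses import SynapseSpec, mg_block, quantize_fixed

__all__ = [
    "SimulationConfig",
    "StimulusPulse",
    "NeuronModel",
    "Network",
    "TraceRecord",
    "Simulation",
    "run",
    "count_spikes",
]

log = logging.getLogger(__name__)

MODES = ("reference-64bit", "hardware-32bit")
SYNAPSE_PRECISIONS = ("reference", "fixed-18bit")


@dataclass
class SimulationConfig:
    """Run settings: time step, duration, numerics mode, recording."""

    duration: float = 100.0        # ms
    dt: float = 0.03125            # ms (the 32 kHz hardware tick)
    mode: str = "reference-64bit"
    synapse_precision: str = "reference"
    table_nbins: int = _ch.DEFAULT_NBINS
    table_vmin: float = _ch.DEFAULT_VMIN
    table_vmax: float = _ch.DEFAULT_VMAX
    record: str | list[tuple[int, int]] = "all"
    record_period: float | None = None  # ms; None records every step
    interp_lookup: bool = False
    clamp_gates: bool | None = None    # None: clamp only in hardware mode
    staggered_gates: bool = False      # advance gates dt/2 on the first step
    settle: float = 0.0                # ms discarded before t = 0
    v_init: float | None = None        # overrides every neuron's resting voltage
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.duration < 0:
            raise ValueError("duration must be >= 0")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.synapse_precision not in SYNAPSE_PRECISIONS:
            raise ValueError(f"synapse_precision must be one of {SYNAPSE_PRECISIONS}")
        if self.record_period is not None and self.record_period < self.dt:
            raise ValueError("record period must be >= dt")

    @property
    def hardware(self) -> bool:
        return self.mode == "hardware-32bit"

    @property
    def clamp(self) -> bool:
        if self.clamp_gates is None:
            return self.mode == "hardware-32bit"
        return self.clamp_gates


@dataclass
class StimulusPulse:
    """A rectangular current pulse into one compartment (amplitude in nA)."""

    neuron: int
    node: int
    onset: float
    duration: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("stimulus duration must be > 0")
        if not np.isfinite(self.amplitude):
            raise ValueError("stimulus amplitude must be finite")


@dataclass
class NeuronModel:
    """One neuron: its sections, channel definitions and resting voltage.

    Section ``channel_densities`` refer to channels by name, resolved first in
    ``channel_defs`` and then among the built-in presets.
    """

    name: str
    sections: list[Section]
    channel_defs: dict[str, ChannelSpec] = field(default_factory=dict)
    v_rest: float = -65.0

    def resolve_channel(self, name: str) -> ChannelSpec:
        if name in self.channel_defs:
            return self.channel_defs[name]
        return _ch.get_preset(name)


@dataclass
class Network:
    neurons: list[NeuronModel]
    synapses: list[SynapseSpec] = field(default_factory=list)


@dataclass
class TraceRecord:
    """Recorded membrane voltages: time (ms) x labelled compartments (mV)."""

    time: np.ndarray
    voltages: np.ndarray  # (n_samples, n_channels)
    labels: list[str]
    meta: dict = field(default_factory=dict)

    def column(self, label: str) -> np.ndarray:
        return self.voltages[:, self.labels.index(label)]


class _ChannelGroup:
    """Channels sharing identical gate kinetics, merged across sections/neurons."""

    __slots__ = ("spec", "nodes", "gbar", "erev", "gates", "tables", "x")

    def __init__(self, spec: ChannelSpec):
        self.spec = spec
        self.nodes: list[int] = []       # global node indices (lists until frozen)
        self.gbar: list[float] = []      # uS
        self.erev: list[float] = []      # mV
        self.gates: list[GateSpec] = spec.gates
        self.tables = []                 # RateTable per gate
        self.x = []                      # state array per gate


class _SynapseGroup:
    """All synapses of one receptor type, updated vectorized."""

    __slots__ = ("receptor", "specs", "pre", "post", "g_unit", "esyn", "threshold",
                 "cmax", "cdur", "e_on", "rinf_on", "e_off", "e4", "k34", "kd",
                 "hill_n", "mg", "r", "s", "release_steps", "prev_pre_v")


def _compile_synapses(specs: list[SynapseSpec], offsets: list[int], dt: float):
    groups = []
    for receptor in ("AMPA", "NMDA", "GABA_A", "GABA_B"):
        sub = [s for s in specs if s.receptor == receptor]
        if not sub:
            continue
        g = _SynapseGroup()
        g.receptor = receptor
        g.specs = sub
        g.pre = np.array([offsets[s.pre[0]] + s.pre[1] for s in sub])
        g.post = np.array([offsets[s.post[0]] + s.post[1] for s in sub])
        g.g_unit = np.array([s.weight * s.gmax * 1e-3 for s in sub])  # uS
        g.esyn = np.array([s.param("esyn") for s in sub])
        g.threshold = np.array([s.param("threshold") for s in sub])
        g.cmax = np.array([s.param("cmax") for s in sub])
        g.cdur = np.maximum(1, np.round(
            np.array([s.param("cdur") for s in sub]) / dt)).astype(np.int64)
        if receptor == "GABA_B":
            k1 = np.array([s.param("k1") for s in sub])
            k2 = np.array([s.param("k2") for s in sub])
            k3 = np.array([s.param("k3") for s in sub])
            k4 = np.array([s.param("k4") for s in sub])
            kon = k1 * g.cmax + k2
            g.e_on = np.exp(-kon * dt)
            g.rinf_on = k1 * g.cmax / kon
            g.e_off = np.exp(-k2 * dt)
            g.e4 = np.exp(-k4 * dt)
            g.k34 = k3 / k4
            g.kd = np.array([s.param("kd") for s in sub])
            g.hill_n = np.array([s.param("n") for s in sub])
        else:
            alpha = np.array([s.param("alpha") for s in sub])
            beta = np.array([s.param("beta") for s in sub])
            kon = alpha * g.cmax + beta
            g.e_on = np.exp(-kon * dt)
            g.rinf_on = alpha * g.cmax / kon
            g.e_off = np.exp(-beta * dt)
        if receptor == "NMDA":
            g.mg = np.array([s.param("mg") for s in sub])
        n = len(sub)
        g.r = np.zeros(n)
        g.s = np.zeros(n)
        g.release_steps = np.zeros(n)
        g.prev_pre_v = np.zeros(n)
        groups.append(g)
    return groups


def _round32(a: np.ndarray) -> np.ndarray:
    """Round values through 32-bit floating point (storage stays float64)."""
    return np.asarray(a, dtype=np.float32).astype(np.float64)


def _identity(a: np.ndarray) -> np.ndarray:
    return a


class Simulation:
    """A compiled, runnable network simulation.

    Construction discretizes every neuron, merges identical channels across
    the network into vectorized groups, builds the rate tables for the
    configured dt and initializes all state at rest (voltage at each neuron's
    resting potential, gates at their steady state there, synapses zeroed).

    In ``hardware-32bit`` mode every persistent quantity -- stored model
    parameters, table entries, and each pipeline stage's output (gate states,
    the accumulated D/B coefficient contributions, the solved voltages) -- is
    rounded to 32-bit floating point, emulating a single-precision datapath
    whose block memories and inter-stage registers hold float32 words.
    """

    def __init__(
        self,
        network: Network,
        config: SimulationConfig,
        stimuli: list[StimulusPulse] | None = None,
    ):
        self.network = network
        self.config = config
        self.stimuli = list(stimuli or [])
        rnd = _round32 if config.hardware else _identity
        self._round = rnd

        self.grids: list[CompartmentGrid] = [build_grid(n.sections) for n in network.neurons]
        self.offsets = np.concatenate([[0], np.cumsum([g.n_nodes for g in self.grids])])
        self.n_nodes = int(self.offsets[-1])
        parent = []
        for off, grid in zip(self.offsets, self.grids):
            p = grid.parent.copy()
            p[p >= 0] += off
            parent.append(p)
        self.parent = np.concatenate(parent)

        gax = rnd(np.concatenate([_solver.precompute_axial(g).g_parent for g in self.grids]))
        self._axial = _solver.AxialCoefficients(g_parent=gax)
        couple = gax.copy()
        np.add.at(couple, self.parent[self.parent >= 0], gax[self.parent >= 0])
        self._couple_sum = rnd(couple)
        self._U = rnd(-gax)
        cap = np.concatenate([g.cap_nF for g in self.grids])
        self._cap_nF = cap
        self._two_c_dt = rnd((2.0 / config.dt) * cap)

        self._v_rest_nodes = np.concatenate([
            np.full(grid.n_nodes, config.v_init if config.v_init is not None else nm.v_rest)
            for nm, grid in zip(network.neurons, self.grids)
        ])
        self._build_channel_groups()
        self._syn_groups = _compile_synapses(network.synapses, list(self.offsets), config.dt)
        for s in network.synapses:
            for end, (ni, node) in (("pre", s.pre), ("post", s.post)):
                if not (0 <= ni < len(self.grids)) or not (0 <= node < self.grids[ni].n_nodes):
                    raise ValueError(
                        f"synapse {end} endpoint (neuron {ni}, node {node}) out of range")
        for st in self.stimuli:
            if not (0 <= st.neuron < len(self.grids)) or \
                    not (0 <= st.node < self.grids[st.neuron].n_nodes):
                raise ValueError(f"stimulus target (neuron {st.neuron}, node {st.node}) "
                                 "out of range")
        self._compiled_stimuli = [
            (int(self.offsets[s.neuron] + s.node),
             int(round(s.onset / config.dt)),
             int(round((s.onset + s.duration) / config.dt)),
             s.amplitude)
            for s in self.stimuli
        ]
        self.initialize_state()

    # -- compilation ------------------------------------------------------

    def _build_channel_groups(self) -> None:
        cfg = self.config
        groups: dict[tuple, _ChannelGroup] = {}
        for ni, (nm, grid) in enumerate(zip(self.network.neurons, self.grids)):
            off = self.offsets[ni]
            for sec in nm.sections:
                nodes = off + grid.nodes_of(sec.name)
                areas = self._area_cm2(grid, sec.name)
                for chan_name, gbar in sec.channel_densities.items():
                    if gbar < 0:
                        raise ValueError(f"negative gbar for {chan_name!r} in {sec.name!r}")
                    spec = nm.resolve_channel(chan_name)
                    erev = spec.erev
                    for key in (chan_name, spec.ion):
                        if key is not None and key in sec.reversal_potentials:
                            erev = sec.reversal_potentials[key]
                    gkey = spec.digest_key()
                    grp = groups.setdefault(gkey, _ChannelGroup(spec))
                    grp.nodes.extend(int(i) for i in nodes)
                    grp.gbar.extend(gbar * areas * 1e6)  # S/cm2 * cm2 -> S -> uS
                    grp.erev.extend([erev] * len(nodes))
        vgrid = (cfg.table_vmin, cfg.table_vmax, cfg.table_nbins)
        self._groups: list[_ChannelGroup] = []
        for grp in groups.values():
            grp.nodes = np.asarray(grp.nodes, dtype=np.int64)
            grp.gbar = self._round(np.asarray(grp.gbar, dtype=float))
            grp.erev = self._round(np.asarray(grp.erev, dtype=float))
            tables = [build_rate_table(g, cfg.dt, vgrid) for g in grp.gates]
            if cfg.hardware:
                for t in tables:
                    t.r1 = _round32(t.r1)
                    t.r2 = _round32(t.r2)
            grp.tables = tables
            self._groups.append(grp)

    def _area_cm2(self, grid: CompartmentGrid, section: str) -> np.ndarray:
        return grid.area_cm2[grid.nodes_of(section)]

    # -- state ------------------------------------------------------------

    def initialize_state(self) -> None:
        """Voltages to rest, gates to steady state, synapses zeroed, t = 0."""
        cfg = self.config
        self.V = self._round(self._v_rest_nodes.astype(float))
        for grp in self._groups:
            v0 = self._v_rest_nodes[grp.nodes]
            grp.x = []
            for gate, table in zip(grp.gates, grp.tables):
                x0 = np.atleast_1d(np.asarray(gate.steady_state(v0), dtype=float))
                bad = ~np.isfinite(x0)
                if np.any(bad):
                    idx = table_index(v0[bad], table.vmin, table.vmax, table.nbins)
                    denom = 1.0 - table.r1[idx]
                    if np.any(denom == 0):
                        raise ValueError(
                            f"gate {gate.name!r}: steady state undefined at rest")
                    x0[bad] = table.r2[idx] / denom
                grp.x.append(self._round(x0))
        if cfg.staggered_gates:
            # half-step gate advance so conductances sit at n+1/2 from step one
            half = cfg.dt / 2.0
            vgrid = (cfg.table_vmin, cfg.table_vmax, cfg.table_nbins)
            for grp in self._groups:
                v0 = self.V[grp.nodes]
                for k, gate in enumerate(grp.gates):
                    t_half = build_rate_table(gate, half, vgrid, warn_unstable=False)
                    grp.x[k] = self._round(_ch.update_gates(grp.x[k], v0, t_half))
        for sg in self._syn_groups:
            n = len(sg.pre)
            sg.r = np.zeros(n)
            sg.s = np.zeros(n)
            sg.release_steps = np.zeros(n)
            sg.prev_pre_v = self.V[sg.pre].astype(float)
        self.step_index = 0
        if cfg.settle > 0:
            for _ in range(int(round(cfg.settle / cfg.dt))):
                self.step()
            self.step_index = 0

    # -- stepping ---------------------------------------------------------

    def _injection(self, step: int) -> np.ndarray:
        I = np.zeros(self.n_nodes)
        for node, on, off, amp in self._compiled_stimuli:
            if on <= step < off:
                I[node] += amp
        return I

    def _synaptic(self, V_prev, g_tot, gE) -> None:
        cfg = self.config
        dt = cfg.dt
        fixed = cfg.synapse_precision == "fixed-18bit"
        for sg in self._syn_groups:
            pre_v = np.asarray(V_prev[sg.pre], dtype=float)
            crossing = (sg.prev_pre_v < sg.threshold) & (pre_v >= sg.threshold)
            sg.prev_pre_v = pre_v
            active = sg.release_steps > 0
            sg.release_steps = np.where(
                active,
                sg.release_steps - 1,
                np.where(crossing, sg.cdur, 0),
            )
            on = sg.release_steps > 0
            sg.r = np.where(on, sg.rinf_on + (sg.r - sg.rinf_on) * sg.e_on,
                            sg.r * sg.e_off)
            if fixed:
                sg.r = quantize_fixed(sg.r)
            if sg.receptor == "GABA_B":
                sg.s = sg.s * sg.e4 + sg.k34 * sg.r * (1.0 - sg.e4)
                if fixed:
                    sg.s = quantize_fixed(sg.s)
                sn = sg.s ** sg.hill_n
                g = sg.g_unit * sn / (sn + sg.kd)
            elif sg.receptor == "NMDA":
                g = sg.g_unit * sg.r * mg_block(np.asarray(V_prev[sg.post], dtype=float),
                                                sg.mg)
            else:
                g = sg.g_unit * sg.r
            if np.any(~np.isfinite(g)):
                raise FloatingPointError(f"non-finite {sg.receptor} synaptic conductance "
                                         f"at step {self.step_index}")
            np.add.at(g_tot, sg.post, g)
            np.add.at(gE, sg.post, g * sg.esyn)

    def step(self, dt_override: float | None = None) -> None:
        """Advance the whole network by one time step.

        ``dt_override`` changes only the assembly dt of this step (the
        channel tables keep their configured dt); its sole intended use is
        the negated-dt step of Crank-Nicolson reversibility checks on
        passive models.
        """
        cfg = self.config
        rnd = self._round
        V_prev = self.V

        g_tot = np.zeros(self.n_nodes)
        gE = np.zeros(self.n_nodes)
        for grp in self._groups:
            Vn = V_prev[grp.nodes]
            g = grp.gbar.copy()
            for k, (gate, table) in enumerate(zip(grp.gates, grp.tables)):
                x = rnd(_ch.update_gates(grp.x[k], Vn, table,
                                         clamp=cfg.clamp,
                                         interpolate=cfg.interp_lookup))
                grp.x[k] = x
                e = gate.exponent
                g = g * (x if e == 1 else x**e)
            g = rnd(g)
            g_tot[grp.nodes] += g
            gE[grp.nodes] += g * grp.erev

        self._synaptic(V_prev, g_tot, gE)
        g_tot = rnd(g_tot)
        gE = rnd(gE)
        I = self._injection(self.step_index)

        dt = cfg.dt if dt_override is None else dt_override
        two_c_dt = self._two_c_dt if dt_override is None \
            else rnd((2.0 / dt) * self._cap_nF)
        D = rnd(self._couple_sum + two_c_dt + g_tot)
        B = rnd(two_c_dt * V_prev + gE + I)
        system = _solver.HinesSystem(p=self.parent, D=D, U=self._U.copy(), B=B)
        V_half = rnd(_solver.hines_solve(system))
        V_new = rnd(2.0 * V_half - V_prev)
        if not np.all(np.isfinite(V_new)):
            node = int(np.flatnonzero(~np.isfinite(V_new))[0])
            raise FloatingPointError(
                f"non-finite voltage at node {node} on step {self.step_index}")
        self.V = V_new
        self.step_index += 1

    def run(self) -> TraceRecord:
        """Run for the configured duration; returns the recorded traces."""
        cfg = self.config
        n_steps = int(round(cfg.duration / cfg.dt))
        k = 1 if cfg.record_period is None else max(1, int(round(cfg.record_period / cfg.dt)))
        rec_nodes, labels = self._recording_plan()
        n_samples = n_steps // k + 1
        out = np.empty((n_samples, len(rec_nodes)))
        time = np.arange(n_samples) * (k * cfg.dt)
        out[0] = self.V[rec_nodes]
        row = 1
        for s in range(1, n_steps + 1):
            self.step()
            if s % k == 0:
                out[row] = self.V[rec_nodes]
                row += 1
        return TraceRecord(
            time=time,
            voltages=out,
            labels=labels,
            meta={
                "dt": cfg.dt,
                "mode": cfg.mode,
                "synapse_precision": cfg.synapse_precision,
                "record_period": k * cfg.dt,
                "digest": self.config_digest(),
            },
        )

    def _recording_plan(self):
        if self.config.record == "all":
            pairs = [(ni, j) for ni, grid in enumerate(self.grids)
                     for j in range(grid.n_nodes)]
        else:
            pairs = list(self.config.record)
        nodes, labels = [], []
        for ni, j in pairs:
            grid = self.grids[ni]
            if not (0 <= j < grid.n_nodes):
                raise ValueError(f"record target (neuron {ni}, node {j}) out of range")
            nodes.append(int(self.offsets[ni] + j))
            sec = grid.section_of[j]
            within = j - int(np.flatnonzero(
                [s == sec for s in grid.section_of])[0])
            labels.append(f"neuron{ni}/{sec}[{within}]")
        return np.asarray(nodes), labels

    def config_digest(self) -> str:
        h = hashlib.sha256()
        h.update(repr((self.config, len(self.network.neurons), self.n_nodes,
                       len(self.network.synapses), len(self.stimuli))).encode())
        return h.hexdigest()[:16]


def run(
    network: Network,
    config: SimulationConfig,
    stimuli: list[StimulusPulse] | None = None,
) -> TraceRecord:
    """Compile and run a network; deterministic for a fixed configuration."""
    return Simulation(network, config, stimuli).run()


def count_spikes(
    time: np.ndarray,
    v: np.ndarray,
    threshold: float = 0.0,
    refractory: float = 1.0,
) -> int:
    """Upward threshold crossings with a refractory lockout (reporting only)."""
    v = np.asarray(v)
    up = np.flatnonzero((v[:-1] < threshold) & (v[1:] >= threshold))
    if len(up) == 0:
        return 0
    t = np.asarray(time)[up + 1]
    count = 1
    last = t[0]
    for ti in t[1:]:
        if ti - last >= refractory:
            count += 1
            last = ti
    return count
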