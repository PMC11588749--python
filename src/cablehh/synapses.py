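"""Conductance-based kinetic synapses: AMPA, NMDA, GABA_A and GABA_B.

Any compartment of any neuron can be connected to any other, each connection
independently weighted.  Transmitter release is a rectangular concentration
pulse (amplitude ``cmax`` mM, duration ``cdur`` ms) triggered when the
presynaptic voltage crosses ``threshold`` upward; the bound-receptor fraction
r follows two-state binding kinetics

    dr/dt = alpha * [T] * (1 - r) - beta * r

advanced by the exact exponential update with per-dt precomputed rate
scalars (the software analogue of tabulated exponential rates).  Conductances:

    AMPA, GABA_A:  g = weight * gmax * r
    NMDA:          g = weight * gmax * r * B(V),  B(V) = 1/(1 + exp(-0.062 V) * [Mg]/3.57)
    GABA_B:        g = weight * gmax * s^n / (s^n + Kd)

where for GABA_B r drives a second-messenger cascade ds/dt = k3*r - k4*s.
Default kinetic constants ship in ``data/receptors.yaml`` and may be
overridden per synapse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "RECEPTOR_TYPES",
    "receptor_defaults",
    "SynapseSpec",
    "SynapseState",
    "detect_release",
    "update_receptor",
    "accumulate_synaptic",
    "quantize_fixed",
    "mg_block",
]

log = logging.getLogger(__name__)

RECEPTOR_TYPES = ("AMPA", "NMDA", "GABA_A", "GABA_B")

# Fig-9-style demonstration conductances (nS), used by fixtures.
DEMO_GMAX_NS = {"AMPA": 0.0875, "NMDA": 0.45, "GABA_A": 0.15, "GABA_B": 1.5}


def receptor_defaults() -> dict[str, dict[str, float]]:
    """Default kinetic parameters per receptor, loaded from the parameter file."""
    text = resources.files("cablehh").joinpath("data/receptors.yaml").read_text()
    return yaml.safe_load(text)


_DEFAULTS = None


def _defaults(receptor: str) -> dict[str, float]:
    global _DEFAULTS
    if _DEFAULTS is None:
        _DEFAULTS = receptor_defaults()
    return _DEFAULTS[receptor]


@dataclass
class SynapseSpec:
    """One synapse instance: pre/post compartment, receptor type and strength.

    ``gmax`` is the unitary maximal conductance in nS; ``weight`` a
    dimensionless multiplier.  ``params`` overrides entries of the receptor's
    default kinetics (alpha, beta, esyn, cmax, cdur, threshold, mg,
    k1..k4, kd, n).
    """

    pre: tuple[int, int]   # (neuron index, node index)
    post: tuple[int, int]
    receptor: str
    weight: float = 1.0
    gmax: float | None = None  # nS; default per receptor (demonstration value)
    params: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.receptor not in RECEPTOR_TYPES:
            raise ValueError(f"unknown receptor {self.receptor!r}; one of {RECEPTOR_TYPES}")
        if self.weight < 0 or (self.gmax is not None and self.gmax < 0):
            raise ValueError("weight and gmax must be >= 0")
        if self.gmax is None:
            self.gmax = DEMO_GMAX_NS[self.receptor]
        if self.pre == self.post:
            log.info("autapse configured on neuron %d node %d", *self.pre)

    def param(self, key: str) -> float:
        if key in self.params:
            return float(self.params[key])
        return float(_defaults(self.receptor)[key])


@dataclass
class SynapseState:
    """Kinetic state of one synapse: bound fraction r, cascade level s, release clock.

    The release clock counts whole steps (an integer counter, as a hardware
    timer would) so pulse lengths never drift with floating-point
    accumulation.
    """

    r: float = 0.0
    s: float = 0.0
    release_steps: int = 0  # transmitter pulse steps left
    prev_pre_v: float = -65.0


def detect_release(
    pre_V: float,
    state: SynapseState,
    t: float,
    dt: float,
    threshold: float = 0.0,
    cdur: float = 1.0,
    cmax: float = 1.0,
) -> float:
    """Advance the release window one step; returns transmitter concentration (mM).

    A pulse starts on an upward threshold crossing of the presynaptic voltage
    (previous completed step's value vs the one before) and lasts ``cdur`` ms
    (rounded to whole steps); a new crossing retriggers only after the pulse
    has ended.
    """
    crossing = state.prev_pre_v < threshold <= pre_V
    state.prev_pre_v = float(pre_V)
    if state.release_steps > 0:
        state.release_steps -= 1
    elif crossing:
        state.release_steps = max(1, int(round(cdur / dt)))
    return cmax if state.release_steps > 0 else 0.0


def mg_block(v, mg: float = 1.0) -> np.ndarray:
    """Voltage-dependent magnesium unblock factor of the NMDA receptor."""
    return 1.0 / (1.0 + np.exp(-0.062 * np.asarray(v, dtype=float)) * (mg / 3.57))


def _exact_r_update(r, transmitter_on, alpha_T, beta, dt):
    """Exact exponential update of dr/dt = alpha*T*(1-r) - beta*r over one step."""
    if transmitter_on:
        k = alpha_T + beta
        rinf = alpha_T / k
        return rinf + (r - rinf) * np.exp(-k * dt)
    return r * np.exp(-beta * dt)


def update_receptor(
    spec: SynapseSpec,
    state: SynapseState,
    transmitter: float,
    post_V: float,
    dt: float,
) -> float:
    """Advance one synapse's kinetic state by dt; returns g_syn in nS.

    Scalar reference implementation of the per-receptor kinetics; the engine
    runs the same update vectorized over synapse groups with the exponential
    factors precomputed per dt.
    """
    on = transmitter > 0
    if spec.receptor == "GABA_B":
        k1, k2 = spec.param("k1"), spec.param("k2")
        k3, k4 = spec.param("k3"), spec.param("k4")
        state.r = float(_exact_r_update(state.r, on, k1 * spec.param("cmax"), k2, dt))
        e4 = np.exp(-k4 * dt)
        state.s = float(state.s * e4 + (k3 / k4) * state.r * (1.0 - e4))
        sn = state.s ** spec.param("n")
        g = spec.weight * spec.gmax * sn / (sn + spec.param("kd"))
    else:
        alpha, beta = spec.param("alpha"), spec.param("beta")
        state.r = float(_exact_r_update(state.r, on, alpha * spec.param("cmax"), beta, dt))
        g = spec.weight * spec.gmax * state.r
        if spec.receptor == "NMDA":
            g = g * float(mg_block(post_V, spec.param("mg")))
    if not np.isfinite(g) or not np.isfinite(state.r):
        raise FloatingPointError("non-finite synaptic state")
    return float(g)


def accumulate_synaptic(
    g_syn_nS: np.ndarray,
    esyn_mV: np.ndarray,
    post_nodes: np.ndarray,
    n_nodes: int,
    out_g: np.ndarray | None = None,
    out_gE: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Scatter point synaptic conductances into per-node solver accumulators.

    Point conductances in nS convert to the solver's area-scaled uS
    (1 nS = 1e-3 uS); each synapse adds g to its postsynaptic node's total
    conductance and g*Esyn to the matching driving-force sum.
    """
    g_uS = np.asarray(g_syn_nS, dtype=float) * 1e-3
    g_tot = out_g if out_g is not None else np.zeros(n_nodes)
    gE = out_gE if out_gE is not None else np.zeros(n_nodes)
    np.add.at(g_tot, post_nodes, g_uS)
    np.add.at(gE, post_nodes, g_uS * np.asarray(esyn_mV, dtype=float))
    return g_tot, gE


def quantize_fixed(x: np.ndarray | float, frac_bits: int = 18):
    """Round to ``frac_bits`` fractional bits (fixed-point state emulation)."""
    scale = float(1 << frac_bits)
    return np.round(np.asarray(x, dtype=float) * scale) / scale
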