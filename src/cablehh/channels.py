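"""Ion-channel kinetics via premultiplied voltage-indexed rate tables.

Each gating variable x follows first-order kinetics in either alpha/beta or
tau/x_inf form.  Folding the time step into the update gives, per step, a
single multiply-add from two voltage-indexed tables:

    x_{n+1} = r1(V_n) * x_n + r2(V_n)

with, for the alpha/beta formalism,

    r1(V) = 1 - dt*(alpha(V) + beta(V)),    r2(V) = dt*alpha(V)

and for the tau/x_inf formalism

    r1(V) = 1 - dt/tau(V),                  r2(V) = dt*x_inf(V)/tau(V).

Tables are built once per (gate, dt) at bin-centre voltages; lookup is
nearest-bin (a hardware-style address decode) with optional linear
interpolation in reference mode.  Out-of-range voltages saturate to the end
bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .morphology import CompartmentGrid
from .rates import RateFunction, compile_rate, finite_or_raise

__all__ = [
    "GateSpec",
    "RateTable",
    "ChannelSpec",
    "build_rate_table",
    "table_index",
    "update_gates",
    "accumulate_currents",
    "steady_state",
    "CHANNEL_PRESETS",
    "get_preset",
]

DEFAULT_VMIN = -100.0
DEFAULT_VMAX = 50.0
DEFAULT_NBINS = 4096


@dataclass
class GateSpec:
    """One gating variable of a channel.

    ``formalism`` selects between ``"alpha-beta"`` (supply ``alpha``/``beta``,
    ms^-1) and ``"tau-inf"`` (supply ``tau`` in ms and dimensionless ``inf``).
    ``exponent`` is the power of this gate in the conductance product.
    """

    name: str
    formalism: str  # "alpha-beta" | "tau-inf"
    exponent: int = 1
    alpha: RateFunction | None = None
    beta: RateFunction | None = None
    tau: RateFunction | None = None
    inf: RateFunction | None = None

    def __post_init__(self) -> None:
        if self.formalism not in ("alpha-beta", "tau-inf"):
            raise ValueError(f"gate {self.name!r}: unknown formalism {self.formalism!r}")
        if self.exponent < 1:
            raise ValueError(f"gate {self.name!r}: exponent must be >= 1")
        if self.formalism == "alpha-beta":
            if self.alpha is None or self.beta is None:
                raise ValueError(f"gate {self.name!r}: alpha and beta required")
            self.alpha = compile_rate(self.alpha)
            self.beta = compile_rate(self.beta)
        else:
            if self.tau is None or self.inf is None:
                raise ValueError(f"gate {self.name!r}: tau and inf required")
            self.tau = compile_rate(self.tau)
            self.inf = compile_rate(self.inf)

    def steady_state(self, v) -> np.ndarray:
        """Equilibrium open fraction at voltage v (alpha/(alpha+beta) or x_inf)."""
        if self.formalism == "alpha-beta":
            a, b = self.alpha(v), self.beta(v)
            with np.errstate(invalid="ignore", divide="ignore"):
                return np.where(a + b > 0, a / (a + b), np.nan)
        return self.inf(v)

    def digest_key(self) -> tuple:
        fns = tuple(
            f.digest_key() if f is not None else None
            for f in (self.alpha, self.beta, self.tau, self.inf)
        )
        return (self.name, self.formalism, self.exponent) + fns


@dataclass
class RateTable:
    """Premultiplied (r1, r2) coefficients for one gate at a fixed dt."""

    vmin: float
    vmax: float
    nbins: int
    dt: float
    r1: np.ndarray
    r2: np.ndarray

    @property
    def bin_width(self) -> float:
        return (self.vmax - self.vmin) / self.nbins

    @property
    def bin_centers(self) -> np.ndarray:
        return self.vmin + (np.arange(self.nbins) + 0.5) * self.bin_width

    def astype(self, dtype) -> "RateTable":
        return RateTable(self.vmin, self.vmax, self.nbins, self.dt,
                         self.r1.astype(dtype), self.r2.astype(dtype))


@dataclass
class ChannelSpec:
    """A conductance-based membrane current: gbar * prod(x^e) * (V - Erev).

    Densities (gbar, S/cm^2) live on sections; the spec carries the reversal
    potential, the gate list (empty for leak) and an optional ion label that
    section-level reversal overrides may address.
    """

    name: str
    erev: float
    gates: list[GateSpec] = field(default_factory=list)
    ion: str | None = None

    def digest_key(self) -> tuple:
        return (tuple(g.digest_key() for g in self.gates),)


def build_rate_table(
    gate: GateSpec,
    dt: float,
    vgrid: tuple[float, float, int] = (DEFAULT_VMIN, DEFAULT_VMAX, DEFAULT_NBINS),
    warn_unstable: bool = True,
) -> RateTable:
    """Tabulate (r1, r2) for one gate at bin-centre voltages.

    Raises if any rate evaluates non-finite on the grid.  Warns when
    |r1| >= 1 anywhere (the per-bin stability guard dt < 2/(alpha+beta),
    resp. dt < 2*tau, is violated there).
    """
    vmin, vmax, nbins = vgrid
    if not vmin < vmax:
        raise ValueError("vmin must be < vmax")
    if dt == 0 or not np.isfinite(dt):
        raise ValueError("dt must be nonzero and finite")
    v = vmin + (np.arange(int(nbins)) + 0.5) * (vmax - vmin) / int(nbins)
    if gate.formalism == "alpha-beta":
        a, b = gate.alpha(v), gate.beta(v)
        finite_or_raise(a, v, f"alpha of gate {gate.name!r}")
        finite_or_raise(b, v, f"beta of gate {gate.name!r}")
        r1 = 1.0 - dt * (a + b)
        r2 = dt * a
    else:
        tau, inf = gate.tau(v), gate.inf(v)
        finite_or_raise(tau, v, f"tau of gate {gate.name!r}")
        finite_or_raise(inf, v, f"inf of gate {gate.name!r}")
        if np.any(tau <= 0):
            raise ValueError(f"gate {gate.name!r}: tau must be positive on the table range")
        r1 = 1.0 - dt / tau
        r2 = dt * inf / tau
    if warn_unstable and dt > 0 and np.any(np.abs(r1) >= 1.0):
        k = int(np.argmax(np.abs(r1)))
        warnings.warn(
            f"gate {gate.name!r}: |r1| >= 1 at V = {v[k]:.2f} mV "
            f"(dt = {dt} ms exceeds the per-bin stability bound)",
            RuntimeWarning,
            stacklevel=2,
        )
    return RateTable(float(vmin), float(vmax), int(nbins), float(dt), r1, r2)


def table_index(V, vmin: float, vmax: float, nbins: int) -> np.ndarray:
    """Nearest-bin lookup index: floor((V - vmin)/binwidth), clamped to range."""
    w = (vmax - vmin) / nbins
    idx = np.floor((np.asarray(V) - vmin) / w).astype(np.int64)
    return np.clip(idx, 0, nbins - 1)


def update_gates(
    states: np.ndarray,
    V_prev: np.ndarray,
    table: RateTable,
    clamp: bool = False,
    interpolate: bool = False,
) -> np.ndarray:
    """One premultiplied-table step: x <- r1(V_prev)*x + r2(V_prev).

    ``V_prev`` is the membrane voltage of the previous completed step.  With
    ``interpolate`` the tables are linearly interpolated between bin centres
    (reference mode only); the default reproduces a hardware address decode.
    With ``clamp`` the result is clipped to [0, 1] (hardware-faithful mode).
    """
    V = np.asarray(V_prev)
    if interpolate:
        pos = (V - (table.vmin + 0.5 * table.bin_width)) / table.bin_width
        pos = np.clip(pos, 0.0, table.nbins - 1.0)
        lo = np.floor(pos).astype(np.int64)
        hi = np.minimum(lo + 1, table.nbins - 1)
        f = pos - lo
        r1 = table.r1[lo] * (1 - f) + table.r1[hi] * f
        r2 = table.r2[lo] * (1 - f) + table.r2[hi] * f
    else:
        idx = table_index(V, table.vmin, table.vmax, table.nbins)
        r1 = table.r1[idx]
        r2 = table.r2[idx]
    out = r1 * states + r2
    if clamp:
        out = np.clip(out, 0.0, 1.0)
    return out


def accumulate_currents(
    gate_states: dict[str, np.ndarray],
    channels: list[tuple[ChannelSpec, np.ndarray, np.ndarray]],
    out_g: np.ndarray | None = None,
    out_gE: np.ndarray | None = None,
    n_nodes: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sum channel conductances and conductance-weighted reversals per node.

    ``channels`` is a list of (spec, node_indices, gbar_uS) triples with
    gbar already area-scaled to uS per node; ``gate_states[gate_name]`` holds
    the per-node gate values for those same node indices.  Returns
    (g_tot [uS], gE_sum [nA]), the two membrane-current contributions to the
    solver's D and B coefficients.
    """
    if n_nodes is None:
        n_nodes = max((idx.max() + 1 for _, idx, _ in channels if len(idx)), default=0)
    g_tot = out_g if out_g is not None else np.zeros(n_nodes)
    gE = out_gE if out_gE is not None else np.zeros(n_nodes)
    for spec, idx, gbar in channels:
        g = gbar.copy()
        for gate in spec.gates:
            x = gate_states[gate.name]
            g = g * x**gate.exponent
        if np.any(~np.isfinite(g)):
            raise FloatingPointError(f"channel {spec.name!r}: non-finite conductance")
        np.add.at(g_tot, idx, g)
        np.add.at(gE, idx, g * spec.erev)
    return g_tot, gE


def steady_state(gate: GateSpec, v: float, table: RateTable | None = None) -> float:
    """Gate equilibrium at voltage v, falling back to the table fixed point.

    The direct value alpha/(alpha+beta) (or x_inf) is preferred; when the
    rates vanish the fixed point r2/(1 - r1) of the affine table update is
    used instead.  Raises if both are undefined.
    """
    x = float(np.asarray(gate.steady_state(v)))
    if np.isfinite(x):
        return x
    if table is not None:
        idx = int(table_index(v, table.vmin, table.vmax, table.nbins))
        denom = 1.0 - table.r1[idx]
        if denom != 0:
            return float(table.r2[idx] / denom)
    raise ValueError(f"gate {gate.name!r}: steady state undefined at V = {v} mV")


# --------------------------------------------------------------------------
# Built-in channel presets.
#
# The squid-axon set is the textbook Hodgkin-Huxley Na/K/Leak parametrization
# (rest near -65 mV).  The fast-spiking (FS) cortical set follows the
# Pospischil-style Na/Kd/M/Leak structure with representative stand-in
# parameters (VT = -58 mV threshold shift, tau_max = 600 ms for the slow
# potassium M-current); densities are chosen per fixture, not here.
# --------------------------------------------------------------------------

_VT = {"vt": -58.0}


def _presets() -> dict[str, ChannelSpec]:
    squid_na = ChannelSpec(
        name="squid_na", erev=50.0, ion="Na",
        gates=[
            GateSpec("m", "alpha-beta", 3,
                     alpha=RateFunction("0.1 * vtrap(-(v + 40.0), 10.0)"),
                     beta=RateFunction("4.0 * exp(-(v + 65.0) / 18.0)")),
            GateSpec("h", "alpha-beta", 1,
                     alpha=RateFunction("0.07 * exp(-(v + 65.0) / 20.0)"),
                     beta=RateFunction("1.0 / (1.0 + exp(-(v + 35.0) / 10.0))")),
        ],
    )
    squid_k = ChannelSpec(
        name="squid_k", erev=-77.0, ion="K",
        gates=[
            GateSpec("n", "alpha-beta", 4,
                     alpha=RateFunction("0.01 * vtrap(-(v + 55.0), 10.0)"),
                     beta=RateFunction("0.125 * exp(-(v + 65.0) / 80.0)")),
        ],
    )
    squid_leak = ChannelSpec(name="squid_leak", erev=-54.3, ion="Leak")

    fs_na = ChannelSpec(
        name="fs_na", erev=50.0, ion="Na",
        gates=[
            GateSpec("m", "alpha-beta", 3,
                     alpha=RateFunction("0.32 * vtrap(-(v - vt - 13.0), 4.0)", _VT),
                     beta=RateFunction("0.28 * vtrap(v - vt - 40.0, 5.0)", _VT)),
            GateSpec("h", "alpha-beta", 1,
                     alpha=RateFunction("0.128 * exp(-(v - vt - 17.0) / 18.0)", _VT),
                     beta=RateFunction("4.0 / (1.0 + exp(-(v - vt - 40.0) / 5.0))", _VT)),
        ],
    )
    fs_kd = ChannelSpec(
        name="fs_kd", erev=-90.0, ion="K",
        gates=[
            GateSpec("n", "alpha-beta", 4,
                     alpha=RateFunction("0.032 * vtrap(-(v - vt - 15.0), 5.0)", _VT),
                     beta=RateFunction("0.5 * exp(-(v - vt - 10.0) / 40.0)", _VT)),
        ],
    )
    fs_m = ChannelSpec(
        name="fs_m", erev=-90.0, ion="K",
        gates=[
            GateSpec("p", "tau-inf", 1,
                     tau=RateFunction(
                         "tau_max / (3.3 * exp((v + 35.0) / 20.0) + exp(-(v + 35.0) / 20.0))",
                         {"tau_max": 600.0}),
                     inf=RateFunction("1.0 / (1.0 + exp(-(v + 35.0) / 10.0))")),
        ],
    )
    fs_leak = ChannelSpec(name="fs_leak", erev=-70.4, ion="Leak")
    pas = ChannelSpec(name="pas", erev=-70.0, ion="Leak")
    return {c.name: c for c in
            (squid_na, squid_k, squid_leak, fs_na, fs_kd, fs_m, fs_leak, pas)}


CHANNEL_PRESETS: dict[str, ChannelSpec] = _presets()


def get_preset(name: str, erev: float | None = None) -> ChannelSpec:
    """A fresh copy of a built-in channel preset, optionally with Erev overridden."""
    import copy

    if name not in CHANNEL_PRESETS:
        raise KeyError(f"unknown channel preset {name!r}; "
                       f"available: {sorted(CHANNEL_PRESETS)}")
    spec = copy.deepcopy(CHANNEL_PRESETS[name])
    if erev is not None:
        spec.erev = float(erev)
    return spec
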