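"""Configuration files: schema validation, loading, dumping, digests.

A network configuration is a structured YAML or JSON document with blocks
``neurons`` (morphology + channel densities per section), ``channels``
(user-defined channel kinetics, extending the built-in presets),
``synapses`` (sparse list or dense weight-matrix form), ``stimuli`` and
``simulation``.  Loading validates the schema (unknown keys are rejected
with their path), fills documented defaults, and computes a content digest
over the normalized document, so the digest is stable under key reordering
and comments but changes with any semantically meaningful field.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import yaml

from .channels import CHANNEL_PRESETS, ChannelSpec, GateSpec
from .engine import Network, NeuronModel, SimulationConfig, StimulusPulse
from .morphology import Section
from .rates import RateFunction
from .synapses import RECEPTOR_TYPES, SynapseSpec

__all__ = ["ConfigError", "ConfigBundle", "load_config", "loads", "dumps", "digest"]


class ConfigError(ValueError):
    """Schema violation(s); ``errors`` holds (path, message) pairs."""

    def __init__(self, errors: list[tuple[str, str]]):
        self.errors = errors
        super().__init__("; ".join(f"{p}: {m}" for p, m in errors))


@dataclass
class ConfigBundle:
    """A loaded configuration: runnable objects plus normalized provenance."""

    network: Network
    sim: SimulationConfig
    stimuli: list[StimulusPulse]
    data: dict = field(repr=False, default_factory=dict)  # normalized document
    digest: str = ""


_SECTION_KEYS = {"name", "length", "diameter", "nseg", "ra", "cm",
                 "channels", "reversal_potentials", "parent"}
_NEURON_KEYS = {"name", "v_rest", "sections"}
_GATE_KEYS = {"name", "formalism", "exponent", "alpha", "beta", "tau", "inf", "params"}
_CHANNEL_KEYS = {"erev", "ion", "gates"}
_SYN_KEYS = {"pre", "post", "receptor", "weight", "gmax", "params"}
_MATRIX_KEYS = {"matrix"}
_MATRIX_INNER = {"pre_neuron", "post_neuron", "receptor", "gmax", "weights", "params"}
_STIM_KEYS = {"neuron", "node", "onset", "duration", "amplitude"}
_SIM_KEYS = {"dt", "duration", "mode", "synapse_precision", "table_nbins",
             "table_vmin", "table_vmax", "record", "record_period",
             "interp_lookup", "clamp_gates", "staggered_gates", "settle",
             "v_init", "seed"}
_TOP_KEYS = {"neurons", "channels", "synapses", "stimuli", "simulation"}


def _check_keys(d, allowed, required, path, errors) -> bool:
    if not isinstance(d, dict):
        errors.append((path, f"expected a mapping, got {type(d).__name__}"))
        return False
    ok = True
    for k in d:
        if k not in allowed:
            errors.append((f"{path}.{k}", "unknown key"))
            ok = False
    for k in required:
        if k not in d:
            errors.append((path, f"missing required key {k!r}"))
            ok = False
    return ok


def _neuron_index(ref, names: list[str], path: str, errors) -> int | None:
    if isinstance(ref, bool):
        errors.append((path, "neuron reference must be an index or name"))
        return None
    if isinstance(ref, int):
        if 0 <= ref < len(names):
            return ref
        errors.append((path, f"neuron index {ref} out of range (have {len(names)})"))
        return None
    if isinstance(ref, str) and ref in names:
        return names.index(ref)
    errors.append((path, f"unknown neuron {ref!r}"))
    return None


def loads(doc: dict) -> ConfigBundle:
    """Validate a configuration document and build runnable objects.

    Raises ConfigError listing every schema violation with its path.
    """
    errors: list[tuple[str, str]] = []
    if not _check_keys(doc, _TOP_KEYS, {"neurons"}, "$", errors):
        raise ConfigError(errors)

    # user channel definitions
    channel_defs: dict[str, ChannelSpec] = {}
    norm_channels: dict = {}
    for cname, cdef in (doc.get("channels") or {}).items():
        path = f"channels.{cname}"
        if not _check_keys(cdef, _CHANNEL_KEYS, {"erev"}, path, errors):
            continue
        gates = []
        norm_gates = []
        for gi, gdef in enumerate(cdef.get("gates") or []):
            gpath = f"{path}.gates[{gi}]"
            if not _check_keys(gdef, _GATE_KEYS, {"name", "formalism"}, gpath, errors):
                continue
            params = dict(gdef.get("params") or {})
            kw = {}
            try:
                for fkey in ("alpha", "beta", "tau", "inf"):
                    if fkey in gdef:
                        kw[fkey] = RateFunction(str(gdef[fkey]), params)
                gates.append(GateSpec(gdef["name"], gdef["formalism"],
                                      int(gdef.get("exponent", 1)), **kw))
            except ValueError as exc:
                errors.append((gpath, str(exc)))
                continue
            norm_gates.append({
                "name": gdef["name"], "formalism": gdef["formalism"],
                "exponent": int(gdef.get("exponent", 1)),
                **{k: str(gdef[k]) for k in ("alpha", "beta", "tau", "inf") if k in gdef},
                "params": params,
            })
        channel_defs[cname] = ChannelSpec(cname, float(cdef["erev"]), gates,
                                          cdef.get("ion"))
        norm_channels[cname] = {"erev": float(cdef["erev"]),
                                "ion": cdef.get("ion"), "gates": norm_gates}

    # neurons
    neurons: list[NeuronModel] = []
    names: list[str] = []
    node_counts: list[int] = []
    norm_neurons = []
    for ni, ndef in enumerate(doc.get("neurons") or []):
        path = f"neurons[{ni}]"
        if not _check_keys(ndef, _NEURON_KEYS, {"sections"}, path, errors):
            continue
        name = str(ndef.get("name", f"neuron{ni}"))
        sections = []
        norm_sections = []
        count = 0
        for si, sdef in enumerate(ndef.get("sections") or []):
            spath = f"{path}.sections[{si}]"
            if not _check_keys(sdef, _SECTION_KEYS, {"name", "length", "diameter"},
                               spath, errors):
                continue
            diam = sdef["diameter"]
            if isinstance(diam, (list, tuple)):
                diam = (float(diam[0]), float(diam[1]))
            else:
                diam = float(diam)
            parent = sdef.get("parent")
            if parent is not None:
                parent = (str(parent[0]), str(parent[1]))
            dens = {str(k): float(v) for k, v in (sdef.get("channels") or {}).items()}
            for chan in dens:
                if chan not in channel_defs and chan not in CHANNEL_PRESETS:
                    errors.append((f"{spath}.channels.{chan}", "unknown channel"))
            try:
                sections.append(Section(
                    name=str(sdef["name"]), length=float(sdef["length"]),
                    diameter=diam, nseg=int(sdef.get("nseg", 1)),
                    Ra=float(sdef.get("ra", 150.0)), Cm=float(sdef.get("cm", 1.0)),
                    channel_densities=dens,
                    reversal_potentials={str(k): float(v) for k, v in
                                         (sdef.get("reversal_potentials") or {}).items()},
                    parent=parent,
                ))
            except ValueError as exc:
                errors.append((spath, str(exc)))
                continue
            count += int(sdef.get("nseg", 1))
            norm_sections.append({
                "name": str(sdef["name"]), "length": float(sdef["length"]),
                "diameter": list(diam) if isinstance(diam, tuple) else diam,
                "nseg": int(sdef.get("nseg", 1)), "ra": float(sdef.get("ra", 150.0)),
                "cm": float(sdef.get("cm", 1.0)), "channels": dens,
                "reversal_potentials": {str(k): float(v) for k, v in
                                        (sdef.get("reversal_potentials") or {}).items()},
                "parent": list(parent) if parent else None,
            })
        v_rest = float(ndef.get("v_rest", -65.0))
        neurons.append(NeuronModel(name, sections, channel_defs, v_rest))
        names.append(name)
        node_counts.append(count)
        norm_neurons.append({"name": name, "v_rest": v_rest, "sections": norm_sections})

    # synapses (sparse entries and/or dense matrix blocks)
    synapses: list[SynapseSpec] = []
    norm_synapses = []
    for yi, ydef in enumerate(doc.get("synapses") or []):
        path = f"synapses[{yi}]"
        if isinstance(ydef, dict) and "matrix" in ydef:
            if not _check_keys(ydef, _MATRIX_KEYS, {"matrix"}, path, errors):
                continue
            m = ydef["matrix"]
            if not _check_keys(m, _MATRIX_INNER,
                               {"pre_neuron", "post_neuron", "receptor", "weights"},
                               f"{path}.matrix", errors):
                continue
            pi = _neuron_index(m["pre_neuron"], names, f"{path}.matrix.pre_neuron", errors)
            qi = _neuron_index(m["post_neuron"], names, f"{path}.matrix.post_neuron", errors)
            if pi is None or qi is None:
                continue
            W = np.asarray(m["weights"], dtype=float)
            if W.shape != (node_counts[pi], node_counts[qi]):
                errors.append((f"{path}.matrix.weights",
                               f"shape {W.shape} != ({node_counts[pi]}, {node_counts[qi]})"))
                continue
            for i, j in zip(*np.nonzero(W)):
                synapses.append(SynapseSpec(
                    (pi, int(i)), (qi, int(j)), str(m["receptor"]),
                    weight=float(W[i, j]), gmax=m.get("gmax"),
                    params=dict(m.get("params") or {})))
            norm_synapses.append({"matrix": {
                "pre_neuron": pi, "post_neuron": qi, "receptor": str(m["receptor"]),
                "gmax": m.get("gmax"), "weights": W.tolist(),
                "params": dict(m.get("params") or {})}})
            continue
        if not _check_keys(ydef, _SYN_KEYS, {"pre", "post", "receptor"}, path, errors):
            continue
        receptor = str(ydef["receptor"])
        if receptor not in RECEPTOR_TYPES:
            errors.append((f"{path}.receptor",
                           f"unknown receptor {receptor!r}; one of {RECEPTOR_TYPES}"))
            continue
        entry = {}
        ok = True
        for end in ("pre", "post"):
            ref = ydef[end]
            idx = _neuron_index(ref[0], names, f"{path}.{end}", errors)
            if idx is None:
                ok = False
                continue
            node = int(ref[1])
            if not (0 <= node < node_counts[idx]):
                errors.append((f"{path}.{end}",
                               f"node {node} out of range for neuron {names[idx]!r} "
                               f"({node_counts[idx]} nodes)"))
                ok = False
                continue
            entry[end] = (idx, node)
        if not ok:
            continue
        spec = SynapseSpec(entry["pre"], entry["post"], receptor,
                           weight=float(ydef.get("weight", 1.0)),
                           gmax=ydef.get("gmax"),
                           params=dict(ydef.get("params") or {}))
        synapses.append(spec)
        norm_synapses.append({
            "pre": list(entry["pre"]), "post": list(entry["post"]),
            "receptor": receptor, "weight": spec.weight, "gmax": spec.gmax,
            "params": dict(spec.params)})

    # stimuli
    stimuli: list[StimulusPulse] = []
    norm_stimuli = []
    for si, sdef in enumerate(doc.get("stimuli") or []):
        path = f"stimuli[{si}]"
        if not _check_keys(sdef, _STIM_KEYS,
                           {"neuron", "node", "onset", "duration", "amplitude"},
                           path, errors):
            continue
        idx = _neuron_index(sdef["neuron"], names, f"{path}.neuron", errors)
        if idx is None:
            continue
        node = int(sdef["node"])
        if not (0 <= node < node_counts[idx]):
            errors.append((f"{path}.node", f"node {node} out of range "
                           f"for neuron {names[idx]!r}"))
            continue
        try:
            stimuli.append(StimulusPulse(idx, node, float(sdef["onset"]),
                                         float(sdef["duration"]),
                                         float(sdef["amplitude"])))
        except ValueError as exc:
            errors.append((path, str(exc)))
            continue
        norm_stimuli.append({"neuron": idx, "node": node,
                             "onset": float(sdef["onset"]),
                             "duration": float(sdef["duration"]),
                             "amplitude": float(sdef["amplitude"])})

    # simulation settings
    sdef = doc.get("simulation") or {}
    _check_keys(sdef, _SIM_KEYS, set(), "simulation", errors)
    record = sdef.get("record", "all")
    if record != "all":
        rec = []
        for ri, pair in enumerate(record):
            idx = _neuron_index(pair[0], names, f"simulation.record[{ri}]", errors)
            if idx is None:
                continue
            node = int(pair[1])
            if not (0 <= node < node_counts[idx]):
                errors.append((f"simulation.record[{ri}]", f"node {node} out of range"))
                continue
            rec.append((idx, node))
        record = rec
    try:
        sim = SimulationConfig(
            duration=float(sdef.get("duration", 100.0)),
            dt=float(sdef.get("dt", 0.03125)),
            mode=str(sdef.get("mode", "reference-64bit")),
            synapse_precision=str(sdef.get("synapse_precision", "reference")),
            table_nbins=int(sdef.get("table_nbins", 4096)),
            table_vmin=float(sdef.get("table_vmin", -100.0)),
            table_vmax=float(sdef.get("table_vmax", 50.0)),
            record=record,
            record_period=(None if sdef.get("record_period") is None
                           else float(sdef["record_period"])),
            interp_lookup=bool(sdef.get("interp_lookup", False)),
            clamp_gates=sdef.get("clamp_gates"),
            staggered_gates=bool(sdef.get("staggered_gates", False)),
            settle=float(sdef.get("settle", 0.0)),
            v_init=(None if sdef.get("v_init") is None else float(sdef["v_init"])),
            seed=int(sdef.get("seed", 0)),
        )
    except ValueError as exc:
        errors.append(("simulation", str(exc)))
        sim = None

    if errors:
        raise ConfigError(errors)

    normalized = {
        "neurons": norm_neurons,
        "channels": norm_channels,
        "synapses": norm_synapses,
        "stimuli": norm_stimuli,
        "simulation": {
            "duration": sim.duration, "dt": sim.dt, "mode": sim.mode,
            "synapse_precision": sim.synapse_precision,
            "table_nbins": sim.table_nbins, "table_vmin": sim.table_vmin,
            "table_vmax": sim.table_vmax,
            "record": "all" if sim.record == "all" else [list(p) for p in sim.record],
            "record_period": sim.record_period,
            "interp_lookup": sim.interp_lookup, "clamp_gates": sim.clamp_gates,
            "staggered_gates": sim.staggered_gates, "settle": sim.settle,
            "v_init": sim.v_init, "seed": sim.seed,
        },
    }
    return ConfigBundle(network=Network(neurons, synapses), sim=sim,
                        stimuli=stimuli, data=normalized,
                        digest=digest(normalized))


def digest(normalized: dict) -> str:
    """Content digest of a normalized document (key order never matters)."""
    blob = json.dumps(normalized, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()


def load_config(path: str) -> ConfigBundle:
    """Load and validate a YAML (or JSON; JSON is a YAML subset) config file."""
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError([("$", f"parse error: {exc}")]) from exc
    if not isinstance(doc, dict):
        raise ConfigError([("$", "top level must be a mapping")])
    return loads(doc)


def dumps(bundle_or_doc) -> str:
    """Serialize a (normalized) configuration back to YAML."""
    doc = bundle_or_doc.data if isinstance(bundle_or_doc, ConfigBundle) else bundle_or_doc
    return yaml.safe_dump(doc, sort_keys=True)
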