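"""Built-in demonstration and test configurations.

Four generators return complete, runnable configuration documents:

``fs_soma_64``
    A fast-spiking cortical soma (length 70 um, diameter 9 um) modeled with
    64 compartments and the FS-style Na/Kd/M/Leak preset, driven by a 15 ms,
    0.3 nA pulse into the first compartment (the pulse-response validation
    protocol; 0.3 nA is the demonstration drive, 15 ms the pulse length).
``motoneuron_like_64``
    A synthetic stand-in for a reduced embryonic motor-neuron morphology:
    soma + active axon initial segment + axon + branched dendrites, 64
    compartments in total.  The topology mirrors the reduced model family
    (sodium only in the axonal sections); lengths, diameters and densities
    are plausible placeholders, not published values.
``squid_axon_chain``
    An unbranched chain with classic squid-axon Na/K/Leak kinetics, for
    excitability and rheobase tests.
``random_tree``
    A seeded random passive tree (<= 128 nodes) for solver property tests.
"""

from __future__ import annotations

import numpy as np

__all__ = ["FIXTURE_NAMES", "make_fixture"]

FIXTURE_NAMES = ("fs_soma_64", "motoneuron_like_64", "squid_axon_chain", "random_tree")

# FS-style densities (S/cm^2): representative stand-ins for a fast-spiking
# cortical cell (Na/Kd spiking, weak M-current adaptation, leak at -70.4 mV).
_FS_CHANNELS = {"fs_na": 0.05, "fs_kd": 0.005, "fs_m": 1e-5, "fs_leak": 3.8e-5}


def _simulation(duration: float, **over) -> dict:
    sim = {"dt": 0.03125, "duration": duration, "record": "all",
           "record_period": 1.0}
    sim.update(over)
    return sim


def _fs_soma_64() -> dict:
    return {
        "neurons": [{
            "name": "fs0",
            "v_rest": -70.4,
            "sections": [{
                "name": "soma", "length": 70.0, "diameter": 9.0, "nseg": 64,
                "ra": 150.0, "cm": 1.0, "channels": dict(_FS_CHANNELS),
            }],
        }],
        "stimuli": [{"neuron": 0, "node": 0, "onset": 10.0, "duration": 15.0,
                     "amplitude": 0.3}],
        "simulation": _simulation(1000.0),
    }


def _motoneuron_like_64() -> dict:
    # 4 + 4 + 16 + 8 + 16 + 16 = 64 compartments
    sections = [
        {"name": "soma", "length": 30.0, "diameter": 20.0, "nseg": 4,
         "channels": {"squid_k": 0.012, "squid_leak": 1e-4}},
        {"name": "ais", "length": 30.0, "diameter": 2.5, "nseg": 4,
         "parent": ["soma", "distal"],
         "channels": {"squid_na": 0.5, "squid_k": 0.08, "squid_leak": 1e-4}},
        {"name": "axon", "length": 400.0, "diameter": 1.5, "nseg": 16,
         "parent": ["ais", "distal"],
         "channels": {"squid_na": 0.12, "squid_k": 0.036, "squid_leak": 1e-4}},
        {"name": "dend_main", "length": 150.0, "diameter": 4.0, "nseg": 8,
         "parent": ["soma", "proximal"],
         "channels": {"squid_leak": 1e-4}},
        {"name": "dend_a", "length": 250.0, "diameter": 2.0, "nseg": 16,
         "parent": ["dend_main", "distal"],
         "channels": {"squid_leak": 1e-4}},
        {"name": "dend_b", "length": 250.0, "diameter": 2.0, "nseg": 16,
         "parent": ["dend_main", "distal"],
         "channels": {"squid_leak": 1e-4}},
    ]
    for s in sections:
        s.setdefault("ra", 150.0)
        s.setdefault("cm", 1.0)
    return {
        "neurons": [{"name": "mn0", "v_rest": -65.0, "sections": sections}],
        "stimuli": [{"neuron": 0, "node": 0, "onset": 10.0, "duration": 15.0,
                     "amplitude": 1.5}],
        "simulation": _simulation(100.0),
    }


def _squid_axon_chain() -> dict:
    return {
        "neurons": [{
            "name": "axon0",
            "v_rest": -65.0,
            "sections": [{
                "name": "axon", "length": 600.0, "diameter": 2.0, "nseg": 16,
                "ra": 150.0, "cm": 1.0,
                "channels": {"squid_na": 0.12, "squid_k": 0.036,
                             "squid_leak": 3e-4},
            }],
        }],
        "stimuli": [{"neuron": 0, "node": 0, "onset": 5.0, "duration": 90.0,
                     "amplitude": 0.3}],
        "simulation": _simulation(100.0, dt=0.025),
    }


def _random_tree(seed: int) -> dict:
    rng = np.random.default_rng(seed)
    n_sections = int(rng.integers(2, 9))
    sections = []
    total = 0
    for k in range(n_sections):
        nseg = int(rng.integers(1, 17))
        if total + nseg > 128:
            nseg = max(1, 128 - total)
        total += nseg
        sec = {
            "name": f"sec{k}",
            "length": float(np.round(rng.uniform(20.0, 300.0), 3)),
            "diameter": float(np.round(rng.uniform(0.5, 10.0), 3)),
            "nseg": nseg,
            "ra": float(np.round(rng.uniform(80.0, 250.0), 3)),
            "cm": float(np.round(rng.uniform(0.6, 2.0), 3)),
            "channels": {"pas": float(np.round(rng.uniform(2e-5, 3e-4), 9))},
        }
        if k > 0:
            parent = int(rng.integers(0, k))
            end = "distal" if rng.random() < 0.5 else "proximal"
            sec["parent"] = [f"sec{parent}", end]
        sections.append(sec)
        if total >= 128:
            break
    return {
        "neurons": [{"name": "rand0", "v_rest": -70.0, "sections": sections}],
        "simulation": _simulation(50.0, seed=int(seed)),
    }


def make_fixture(name: str, seed: int = 0) -> dict:
    """Return a complete configuration document for a named fixture.

    ``seed`` is used only by ``random_tree``; two calls with the same seed
    produce identical documents.
    """
    if name == "fs_soma_64":
        return _fs_soma_64()
    if name == "motoneuron_like_64":
        return _motoneuron_like_64()
    if name == "squid_axon_chain":
        return _squid_axon_chain()
    if name == "random_tree":
        return _random_tree(seed)
    raise KeyError(f"unknown fixture {name!r}; one of {FIXTURE_NAMES}")
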