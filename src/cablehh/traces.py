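"""Trace serialization: delimited text and hierarchical binary (HDF5).

Text traces carry one tab-separated header line (time + compartment labels)
and one row per sample at full round-trippable decimal precision, so
`compare` stays meaningful on text files.  Binary traces store the same
arrays in an HDF5 file with metadata attributes and round-trip exactly;
binary is the better default for long runs.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .engine import TraceRecord, count_spikes

__all__ = ["write_traces", "read_traces", "compare_traces"]

_TEXT_SUFFIXES = (".tsv", ".txt", ".csv", ".dat")


def _is_binary_path(path: str, fmt: str | None) -> bool:
    if fmt is not None:
        if fmt in ("binary", "h5", "hdf5", "binary-hierarchical"):
            return True
        if fmt in ("text", "tsv", "delimited-text"):
            return False
        raise ValueError(f"unknown trace format {fmt!r}")
    return not str(path).lower().endswith(_TEXT_SUFFIXES)


def write_traces(record: TraceRecord, path: str, format: str | None = None) -> None:
    """Write a trace record; format inferred from the suffix unless given."""
    if len(record.time) != record.voltages.shape[0]:
        raise ValueError("time and voltage row counts differ")
    if _is_binary_path(path, format):
        with h5py.File(path, "w") as fh:
            fh.create_dataset("time_ms", data=np.asarray(record.time, dtype=np.float64))
            fh.create_dataset("voltages_mV", data=np.asarray(record.voltages))
            fh.attrs["labels"] = json.dumps(record.labels)
            fh.attrs["meta"] = json.dumps(record.meta)
    else:
        header = "\t".join(["time_ms"] + list(record.labels))
        data = np.column_stack([np.asarray(record.time, dtype=np.float64),
                                np.asarray(record.voltages, dtype=np.float64)])
        np.savetxt(path, data, fmt="%.17g", delimiter="\t",
                   header=header, comments="")


def read_traces(path: str) -> TraceRecord:
    """Read a trace file written by :func:`write_traces` (either format)."""
    if h5py.is_hdf5(path):
        with h5py.File(path, "r") as fh:
            time = fh["time_ms"][...]
            volts = fh["voltages_mV"][...]
            labels = json.loads(fh.attrs.get("labels", "[]"))
            meta = json.loads(fh.attrs.get("meta", "{}"))
        return TraceRecord(time=time, voltages=volts, labels=labels, meta=meta)
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if not header or header[0] != "time_ms":
            raise ValueError(f"{path}: not a trace file (bad header)")
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    if data.size and data.shape[1] != len(header):
        raise ValueError(f"{path}: header names {len(header)} columns, "
                         f"rows have {data.shape[1]}")
    return TraceRecord(time=data[:, 0], voltages=data[:, 1:], labels=header[1:],
                       meta={})


def compare_traces(a: TraceRecord, b: TraceRecord,
                   spike_threshold: float = 0.0) -> list[dict]:
    """Per-channel RMS voltage difference and spike counts of two traces.

    Channels are matched by label where possible, else by position; the two
    records must share their time base.  Symmetric in its inputs.
    """
    if a.voltages.shape != b.voltages.shape:
        raise ValueError(f"shape mismatch: {a.voltages.shape} vs {b.voltages.shape}")
    if len(a.time) != len(b.time) or not np.allclose(a.time, b.time):
        raise ValueError("time bases differ")
    rows = []
    for k, label in enumerate(a.labels):
        j = b.labels.index(label) if label in b.labels else k
        va = np.asarray(a.voltages[:, k], dtype=np.float64)
        vb = np.asarray(b.voltages[:, j], dtype=np.float64)
        rows.append({
            "label": label,
            "rms_mV": float(np.sqrt(np.mean((va - vb) ** 2))),
            "max_abs_mV": float(np.max(np.abs(va - vb))) if len(va) else 0.0,
            "spikes_a": count_spikes(a.time, va, spike_threshold),
            "spikes_b": count_spikes(b.time, vb, spike_threshold),
        })
    return rows
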