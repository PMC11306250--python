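"""Trace and transient file formats.

A trace is a two-column TSV (``x_driven_nm``, ``x_passive_nm``; the
time base is implicit in the sample rate) plus a JSON sidecar
``<path>.json`` holding every parameter, the seed and the truth
intervals.  An HDF5 backend stores the identical schema in one file.
Transients are two-column TSVs (``t_s``, ``signal``).
"""

from __future__ import annotations

import json
import os

import pandas as pd

from . import __version__
from .params import ParameterError
from .synthetics import StateTrajectory, Transient, TrapTrace

__all__ = [
    "write_trace", "read_trace",
    "write_trace_h5", "read_trace_h5",
    "write_transient", "read_transient",
]


class SchemaError(ParameterError):
    """A file did not match the expected schema; names the missing field."""


def _sidecar_payload(trace: TrapTrace) -> dict:
    payload = {
        "format_version": 1,
        "package_version": __version__,
        "sample_rate": trace.sample_rate,
        "metadata": trace.metadata,
    }
    if trace.truth is not None:
        payload["truth_intervals"] = trace.truth.to_records()
    return payload


def write_trace(trace: TrapTrace, path: str) -> None:
    """Write a trace as TSV + JSON sidecar (``path`` and ``path.json``)."""
    df = pd.DataFrame({"x_driven_nm": trace.x_driven,
                       "x_passive_nm": trace.x_passive})
    # no float_format: shortest-round-trip repr keeps the values lossless
    df.to_csv(path, sep="\t", index=False)
    with open(path + ".json", "w") as fh:
        json.dump(_sidecar_payload(trace), fh, indent=1)


def read_trace(path: str) -> TrapTrace:
    side = path + ".json"
    if not os.path.exists(side):
        raise SchemaError(f"missing sidecar {side}")
    with open(side) as fh:
        payload = json.load(fh)
    for field in ("sample_rate", "metadata"):
        if field not in payload:
            raise SchemaError(f"sidecar lacks field {field!r}")
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in ("x_driven_nm", "x_passive_nm"):
        if col not in df.columns:
            raise SchemaError(f"trace lacks column {col!r}")
    truth = None
    if "truth_intervals" in payload:
        truth = StateTrajectory.from_records(payload["truth_intervals"])
    return TrapTrace(df["x_driven_nm"].to_numpy(),
                     df["x_passive_nm"].to_numpy(),
                     payload["sample_rate"], payload["metadata"], truth)


def write_trace_h5(trace: TrapTrace, path: str) -> None:
    import h5py

    with h5py.File(path, "w") as h5:
        h5.create_dataset("x_driven_nm", data=trace.x_driven)
        h5.create_dataset("x_passive_nm", data=trace.x_passive)
        h5.attrs["sidecar"] = json.dumps(_sidecar_payload(trace))


def read_trace_h5(path: str) -> TrapTrace:
    import h5py

    with h5py.File(path, "r") as h5:
        for col in ("x_driven_nm", "x_passive_nm"):
            if col not in h5:
                raise SchemaError(f"HDF5 file lacks dataset {col!r}")
        if "sidecar" not in h5.attrs:
            raise SchemaError("HDF5 file lacks attribute 'sidecar'")
        payload = json.loads(h5.attrs["sidecar"])
        xd = h5["x_driven_nm"][:]
        xp = h5["x_passive_nm"][:]
    truth = None
    if "truth_intervals" in payload:
        truth = StateTrajectory.from_records(payload["truth_intervals"])
    return TrapTrace(xd, xp, payload["sample_rate"],
                     payload["metadata"], truth)


def write_transient(transient: Transient, path: str) -> None:
    df = pd.DataFrame({"t_s": transient.time, "signal": transient.signal})
    df.to_csv(path, sep="\t", index=False)
    if transient.truth_rate is not None:
        with open(path + ".json", "w") as fh:
            json.dump({"truth_rate": transient.truth_rate}, fh)


def read_transient(path: str) -> Transient:
    df = pd.read_csv(path, sep="\t")
    for col in ("t_s", "signal"):
        if col not in df.columns:
            raise SchemaError(f"transient lacks column {col!r}")
    truth = None
    side = path + ".json"
    if os.path.exists(side):
        with open(side) as fh:
            truth = json.load(fh).get("truth_rate")
    return Transient(df["t_s"].to_numpy(), df["signal"].to_numpy(),
                     truth_rate=truth)
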