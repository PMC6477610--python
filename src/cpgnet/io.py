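"""Trace and report serialization.

Traces export to delimited text (CSV with a ``#``-prefixed provenance/unit
header; one row per sample, one column per neuron variable) or to an HDF5
container for long runs.  Both round-trip: HDF5 bit-exactly, text to the
printed precision (1e-6 mV).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .rhythm import BurstReport, CycleReport, ResetReport
from .simulate import TraceSet

__all__ = ["export_traces", "load_traces", "report_to_dict", "save_report"]


class TraceIOError(IOError):
    pass


def export_traces(traces: TraceSet, path: str | Path, format: str | None = None) -> Path:
    """Write a TraceSet to ``path`` as text (.csv) or binary (.h5).

    The format is inferred from the suffix unless given explicitly.
    Refuses to write an empty trace set.
    """
    path = Path(path)
    if traces.V.size == 0 or not traces.neurons:
        raise TraceIOError("refusing to export an empty TraceSet")
    fmt = format or ("hdf5" if path.suffix in (".h5", ".hdf5") else "text")
    if fmt == "text":
        _export_text(traces, path)
    elif fmt == "hdf5":
        _export_hdf5(traces, path)
    else:
        raise TraceIOError(f"unknown trace format {format!r}")
    return path


def _columns(traces: TraceSet) -> tuple[list[str], np.ndarray]:
    cols = ["time_s"]
    arrays = [traces.time[:, None]]
    for i, name in enumerate(traces.neurons):
        cols.append(f"{name}.V_mV")
        arrays.append(traces.V[:, i:i + 1])
    if traces.m is not None:
        for i, name in enumerate(traces.neurons):
            cols.extend([f"{name}.m", f"{name}.h"])
            arrays.extend([traces.m[:, i:i + 1], traces.h[:, i:i + 1]])
    return cols, np.hstack(arrays)


def _export_text(traces: TraceSet, path: Path) -> None:
    cols, data = _columns(traces)
    header = ["# cpgnet trace export",
              "# units: time s, voltage mV, gates dimensionless",
              "# provenance: " + json.dumps(traces.provenance, sort_keys=True),
              ",".join(cols)]
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        np.savetxt(fh, data, fmt="%.6f", delimiter=",")


def _export_hdf5(traces: TraceSet, path: Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("time", data=traces.time)
        f.create_dataset("V", data=traces.V)
        if traces.m is not None:
            f.create_dataset("m", data=traces.m)
            f.create_dataset("h", data=traces.h)
        f.attrs["neurons"] = json.dumps(traces.neurons)
        f.attrs["provenance"] = json.dumps(traces.provenance, sort_keys=True)
        f.attrs["units"] = "time s, voltage mV"


def load_traces(path: str | Path) -> TraceSet:
    """Read back a trace export (text or HDF5)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as f:
            return TraceSet(
                time=f["time"][:], V=f["V"][:],
                m=f["m"][:] if "m" in f else None,
                h=f["h"][:] if "h" in f else None,
                neurons=json.loads(f.attrs["neurons"]),
                provenance=json.loads(f.attrs["provenance"]),
            )
    prov: dict = {}
    with open(path) as fh:
        header_cols: list[str] | None = None
        skip = 0
        for line in fh:
            skip += 1
            if line.startswith("# provenance: "):
                prov = json.loads(line[len("# provenance: "):])
            elif not line.startswith("#"):
                header_cols = line.strip().split(",")
                break
    if not header_cols:
        raise TraceIOError(f"{path}: no column header found")
    data = np.loadtxt(path, delimiter=",", skiprows=skip)
    data = np.atleast_2d(data)
    names = [cname[:-len(".V_mV")] for cname in header_cols if cname.endswith(".V_mV")]
    time = data[:, 0]
    nv = len(names)
    V = data[:, 1:1 + nv]
    m = h = None
    if len(header_cols) > 1 + nv:
        gates = data[:, 1 + nv:]
        m = gates[:, 0::2]
        h = gates[:, 1::2]
    return TraceSet(time=time, V=V, m=m, h=h, neurons=names, provenance=prov)


def report_to_dict(report) -> dict:
    """Structured (JSON-ready) form of any analysis report."""
    if isinstance(report, CycleReport):
        mean, sd, n = report.mean_period()
        return {"kind": "cycles", "threshold_mV": report.threshold,
                "crossings_s": report.crossings.tolist(),
                "periods_s": report.periods.tolist(),
                "mean_period_s": mean, "sd_period_s": sd, "n_periods": n,
                "flags": report.flags}
    if isinstance(report, ResetReport):
        return {"kind": "reset", "classification": report.classification,
                "shift_fraction": report.shift, "period_s": report.period,
                "tolerance": report.tolerance,
                "predicted_s": report.predicted.tolist(),
                "observed_s": report.observed.tolist(),
                "shifts_fraction": report.shifts.tolist()}
    if isinstance(report, BurstReport):
        return {"kind": "bursts", "threshold_mV": report.threshold,
                "onsets_s": report.onsets.tolist(),
                "offsets_s": report.offsets.tolist(),
                "durations_s": report.durations.tolist(),
                "deletion_onsets_s": report.deletions().tolist(),
                "flags": report.flags}
    raise TypeError(f"unknown report type {type(report).__name__}")


def save_report(report, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(report_to_dict(report), indent=1))
    return path
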