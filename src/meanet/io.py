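"""On-disk formats.

Documented container layouts (no proprietary vendor dialects — convert
first):

* Raw recording: HDF5 with dataset ``signal`` (channels x samples, float or
  int16 with an ``lsb_uV`` scale attribute) and attributes
  ``sampling_rate_hz`` and ``n_channels``.  Alternatively a flat
  little-endian binary file with a JSON sidecar (same keys plus ``dtype``)
  at ``<file>.json``.
* Spike table: CSV with header ``electrode_id,time_s``.
* Layout: CSV with header ``electrode_id,x_um,y_um[,z_um]`` (extra vendor
  label columns are carried but ignored by computation) or the JSON
  equivalent.
* Results: ``sttc_matrix.csv`` (square, header = electrode IDs),
  ``edges.csv``, ``nodes.csv``, ``summary.json``.  Reports contain no
  timestamps or hostnames, so identical inputs and seed reproduce them
  byte-for-byte.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import h5py
import numpy as np
import pandas as pd

from .config import RunConfig
from .containers import MEALayout, RawRecording, SpikeMatrix, SpikeTrain
from .errors import FormatError, ValidationError
from .network import ConnectivityGraph
from .sttc import STTCMatrix

__all__ = [
    "read_recording", "write_recording",
    "read_spike_table", "write_spike_table",
    "read_layout", "write_layout",
    "write_report",
]

_HDF5_SUFFIXES = {".h5", ".hdf5"}


def write_recording(recording: RawRecording, path: str | Path,
                    dtype: str = "float32", lsb_uV: float | None = None) -> Path:
    """Write a recording container (HDF5, or flat binary + JSON sidecar)."""
    path = Path(path)
    sig = recording.signal
    if dtype == "int16":
        scale = lsb_uV if lsb_uV is not None else max(
            np.abs(sig).max() / 32000.0, np.finfo(np.float64).tiny)
        data = np.round(sig / scale).astype(np.int16)
    else:
        scale = None
        data = sig.astype(dtype)
    if path.suffix.lower() in _HDF5_SUFFIXES:
        with h5py.File(path, "w") as f:
            d = f.create_dataset("signal", data=data)
            f.attrs["sampling_rate_hz"] = recording.sampling_rate_hz
            f.attrs["n_channels"] = recording.n_channels
            if scale is not None:
                d.attrs["lsb_uV"] = scale
    else:
        data.tofile(path)
        meta = {"sampling_rate_hz": recording.sampling_rate_hz,
                "n_channels": recording.n_channels,
                "dtype": str(data.dtype)}
        if scale is not None:
            meta["lsb_uV"] = scale
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))
    return path


def read_recording(path: str | Path) -> RawRecording:
    """Read a recording container; int16 data are rescaled by ``lsb_uV``."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such recording file: {path}")
    if path.suffix.lower() in _HDF5_SUFFIXES:
        with h5py.File(path, "r") as f:
            if "signal" not in f:
                raise FormatError(f"{path}: missing dataset 'signal'")
            d = f["signal"]
            if "sampling_rate_hz" not in f.attrs:
                raise FormatError(f"{path}: missing attribute 'sampling_rate_hz'")
            rate = float(f.attrs["sampling_rate_hz"])
            sig = d[()]
            if d.dtype == np.int16:
                if "lsb_uV" not in d.attrs:
                    raise FormatError(f"{path}: int16 signal without 'lsb_uV' scale")
                sig = sig.astype(np.float64) * float(d.attrs["lsb_uV"])
    else:
        sidecar = Path(str(path) + ".json")
        if not sidecar.exists():
            raise FormatError(f"{path}: flat binary recording needs sidecar {sidecar}")
        meta = json.loads(sidecar.read_text())
        for key in ("sampling_rate_hz", "n_channels", "dtype"):
            if key not in meta:
                raise FormatError(f"{sidecar}: missing key '{key}'")
        rate = float(meta["sampling_rate_hz"])
        flat = np.fromfile(path, dtype=np.dtype(meta["dtype"]))
        n_ch = int(meta["n_channels"])
        if n_ch <= 0 or flat.size % n_ch:
            raise FormatError(f"{path}: {flat.size} samples not divisible by "
                              f"{n_ch} channels (ragged channels?)")
        sig = flat.reshape(n_ch, -1)
        if "lsb_uV" in meta:
            sig = sig.astype(np.float64) * float(meta["lsb_uV"])
    if sig.ndim != 2:
        raise FormatError(f"{path}: signal must be channels x samples")
    try:
        return RawRecording(np.asarray(sig, dtype=np.float64), rate)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_spike_table(spike_matrix: SpikeMatrix, path: str | Path) -> Path:
    path = Path(path)
    rows = [(eid, t) for eid, tr in zip(spike_matrix.electrode_ids, spike_matrix)
            for t in tr.times]
    pd.DataFrame(rows, columns=["electrode_id", "time_s"]).to_csv(
        path, index=False, float_format="%.17g")
    return path


def read_spike_table(path: str | Path, duration_s: float,
                     layout: MEALayout | None = None) -> SpikeMatrix:
    """Read a ``electrode_id,time_s`` CSV into a spike matrix.

    Electrodes present in ``layout`` but absent from the table get empty
    trains; times are sorted per electrode.  Times outside ``[0,
    duration_s)`` raise :class:`ValidationError`; non-numeric rows raise
    :class:`FormatError`.
    """
    if not duration_s > 0:
        raise ValidationError("duration_s must be positive")
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"electrode_id": np.int64,
                                      "time_s": np.float64},
                         float_precision="round_trip")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if not {"electrode_id", "time_s"} <= set(df.columns):
        raise FormatError(f"{path}: header must contain electrode_id,time_s")
    if len(df) and (df["time_s"].min() < 0 or df["time_s"].max() >= duration_s):
        raise ValidationError(
            f"{path}: spike times outside the window [0, {duration_s})")
    grouped = {int(eid): np.sort(sub["time_s"].to_numpy())
               for eid, sub in df.groupby("electrode_id")}
    ids = sorted(grouped) if layout is None else list(layout.electrode_ids)
    trains = tuple(
        SpikeTrain(grouped.get(eid, np.empty(0)), duration_s) for eid in ids)
    if not trains:
        raise ValidationError(
            f"{path}: empty table and no layout to define electrodes")
    return SpikeMatrix(trains, tuple(ids))


def write_layout(layout: MEALayout, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {"diameter_um": layout.diameter_um,
                   "pitch_um": layout.pitch_um,
                   "electrodes": layout.to_frame().to_dict(orient="records")}
        path.write_text(json.dumps(payload, indent=1))
    else:
        layout.to_frame().to_csv(path, index=False)
    return path


def read_layout(path: str | Path, diameter_um: float = 12.0,
                pitch_um: float = 200.0) -> MEALayout:
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        df = pd.DataFrame(payload["electrodes"])
        diameter_um = float(payload.get("diameter_um", diameter_um))
        pitch_um = float(payload.get("pitch_um", pitch_um))
    else:
        try:
            df = pd.read_csv(path)
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}: {exc}") from exc
    if "electrode_id" not in df or "x_um" not in df or "y_um" not in df:
        raise FormatError(f"{path}: header must contain electrode_id,x_um,y_um")
    cols = ["x_um", "y_um"] + (["z_um"] if "z_um" in df else [])
    return MEALayout(tuple(int(i) for i in df["electrode_id"]),
                     df[cols].to_numpy(dtype=np.float64),
                     diameter_um=diameter_um, pitch_um=pitch_um)


def write_report(outdir: str | Path, *, sttc: STTCMatrix,
                 graph: ConnectivityGraph, config: RunConfig,
                 surrogate_comparison: dict[str, Any] | None = None,
                 extra_summary: dict[str, Any] | None = None) -> dict[str, Path]:
    """Emit the result files for one run.

    Writes ``sttc_matrix.csv``, ``edges.csv``, ``nodes.csv`` and
    ``summary.json`` (full config echo, global graph metrics, optional
    surrogate comparison).  Content is a pure function of the inputs — no
    timestamps — so reruns are byte-identical.
    """
    if sttc is None or graph is None:
        raise ValidationError("results must include the STTC matrix and graph")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    ids = [str(i) for i in sttc.electrode_ids]
    m = pd.DataFrame(sttc.values, index=ids, columns=ids)
    paths["sttc_matrix"] = outdir / "sttc_matrix.csv"
    m.to_csv(paths["sttc_matrix"], float_format="%.17g")

    paths["edges"] = outdir / "edges.csv"
    graph.edges_table().to_csv(paths["edges"], index=False, float_format="%.17g")

    paths["nodes"] = outdir / "nodes.csv"
    graph.nodes_table().to_csv(paths["nodes"], index=False, float_format="%.17g")

    nodes = graph.nodes_table()
    summary: dict[str, Any] = {
        "config": config.to_dict(),
        "n_electrodes": graph.n_nodes,
        "n_edges": graph.n_edges,
        "mean_degree": graph.mean_degree,
        "edge_density": graph.edge_density,
        "mean_firing_rate_hz": float(nodes["firing_rate_hz"].mean()),
        "total_spikes": int(nodes["n_spikes"].sum()),
        "duration_s": sttc.duration_s,
    }
    if surrogate_comparison is not None:
        summary["surrogate"] = surrogate_comparison
    if extra_summary:
        summary.update(extra_summary)
    paths["summary"] = outdir / "summary.json"
    paths["summary"].write_text(json.dumps(summary, indent=1, sort_keys=True))
    return paths
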