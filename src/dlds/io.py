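"""Reading and writing recordings, model artifacts, and connectivity exports.

Formats:

* recordings — HDF5, CSV/TSV matrix with a JSON label sidecar, or MAT
  archive deposits (wrapped behind the loader contract: ``traces``,
  ``trace_labels``, ``behavior``, ``stimulus``);
* model artifacts — HDF5 (datasets ``D``, ``operators``, ``x``, ``c``,
  ``fit_log``; hyperparameters as attributes) with a JSON metadata sidecar;
* connectivity maps — TSV edge lists and GraphML; reference connectomes are
  accepted as TSV edge lists or dense CSV adjacency.

All HDF5 writes disable object timestamps so identical runs produce
byte-stable artifacts.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .datatypes import (
    CoefficientTrajectory,
    ConnectivityMap,
    DLDSModel,
    Hyperparameters,
    LatentTrajectory,
    NeuralRecording,
)

__all__ = [
    "load_recording",
    "save_recording",
    "save_model",
    "load_model",
    "export_edge_list",
    "export_graphml",
    "load_reference_adjacency",
    "hash_artifact",
]


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------

def save_recording(recording: NeuralRecording, path: str | Path) -> Path:
    """Write a recording to HDF5, or to CSV/TSV + JSON sidecar by suffix."""
    path = Path(path)
    if path.suffix.lower() in {".csv", ".tsv", ".tab"}:
        sep = "\t" if path.suffix.lower() != ".csv" else ","
        pd.DataFrame(recording.traces).to_csv(path, sep=sep, header=False,
                                              index=False)
        meta = {
            "sampling_rate": recording.sampling_rate,
            "subject_id": recording.subject_id,
            "trace_labels": recording.trace_labels,
            "behavior": None if recording.behavior is None
            else np.asarray(recording.behavior).tolist(),
            "stimulus": None if recording.stimulus is None
            else np.asarray(recording.stimulus).tolist(),
            "stimulus_phase": None if recording.stimulus_phase is None
            else np.asarray(recording.stimulus_phase).tolist(),
            "behavior_names": None if recording.behavior_names is None
            else {str(k): v for k, v in recording.behavior_names.items()},
        }
        path.with_suffix(".json").write_text(json.dumps(meta))
        return path
    with h5py.File(path, "w") as f:
        f.create_dataset("traces", data=recording.traces, track_times=False)
        for name in ("behavior", "stimulus", "stimulus_phase"):
            vec = getattr(recording, name)
            if vec is not None:
                f.create_dataset(name, data=np.asarray(vec), track_times=False)
        f.attrs["sampling_rate"] = recording.sampling_rate
        f.attrs["subject_id"] = recording.subject_id
        if recording.trace_labels is not None:
            f.attrs["trace_labels"] = json.dumps(recording.trace_labels)
        if recording.behavior_names is not None:
            f.attrs["behavior_names"] = json.dumps(
                {str(k): v for k, v in recording.behavior_names.items()})
    return path


def _load_hdf5_recording(path: Path) -> NeuralRecording:
    with h5py.File(path, "r") as f:
        traces = f["traces"][()]
        kwargs = {}
        for name in ("behavior", "stimulus", "stimulus_phase"):
            if name in f:
                kwargs[name] = f[name][()]
        if "trace_labels" in f.attrs:
            kwargs["trace_labels"] = json.loads(f.attrs["trace_labels"])
        if "behavior_names" in f.attrs:
            kwargs["behavior_names"] = {
                int(k): v for k, v in json.loads(f.attrs["behavior_names"]).items()}
        return NeuralRecording(
            traces=traces,
            sampling_rate=float(f.attrs.get("sampling_rate", 1.0)),
            subject_id=str(f.attrs.get("subject_id", "")),
            **kwargs,
        )


def _load_csv_recording(path: Path) -> NeuralRecording:
    """CSV/TSV matrix (rows = traces) with optional JSON sidecar ``<stem>.json``."""
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    traces = pd.read_csv(path, sep=sep, header=None).to_numpy(dtype=float)
    sidecar = path.with_suffix(".json")
    kwargs: dict = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        for key in ("trace_labels", "behavior", "stimulus", "stimulus_phase"):
            if meta.get(key) is not None:
                kwargs[key] = meta[key]
        if meta.get("behavior_names"):
            kwargs["behavior_names"] = {int(k): v
                                        for k, v in meta["behavior_names"].items()}
        kwargs["sampling_rate"] = float(meta.get("sampling_rate", 1.0))
        kwargs["subject_id"] = str(meta.get("subject_id", ""))
    rec = NeuralRecording(traces=traces, **kwargs)
    if rec.trace_labels is not None and len(rec.trace_labels) != rec.n_traces:
        raise ValueError(
            f"label sidecar lists {len(rec.trace_labels)} traces, file has "
            f"{rec.n_traces}")
    return rec


def _load_mat_recording(path: Path) -> NeuralRecording:
    """MAT archive layout, read by contract (field names, not structure)."""
    from scipy.io import loadmat

    raw = loadmat(path, squeeze_me=True, simplify_cells=True)
    if "traces" not in raw:
        raise ValueError(f"MAT file {path} lacks a 'traces' variable")
    traces = np.asarray(raw["traces"], dtype=float)
    kwargs: dict = {}
    if "trace_labels" in raw:
        labels = raw["trace_labels"]
        kwargs["trace_labels"] = [
            [str(n) for n in (entry if isinstance(entry, (list, np.ndarray)) else [entry])
             if str(n)]
            for entry in labels
        ]
    for key in ("behavior", "stimulus", "stimulus_phase"):
        if key in raw:
            kwargs[key] = np.asarray(raw[key]).ravel()
    if "sampling_rate" in raw:
        kwargs["sampling_rate"] = float(raw["sampling_rate"])
    if "subject_id" in raw:
        kwargs["subject_id"] = str(raw["subject_id"])
    return NeuralRecording(traces=traces, **kwargs)


def load_recording(path: str | Path, format: str | None = None) -> NeuralRecording:
    """Load a recording from HDF5, CSV/TSV (+ JSON sidecar), or MAT.

    ``format`` is inferred from the suffix when not given.  Shape
    inconsistencies between traces and sidecar labels are hard errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {".h5": "hdf5", ".hdf5": "hdf5", ".csv": "csv", ".tsv": "csv",
                  ".tab": "csv", ".mat": "mat"}.get(suffix)
        if format is None:
            raise ValueError(f"cannot infer format from suffix {suffix!r}")
    if format == "hdf5":
        return _load_hdf5_recording(path)
    if format == "csv":
        return _load_csv_recording(path)
    if format == "mat":
        return _load_mat_recording(path)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# model artifacts
# ---------------------------------------------------------------------------

def save_model(model: DLDSModel, path: str | Path,
               latents: LatentTrajectory | None = None,
               coefficients: CoefficientTrajectory | None = None,
               metadata: dict | None = None) -> Path:
    """Serialize a fitted model (and optional trajectories) to HDF5 + JSON sidecar."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("D", data=model.D, track_times=False)
        f.create_dataset("operators", data=model.operators, track_times=False)
        if latents is not None:
            f.create_dataset("x", data=latents.x, track_times=False)
            if latents.objective is not None:
                f.create_dataset("objective", data=latents.objective,
                                 track_times=False)
        if coefficients is not None:
            f.create_dataset("c", data=coefficients.c, track_times=False)
        if model.fit_log is not None and len(model.fit_log):
            grp = f.create_group("fit_log")
            for col in model.fit_log.columns:
                grp.create_dataset(col, data=model.fit_log[col].to_numpy(),
                                   track_times=False)
        for key, val in model.hyper.to_dict().items():
            f.attrs[f"hyper_{key}"] = val
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = {"hyperparameters": model.hyper.to_dict(),
            "n_traces": model.n_traces, "p": model.p, "M": model.M}
    if metadata:
        meta.update(metadata)
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def load_model(path: str | Path
               ) -> tuple[DLDSModel, LatentTrajectory | None, CoefficientTrajectory | None]:
    """Load a model artifact written by :func:`save_model`."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        hyper_kwargs = {k[len("hyper_"):]: v for k, v in f.attrs.items()
                        if k.startswith("hyper_")}
        for key in ("p", "M", "max_iter", "seed", "inner_max_iter",
                    "n_operator_steps"):
            if key in hyper_kwargs:
                hyper_kwargs[key] = int(hyper_kwargs[key])
        for key in ("projection_spec",):
            if key in hyper_kwargs:
                hyper_kwargs[key] = str(hyper_kwargs[key])
        hyper = Hyperparameters(**hyper_kwargs)
        fit_log = None
        if "fit_log" in f:
            fit_log = pd.DataFrame({col: f["fit_log"][col][()]
                                    for col in f["fit_log"]})
        model = DLDSModel(D=f["D"][()], operators=f["operators"][()],
                          hyper=hyper, fit_log=fit_log)
        latents = None
        if "x" in f:
            latents = LatentTrajectory(
                x=f["x"][()],
                objective=f["objective"][()] if "objective" in f else None)
        coefficients = None
        if "c" in f:
            coefficients = CoefficientTrajectory(
                c=f["c"][()], activity_threshold=hyper.activity_threshold)
    return model, latents, coefficients


def hash_artifact(path: str | Path) -> str:
    """Content hash of an HDF5 artifact (datasets + attrs, layout-independent)."""
    import hashlib

    digest = hashlib.sha256()

    def visit(name, obj):
        digest.update(name.encode())
        if isinstance(obj, h5py.Dataset):
            digest.update(np.ascontiguousarray(obj[()]).tobytes())
        for k in sorted(obj.attrs):
            digest.update(k.encode())
            digest.update(str(obj.attrs[k]).encode())

    with h5py.File(path, "r") as f:
        for k in sorted(f.attrs):
            digest.update(k.encode())
            digest.update(str(f.attrs[k]).encode())
        f.visititems(visit)
    return digest.hexdigest()


# ---------------------------------------------------------------------------
# connectivity exports and references
# ---------------------------------------------------------------------------

def _node_name(i: int, trace_labels: list[list[str]] | None) -> str:
    if trace_labels and trace_labels[i]:
        return "+".join(trace_labels[i])
    return f"trace_{i}"


def export_edge_list(cmap: ConnectivityMap, path: str | Path) -> Path:
    """Write nonzero map entries as a TSV edge list (source, target, weight)."""
    path = Path(path)
    rows, cols = np.nonzero(cmap.weights)
    df = pd.DataFrame({
        "source": [_node_name(i, cmap.trace_labels) for i in rows],
        "target": [_node_name(j, cmap.trace_labels) for j in cols],
        "weight": cmap.weights[rows, cols],
    })
    df.to_csv(path, sep="\t", index=False)
    return path


def export_graphml(cmap: ConnectivityMap, path: str | Path) -> Path:
    """Write the map as GraphML (directed, weighted) for circular-graph tools."""
    import networkx as nx

    G = nx.DiGraph()
    n = cmap.n_traces
    for i in range(n):
        attrs = {}
        if cmap.node_activity is not None:
            attrs["activity"] = float(cmap.node_activity[i])
        G.add_node(_node_name(i, cmap.trace_labels), **attrs)
    rows, cols = np.nonzero(cmap.weights)
    for i, j in zip(rows, cols):
        G.add_edge(_node_name(int(i), cmap.trace_labels),
                   _node_name(int(j), cmap.trace_labels),
                   weight=float(cmap.weights[i, j]))
    path = Path(path)
    nx.write_graphml(G, path)
    return path


def load_reference_adjacency(path: str | Path, n_traces: int | None = None,
                             trace_labels: list[list[str]] | None = None,
                             ) -> np.ndarray:
    """Load a reference connectome as a binary adjacency matrix.

    Dense CSV adjacency (square numeric matrix) or TSV edge list with
    ``source``/``target`` columns; edge-list node names are resolved against
    ``trace_labels``.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        adj = pd.read_csv(path, header=None).to_numpy(dtype=float)
        if adj.shape[0] != adj.shape[1]:
            raise ValueError("dense reference adjacency must be square")
        return (adj != 0).astype(float)
    df = pd.read_csv(path, sep="\t")
    if not {"source", "target"} <= set(df.columns):
        raise ValueError("edge-list reference needs 'source' and 'target' columns")
    if n_traces is None or trace_labels is None:
        raise ValueError("edge-list references need n_traces and trace_labels")
    name_to_idx: dict[str, list[int]] = {}
    for i, names in enumerate(trace_labels):
        for nm in names:
            name_to_idx.setdefault(nm, []).append(i)
    adj = np.zeros((n_traces, n_traces))
    for _, row in df.iterrows():
        for i in name_to_idx.get(str(row["source"]), []):
            for j in name_to_idx.get(str(row["target"]), []):
                adj[i, j] = 1.0
    return adj
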