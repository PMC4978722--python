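"""Reading and writing recordings, feature matrices and models.

Recordings go to HDF5 (``/lfp`` float32 channels x samples, ``/fs``, a
``/site_map`` table and a ``/schedule`` table) with a JSON sidecar holding
the simulation metadata and seed. Feature matrices and characterization
tables go to CSV; fitted decoders to JSON.
"""
from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .signal_features import FeatureMatrix
from .slr import SparseLogisticRegression
from .synthetic_data import LfpRecording, SiteMap, StimulusSchedule


def _write_table(group: h5py.Group, name: str, df: pd.DataFrame) -> None:
    sub = group.create_group(name)
    for col in df.columns:
        values = df[col].to_numpy()
        if values.dtype == object:
            sub.create_dataset(col, data=np.asarray(values, dtype=h5py.string_dtype()))
        else:
            sub.create_dataset(col, data=values)
    sub.attrs["columns"] = list(df.columns)


def _read_table(group: h5py.Group, name: str) -> pd.DataFrame:
    sub = group[name]
    data = {}
    for col in sub.attrs["columns"]:
        values = sub[col][()]
        if values.dtype.kind in ("S", "O"):
            values = np.array([v.decode() if isinstance(v, bytes) else v for v in values])
        data[col] = values
    return pd.DataFrame(data)


def save_recording(recording: LfpRecording, path: str | Path) -> None:
    """Write a recording to HDF5 plus a JSON metadata sidecar."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("lfp", data=recording.data.astype(np.float32))
        f.create_dataset("fs", data=float(recording.fs_hz))
        _write_table(f, "site_map", recording.site_map.table)
        _write_table(f, "schedule", recording.schedule.events)
        f.attrs["protocol"] = recording.schedule.protocol
        f.attrs["total_duration_s"] = recording.schedule.total_duration_s
        f.attrs["grid_shape"] = recording.site_map.grid_shape
        f.attrs["pitch_um"] = recording.site_map.pitch_um
    sidecar = {"meta": recording.meta, "burst_log": recording.burst_log}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def load_recording(path: str | Path) -> LfpRecording:
    path = Path(path)
    with h5py.File(path, "r") as f:
        data = f["lfp"][()]
        fs = float(f["fs"][()])
        site_map = SiteMap(
            table=_read_table(f, "site_map"),
            grid_shape=tuple(int(v) for v in f.attrs["grid_shape"]),
            pitch_um=float(f.attrs["pitch_um"]),
        )
        schedule = StimulusSchedule(
            events=_read_table(f, "schedule"),
            protocol=str(f.attrs["protocol"]),
            total_duration_s=float(f.attrs["total_duration_s"]),
        )
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta, burst_log = {}, []
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        meta = sidecar.get("meta", {})
        burst_log = sidecar.get("burst_log", [])
    return LfpRecording(
        data=data, fs_hz=fs, site_map=site_map, schedule=schedule,
        burst_log=burst_log, meta=meta,
    )


def save_feature_matrix(fm: FeatureMatrix, path: str | Path) -> None:
    """Feature matrix as CSV with a JSON descriptor sidecar."""
    path = Path(path)
    df = pd.DataFrame(fm.values)
    df.insert(0, "label", fm.labels)
    df.to_csv(path, index=False)
    desc = {
        "kind": fm.kind,
        "band": fm.band,
        "window_ms": fm.window_ms,
        "descriptors": [list(d) if isinstance(d, tuple) else d for d in fm.descriptors],
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(desc))


def save_model(model: SparseLogisticRegression, path: str | Path) -> None:
    """Serialize a fitted decoder (weights, precisions, mask, settings) as JSON."""
    payload = {
        "params": model.get_params(),
        "classes": np.asarray(model.classes_).tolist(),
        "coef": model.coef_.tolist(),
        "intercept": model.intercept_.tolist(),
        "alpha": np.where(np.isfinite(model.alpha_), model.alpha_, -1.0).tolist(),
        "active_mask": model.active_mask_.astype(int).tolist(),
        "n_iter": int(model.n_iter_),
        "converged": bool(model.converged_),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> SparseLogisticRegression:
    payload = json.loads(Path(path).read_text())
    model = SparseLogisticRegression(**payload["params"])
    model.classes_ = np.asarray(payload["classes"])
    model.coef_ = np.asarray(payload["coef"], dtype=float)
    model.intercept_ = np.asarray(payload["intercept"], dtype=float)
    alpha = np.asarray(payload["alpha"], dtype=float)
    model.alpha_ = np.where(alpha < 0, np.inf, alpha)
    model.active_mask_ = np.asarray(payload["active_mask"], dtype=bool)
    model.n_iter_ = payload["n_iter"]
    model.converged_ = payload["converged"]
    return model
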