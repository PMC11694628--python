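"""File formats: telemetry/label/feature CSVs, segment store, checkpoints.

Telemetry CSV schema (UTF-8, header required):
``driver_id,trip_id,timestamp,lat,lon,sog_kph`` with ``sog_kph`` optional or
blank. The feature CSV appends ``step_distance_km,speed_kph,azimuth_deg,
azimuth_x,azimuth_y``. The segment store is one CSV per dataset with
``driver_id,trip_id,start_index,label,grid_json`` where ``grid_json`` is the
row-major G x G binary occupancy matrix (row 0 = southernmost).

Model checkpoints are a ``.npz`` of the weight arrays plus a JSON sidecar
recording the model kind, architecture specs, seed/training config; the
pair round-trips through :func:`load_checkpoint`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import SegmentDataset
from .gridding import rasterize_occupancy
from . import models

TELEMETRY_COLUMNS = ["driver_id", "trip_id", "timestamp", "lat", "lon", "sog_kph"]
FEATURE_COLUMNS = TELEMETRY_COLUMNS + [
    "step_distance_km",
    "speed_kph",
    "azimuth_deg",
    "azimuth_x",
    "azimuth_y",
]

__all__ = [
    "TELEMETRY_COLUMNS",
    "FEATURE_COLUMNS",
    "read_telemetry",
    "write_telemetry",
    "read_labels",
    "write_labels",
    "write_features",
    "write_segment_store",
    "read_segment_store",
    "save_checkpoint",
    "load_checkpoint",
]


def read_telemetry(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = [c for c in TELEMETRY_COLUMNS if c != "sog_kph"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"telemetry CSV missing columns: {missing}")
    if "sog_kph" in df.columns:
        df["sog_kph"] = pd.to_numeric(df["sog_kph"], errors="coerce")
    return df


def write_telemetry(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in TELEMETRY_COLUMNS if c in df.columns]
    df[cols].to_csv(path, index=False)


def read_labels(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"driver_id", "label"} <= set(df.columns):
        raise ValueError("labels CSV needs columns driver_id,label")
    if not df["label"].isin([0, 1]).all():
        raise ValueError("labels must be 0 (normal) or 1 (abnormal)")
    return df


def write_labels(df: pd.DataFrame, path: str | Path) -> None:
    df[["driver_id", "label"]].to_csv(path, index=False)


def write_features(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in FEATURE_COLUMNS if c in df.columns]
    df[cols].to_csv(path, index=False)


def write_segment_store(ds: SegmentDataset, path: str | Path) -> None:
    rows = []
    for i, seq in enumerate(ds.sequences):
        grid = rasterize_occupancy(seq, ds.extent_g).matrix
        rows.append(
            {
                "driver_id": ds.driver_ids[i],
                "trip_id": "" if ds.trip_ids is None else ds.trip_ids[i],
                "start_index": -1 if ds.start_indices is None else ds.start_indices[i],
                "label": int(ds.y[i]),
                "grid_json": json.dumps(grid.tolist()),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_segment_store(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["grid"] = df["grid_json"].map(lambda s: np.asarray(json.loads(s), dtype=np.uint8))
    return df


def _spec_to_json(spec) -> dict:
    from dataclasses import asdict

    return asdict(spec)


def save_checkpoint(model, path: str | Path, extra: dict | None = None) -> None:
    """Write model weights (.npz) plus a JSON sidecar describing the model."""
    path = Path(path)
    weights = [p for p, _ in model.parameters()]
    np.savez(path.with_suffix(".npz"), *weights)
    meta: dict = {"kind": model.kind, "fitted": bool(getattr(model, "fitted", False))}
    if model.kind == "combined":
        meta["naive_spec"] = _spec_to_json(model.naive.spec)
        meta["grid_spec"] = _spec_to_json(model.grid.spec)
        meta["combined_spec"] = _spec_to_json(model.spec)
    else:
        meta[f"{model.kind}_spec"] = _spec_to_json(model.spec)
    if getattr(model, "training_config", None):
        meta["training_config"] = model.training_config
    scaler = getattr(model, "naive_scaler", None)
    if scaler is not None:
        meta["naive_scaler"] = {"mean": scaler[0].tolist(), "std": scaler[1].tolist()}
    if extra:
        meta["extra"] = extra
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path: str | Path):
    """Rebuild a model from a checkpoint written by :func:`save_checkpoint`."""
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    kind = meta["kind"]
    kwargs: dict = {}
    if "naive_spec" in meta:
        s = dict(meta["naive_spec"])
        s["hidden_dims"] = tuple(s["hidden_dims"])
        kwargs["naive_spec"] = models.NaiveStreamSpec(**s)
    if "grid_spec" in meta:
        s = dict(meta["grid_spec"])
        s["fc_dims"] = tuple(s["fc_dims"])
        kwargs["grid_spec"] = models.GridStreamSpec(**s)
    if "combined_spec" in meta:
        s = dict(meta["combined_spec"])
        s["fc_dims"] = tuple(s["fc_dims"])
        kwargs["combined_spec"] = models.CombinedSpec(**s)
    model = models.build_model(kind, seed=0, **kwargs)
    with np.load(path.with_suffix(".npz")) as data:
        arrays = [data[f"arr_{i}"] for i in range(len(data.files))]
    params = model.parameters()
    if len(arrays) != len(params):
        raise ValueError("checkpoint does not match the rebuilt architecture")
    for (p, _), a in zip(params, arrays):
        if p.shape != a.shape:
            raise ValueError(f"weight shape mismatch: {p.shape} vs {a.shape}")
        p[...] = a
    model.fitted = meta.get("fitted", False)
    if "training_config" in meta:
        model.training_config = meta["training_config"]
    if "naive_scaler" in meta:
        model.naive_scaler = (
            np.asarray(meta["naive_scaler"]["mean"]),
            np.asarray(meta["naive_scaler"]["std"]),
        )
    return model
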