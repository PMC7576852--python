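"""Delimited-text input/output.

Every artifact is plain text: recordings are CSV files with a small
``# key=value`` metadata header (sampling rate, type, provenance hash);
cycle sets and statistical tables are long-format CSV; the synthetic
ground truth travels in a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .datatypes import CycleSet, EmgRecording, MarkerRecording
from .synth import SynthTruth

__all__ = [
    "write_emg",
    "read_emg",
    "write_markers",
    "read_markers",
    "write_cycle_set",
    "read_cycle_set",
    "write_truth",
    "read_truth",
    "write_table",
    "read_table",
]


def _write_csv_with_meta(path: Path, df: pd.DataFrame, meta: dict[str, Any]) -> None:
    with open(path, "w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, index=False)


def _read_meta(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
    return meta


def write_emg(path: str | Path, rec: EmgRecording, **meta: Any) -> None:
    df = pd.DataFrame(rec.samples, columns=rec.labels)
    _write_csv_with_meta(Path(path), df, {"type": "emg", "fs_hz": rec.fs, **meta})


def read_emg(path: str | Path) -> EmgRecording:
    path = Path(path)
    meta = _read_meta(path)
    if "fs_hz" not in meta:
        raise ValueError(f"{path}: missing 'fs_hz' metadata header")
    df = pd.read_csv(path, comment="#")
    return EmgRecording(df.to_numpy(dtype=float), float(meta["fs_hz"]), list(df.columns))


def write_markers(path: str | Path, rec: MarkerRecording, **meta: Any) -> None:
    cols = {}
    for i, lab in enumerate(rec.labels):
        for j, axis in enumerate("XYZ"):
            cols[f"{lab}_{axis}"] = rec.positions[:, i, j]
    _write_csv_with_meta(
        Path(path), pd.DataFrame(cols), {"type": "markers", "fs_hz": rec.fs, **meta}
    )


def read_markers(path: str | Path) -> MarkerRecording:
    path = Path(path)
    meta = _read_meta(path)
    if "fs_hz" not in meta:
        raise ValueError(f"{path}: missing 'fs_hz' metadata header")
    df = pd.read_csv(path, comment="#")
    labels = []
    for col in df.columns:
        base = col.rsplit("_", 1)[0]
        if base not in labels:
            labels.append(base)
    pos = np.stack(
        [df[[f"{lab}_{ax}" for ax in "XYZ"]].to_numpy(dtype=float) for lab in labels],
        axis=1,
    )
    return MarkerRecording(pos, float(meta["fs_hz"]), labels)


def write_cycle_set(path: str | Path, cs: CycleSet, **meta: Any) -> None:
    ch, reps, pts = cs.curves.shape
    rep_idx, pt_idx = np.meshgrid(np.arange(reps), np.arange(pts), indexing="ij")
    frames = []
    for c, lab in enumerate(cs.labels):
        frames.append(
            pd.DataFrame(
                {
                    "rep": rep_idx.ravel() + 1,
                    "cycle_point": pt_idx.ravel() + 1,
                    "channel": lab,
                    "value": cs.curves[c].ravel(),
                }
            )
        )
    _write_csv_with_meta(
        Path(path),
        pd.concat(frames, ignore_index=True),
        {"type": "cycles", "phase": cs.phase, "n_points": cs.n_points, **meta},
    )


def read_cycle_set(path: str | Path) -> CycleSet:
    path = Path(path)
    meta = _read_meta(path)
    df = pd.read_csv(path, comment="#")
    labels = list(dict.fromkeys(df["channel"]))
    n_points = int(meta.get("n_points", df["cycle_point"].max()))
    n_reps = int(df["rep"].max())
    curves = np.empty((len(labels), n_reps, n_points))
    for c, lab in enumerate(labels):
        sub = df[df["channel"] == lab].sort_values(["rep", "cycle_point"])
        curves[c] = sub["value"].to_numpy().reshape(n_reps, n_points)
    return CycleSet(curves, labels, meta.get("phase", "lift"), n_points)


def _to_jsonable(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (tuple, list)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_truth(path: str | Path, truth: SynthTruth) -> None:
    payload = {
        "W_true": truth.W_true,
        "H_templates": truth.H_templates,
        "J_true": truth.J_true,
        "C_true": truth.C_true,
        "gev_true": truth.gev_true,
        "ngev_true": truth.ngev_true,
        "ima_true": truth.ima_true,
        "cycle_bounds": truth.cycle_bounds,
        "clip_fraction": truth.clip_fraction,
    }
    Path(path).write_text(json.dumps(_to_jsonable(payload), indent=1))


def read_truth(path: str | Path) -> dict[str, Any]:
    raw = json.loads(Path(path).read_text())
    for key in ("W_true", "C_true"):
        raw[key] = np.asarray(raw[key])
    raw["H_templates"] = {k: np.asarray(v) for k, v in raw["H_templates"].items()}
    raw["J_true"] = {k: np.asarray(v) for k, v in raw["J_true"].items()}
    raw["cycle_bounds"] = {
        k: (np.asarray(v[0]), np.asarray(v[1])) for k, v in raw["cycle_bounds"].items()
    }
    return raw


def write_table(path: str | Path, df: pd.DataFrame, **meta: Any) -> None:
    _write_csv_with_meta(Path(path), df, meta)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), comment="#")
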