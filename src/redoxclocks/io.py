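"""Delimited-text input/output and run manifests.

Trajectory tables are tab-separated with a ``time_h`` first column and one
column per state variable; every run writes a JSON sidecar manifest holding
the full parameter set, seed and solver so any table can be regenerated.
"""

from __future__ import annotations

import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "write_series",
    "read_series",
    "write_manifest",
    "write_ensemble_trajectory",
    "write_goodwin_trajectory",
]

SEP = "\t"


def _pkg_version() -> str:
    try:
        return version("redoxclocks")
    except PackageNotFoundError:
        return "unknown"


def write_series(path, times, **columns) -> Path:
    """Write a time-series table: time_h plus one column per keyword."""
    path = Path(path)
    df = pd.DataFrame({"time_h": np.asarray(times)})
    for name, col in columns.items():
        df[name] = np.asarray(col)
    df.to_csv(path, sep=SEP, index=False)
    return path


def read_series(path) -> pd.DataFrame:
    """Read a delimited time-series table (tab, comma or whitespace)."""
    return pd.read_csv(path, sep=None, engine="python")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(v) for k, v in obj.__dict__.items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_manifest(path, meta: dict) -> Path:
    path = Path(path)
    payload = {"package_version": _pkg_version(), **_jsonable(meta)}
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path


def write_ensemble_trajectory(out_dir, traj, stem: str = "ensemble") -> dict[str, Path]:
    """Write x table (+ mean_field), y table, tau sidecar and manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n = traj.n_oscillators
    xcols = {f"x{i}": traj.x[i] for i in range(n)}
    xcols["mean_field"] = traj.mean_field
    ycols = {f"y{i}": traj.y[i] for i in range(n)}
    paths = {
        "x": write_series(out_dir / f"{stem}_x.tsv", traj.times, **xcols),
        "y": write_series(out_dir / f"{stem}_y.tsv", traj.times, **ycols),
    }
    tau = pd.DataFrame({"oscillator": np.arange(n), "tau_h": traj.tau})
    tau_path = out_dir / f"{stem}_tau.tsv"
    tau.to_csv(tau_path, sep=SEP, index=False)
    paths["tau"] = tau_path
    paths["manifest"] = write_manifest(out_dir / f"{stem}_manifest.json", traj.meta)
    return paths


def write_goodwin_trajectory(out_dir, traj, stem: str = "goodwin") -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "table": write_series(
            out_dir / f"{stem}.tsv",
            traj.times,
            CB=traj.cb,
            PCc=traj.pcc,
            PCn=traj.pcn,
            drive=traj.drive,
        )
    }
    meta = dict(traj.meta)
    meta.update({"period_h": traj.period, "cb_mean": traj.cb_mean})
    paths["manifest"] = write_manifest(out_dir / f"{stem}_manifest.json", meta)
    return paths
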