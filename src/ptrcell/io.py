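"""Artifact input/output: trajectory CSV files, JSON reports, configs.

CSV dialect: comma-separated, '.' decimal, header row, UTF-8, no index
column, floats at 17 significant digits (lossless for doubles).  Every
trajectory CSV gets a JSON sidecar with the parameters and integrator
settings so a run can be reproduced from its artifacts alone.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .parameters import PTRParameters, QSectorParameters
from .model import Trajectory

FLOAT_FORMAT = "%.17g"

PARAM_FIELDS = [f.name for f in dataclasses.fields(PTRParameters)]
QSECTOR_FIELDS = [f.name for f in dataclasses.fields(QSectorParameters)]


def params_to_dict(params: PTRParameters) -> dict:
    return dataclasses.asdict(params)


def params_from_dict(data: dict) -> PTRParameters:
    """Rebuild parameters from a mapping; Q-sector keys select the extended
    type.  Unknown keys are rejected."""
    keys = set(data)
    if keys - set(QSECTOR_FIELDS):
        raise ValueError(f"unknown parameter keys: {sorted(keys - set(QSECTOR_FIELDS))}")
    if keys - set(PARAM_FIELDS):
        return QSectorParameters(**data)
    return PTRParameters(**data)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float) and not math.isfinite(obj):
        return repr(obj)  # "inf" / "-inf" / "nan" as strings
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def write_json(obj, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.write_text(json.dumps(_jsonable(obj), indent=2) + "\n")
    return path


def read_json(path: Union[str, Path]) -> dict:
    return json.loads(Path(path).read_text())


def write_trajectory(traj: Trajectory, csv_path: Union[str, Path]) -> tuple:
    """Write a trajectory as tidy CSV (t, P, T, R[, Q], V) + JSON sidecar."""
    csv_path = Path(csv_path)
    traj.as_frame().to_csv(csv_path, index=False, float_format=FLOAT_FORMAT)
    sidecar = csv_path.with_suffix(".meta.json")
    write_json({"parameters": params_to_dict(traj.params),
                "integrator": traj.meta}, sidecar)
    return csv_path, sidecar


def read_trajectory(csv_path: Union[str, Path]) -> Trajectory:
    """Reload a trajectory written by :func:`write_trajectory`."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path, float_precision="round_trip")
    meta = read_json(csv_path.with_suffix(".meta.json"))
    params = params_from_dict(meta["parameters"])
    return Trajectory(t=df["t"].to_numpy(), P=df["P"].to_numpy(),
                      T=df["T"].to_numpy(), R=df["R"].to_numpy(),
                      Q=df["Q"].to_numpy() if "Q" in df else None,
                      params=params, meta=meta.get("integrator", {}))


def write_table(df: pd.DataFrame, path: Union[str, Path]) -> Path:
    path = Path(path)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def load_config(path: Union[str, Path]) -> dict:
    """Load a YAML or JSON run configuration into a flat dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in {".yaml", ".yml"}:
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping")
    return data
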