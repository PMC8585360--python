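"""File formats: coefficient configs, trace CSVs, trial manifests, summaries.

All files are plain text.  A trace CSV holds one trial's 1 kHz force channels
(columns ``time_s, fz_n, fp_n``); trial metadata lives in a manifest CSV
(columns ``trial_id, h_mm, theta_deg, speed_mm_min, replicate``); calibrated
coefficients round-trip through a flat YAML/JSON mapping at full float
precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import AnisotropyModel, NormalForceModel

TRACE_COLUMNS = ["time_s", "fz_n", "fp_n"]
MANIFEST_COLUMNS = ["trial_id", "h_mm", "theta_deg", "speed_mm_min", "replicate"]
SUMMARY_COLUMNS = [
    "trial_id",
    "h_mm",
    "theta_deg",
    "replicate",
    "fz_mean_n",
    "fp_mean_n",
    "fz_sd_n",
    "fp_sd_n",
    "fp_observed",
    "n_used",
]

_COEF_KEYS = ("C", "alpha", "fp0", "C1", "C2", "C3", "theta0_deg", "convention")


def coefficients_to_dict(
    nmodel: NormalForceModel, amodel: AnisotropyModel
) -> dict:
    """Flat key-value mapping of all calibrated coefficients."""
    return {
        "C": float(nmodel.C),
        "alpha": float(nmodel.alpha),
        "fp0": float(amodel.fp0),
        "C1": float(amodel.C1),
        "C2": float(amodel.C2),
        "C3": float(amodel.C3),
        "theta0_deg": float(amodel.theta0),
        "convention": amodel.convention,
    }


def coefficients_from_dict(d: dict) -> tuple[NormalForceModel, AnisotropyModel]:
    unknown = set(d) - set(_COEF_KEYS)
    if unknown:
        raise ValueError(f"unknown coefficient keys: {sorted(unknown)}")
    missing = set(_COEF_KEYS) - set(d)
    if missing:
        raise ValueError(f"missing coefficient keys: {sorted(missing)}")
    nmodel = NormalForceModel(C=float(d["C"]), alpha=float(d["alpha"]))
    amodel = AnisotropyModel(
        fp0=float(d["fp0"]),
        C1=float(d["C1"]),
        C2=float(d["C2"]),
        C3=float(d["C3"]),
        theta0=float(d["theta0_deg"]),
        convention=str(d["convention"]),
    )
    return nmodel, amodel


def save_coefficients(
    nmodel: NormalForceModel, amodel: AnisotropyModel, path: str | Path
) -> None:
    """Write coefficients as YAML (.yaml/.yml) or JSON (.json), losslessly."""
    path = Path(path)
    d = coefficients_to_dict(nmodel, amodel)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def load_coefficients(path: str | Path) -> tuple[NormalForceModel, AnisotropyModel]:
    path = Path(path)
    text = path.read_text()
    d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return coefficients_from_dict(d)


def write_trace_csv(
    path: str | Path, time: np.ndarray, fz: np.ndarray, fp: np.ndarray
) -> None:
    df = pd.DataFrame({"time_s": time, "fz_n": fz, "fp_n": fp})
    df.to_csv(path, index=False)


def read_trace_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV {path} missing columns: {sorted(missing)}")
    return df[TRACE_COLUMNS]


def write_manifest_csv(path: str | Path, manifest: pd.DataFrame) -> None:
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    manifest.to_csv(path, index=False)


def read_manifest_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest CSV {path} missing columns: {sorted(missing)}")
    return df


def write_summary_csv(path: str | Path, summaries: pd.DataFrame) -> None:
    summaries.to_csv(path, index=False)


def read_summary_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(SUMMARY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"summary CSV {path} missing columns: {sorted(missing)}")
    return df
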