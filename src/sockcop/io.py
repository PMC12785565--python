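"""Delimited-text I/O for recordings, ground truth, manifests and metrics.

File schemas (CSV, UTF-8, '.' decimal separator, header required):

* sock recording:  ``t,u0,u1,u2,u3,u4,u5`` — time in seconds, six
  conductance channels;
* CoP series:      ``t,x,y,valid``        — mm, ``valid`` in {0, 1}.

A study directory written by :func:`write_study` contains per trial
``<trial_id>_sock.csv``, ``<trial_id>_platform.csv``,
``<trial_id>_truth.csv`` and one ``manifest.json`` with the design, seed
and all drawn parameters.  Metrics go to a TSV with one row per
(participant, exercise, repetition, foot, axis).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import ConductanceSeries, CoPSeries

__all__ = [
    "read_conductance_csv",
    "write_conductance_csv",
    "read_cop_csv",
    "write_cop_csv",
    "write_study",
    "read_manifest",
    "write_metrics_tsv",
    "read_metrics_tsv",
]

CONDUCTANCE_COLUMNS = ["t", "u0", "u1", "u2", "u3", "u4", "u5"]
COP_COLUMNS = ["t", "x", "y", "valid"]


def _read_csv_checked(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except ValueError as exc:
        raise ValueError(f"{path}: malformed CSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    for col in required:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            # +2: one for the header row, one for 1-based line numbers
            raise ValueError(
                f"{path}: non-numeric value in column {col!r} at line {bad[0] + 2}"
            )
    t = df["t"].to_numpy(float)
    if t.size > 1:
        nonmono = np.flatnonzero(np.diff(t) <= 0)
        if nonmono.size:
            raise ValueError(
                f"{path}: timestamps not strictly increasing at line {nonmono[0] + 3}"
            )
    return df


def read_conductance_csv(path: str | Path, **meta) -> ConductanceSeries:
    df = _read_csv_checked(path, CONDUCTANCE_COLUMNS)
    return ConductanceSeries(
        t=df["t"].to_numpy(float),
        values=df[CONDUCTANCE_COLUMNS[1:]].to_numpy(float),
        **meta,
    )


def write_conductance_csv(path: str | Path, series: ConductanceSeries) -> None:
    df = pd.DataFrame(series.values, columns=CONDUCTANCE_COLUMNS[1:])
    df.insert(0, "t", series.t)
    df.to_csv(path, index=False, float_format="%.9g")


def read_cop_csv(path: str | Path, source: str = "sock", **meta) -> CoPSeries:
    df = _read_csv_checked(path, COP_COLUMNS)
    return CoPSeries(
        t=df["t"].to_numpy(float),
        x=df["x"].to_numpy(float),
        y=df["y"].to_numpy(float),
        valid=df["valid"].to_numpy(float) > 0.5,
        source=source,
        **meta,
    )


def write_cop_csv(path: str | Path, series: CoPSeries) -> None:
    df = pd.DataFrame(
        {
            "t": series.t,
            "x": series.x,
            "y": series.y,
            "valid": series.valid.astype(int),
        }
    )
    df.to_csv(path, index=False, float_format="%.9g")


def write_study(study, out_dir: str | Path) -> Path:
    """Write a simulated study (per-trial CSVs + manifest.json) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for trial in study.trials:
        write_conductance_csv(out / f"{trial.trial_id}_sock.csv", trial.sock)
        write_cop_csv(out / f"{trial.trial_id}_platform.csv", trial.platform)
        write_cop_csv(out / f"{trial.trial_id}_truth.csv", trial.truth)
    manifest = study.manifest()
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out / "manifest.json"


def read_manifest(study_dir: str | Path) -> dict:
    path = Path(study_dir) / "manifest.json"
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


METRICS_COLUMNS = [
    "participant", "exercise", "repetition", "foot", "axis",
    "n", "lag_s",
    "rmse_abs_mm", "rmse_rel",
    "bias_mm", "loa_low_mm", "loa_high_mm", "frac_outside",
    "ccc", "ccc_ci_low", "ccc_ci_high",
    "class_strict", "class_loose",
]


def write_metrics_tsv(path: str | Path, metrics: pd.DataFrame) -> None:
    cols = [c for c in METRICS_COLUMNS if c in metrics.columns]
    cols += [c for c in metrics.columns if c not in cols]
    metrics[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_metrics_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
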