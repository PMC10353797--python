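"""CSV readers/writers, run manifests and draw persistence.

All tabular artefacts are plain UTF-8 comma-separated files with a header
row.  Region labels are kept as strings end-to-end (never positional
indices), so the 7-division and 8-division survey rounds coexist safely.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import surveys, __version__


class SurveyCsvError(ValueError):
    """Malformed survey CSV (message names the offending row)."""


def read_survey_csv(
    path,
    covariates=surveys.COVARIATES,
    levels=None,
    require_outcome: bool = False,
) -> pd.DataFrame:
    """Read and validate a person-level survey CSV.

    Requires ``age`` and ``region`` columns; checks that age and (when
    present) BMI are numeric and positive, and that categorical levels
    match the schema.  Error messages carry 1-based data row numbers.
    """
    df = pd.read_csv(path, dtype={"region": str})
    levels = levels or surveys.COVARIATE_LEVELS
    for col in ("age", "region"):
        if col not in df.columns:
            raise SurveyCsvError(f"{path}: missing required column {col!r}")
    for col in ("age", "bmi"):
        if col not in df.columns:
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 1
            raise SurveyCsvError(
                f"{path}: non-numeric {col} {df[col][bad].iloc[0]!r} at data row {row}"
            )
        if (vals <= 0).any():
            row = int(np.flatnonzero(vals <= 0)[0]) + 1
            raise SurveyCsvError(f"{path}: non-positive {col} at data row {row}")
        df[col] = vals
    for cov in covariates:
        if cov not in df.columns or cov not in levels:
            continue
        observed = df[cov].dropna().astype(str)
        bad = ~observed.isin(levels[cov])
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 1
            raise SurveyCsvError(
                f"{path}: unknown {cov} level {observed[bad].iloc[0]!r} "
                f"at data row {row}"
            )
    if require_outcome and "nutrition_category" not in df.columns:
        if "bmi" not in df.columns:
            raise SurveyCsvError(f"{path}: need nutrition_category or bmi")
    return df


def write_dataset(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g")


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_manifest(path, seed, config: dict, extra: dict | None = None) -> None:
    """Flat key=value manifest recording tool version, seed and config hash."""
    lines = {
        "tool_version": __version__,
        "seed": seed,
        "config_hash": config_hash(config),
        **(extra or {}),
    }
    with open(path, "w") as fh:
        for k, v in lines.items():
            fh.write(f"{k}={v}\n")
        fh.write("config_json=" + json.dumps(config, sort_keys=True, default=str) + "\n")


def read_manifest(path) -> dict:
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if "=" in line:
                k, v = line.split("=", 1)
                out[k] = v
    return out


def write_draws(fit, out_dir) -> list:
    """Persist retained draws, one long-format CSV per parameter block."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    labels = {
        "beta": list(fit.data.linear_labels),
        "theta": None,
        "g": list(fit.data.graph.region_ids) if fit.data.graph else None,
        "h": list(fit.data.graph.region_ids) if fit.data.graph else None,
    }
    for name, arr in fit.draws.items():
        path = out_dir / f"draws_{name}.csv"
        if arr.ndim == 1:  # deviance trace
            pd.DataFrame({"iteration": np.arange(len(arr)), "value": arr}).to_csv(
                path, index=False
            )
        elif arr.ndim == 2:  # per-category variance
            frames = []
            for ci, cat in enumerate(fit.categories):
                frames.append(
                    pd.DataFrame(
                        {
                            "iteration": np.arange(arr.shape[0]),
                            "category": cat,
                            "parameter": name,
                            "value": arr[:, ci],
                        }
                    )
                )
            pd.concat(frames, ignore_index=True).to_csv(path, index=False)
        else:
            lab = labels.get(name)
            frames = []
            for ci, cat in enumerate(fit.categories):
                for pi in range(arr.shape[2]):
                    frames.append(
                        pd.DataFrame(
                            {
                                "iteration": np.arange(arr.shape[0]),
                                "category": cat,
                                "parameter": lab[pi] if lab else f"{name}[{pi}]",
                                "value": arr[:, ci, pi],
                            }
                        )
                    )
            pd.concat(frames, ignore_index=True).to_csv(path, index=False)
        written.append(path)
    return written


def export_matrix_coordinates(matrix, path) -> None:
    """Write a matrix as (row, col, value) text, one nonzero per line."""
    matrix = np.asarray(matrix)
    with open(path, "w") as fh:
        fh.write("row,col,value\n")
        for i, j in zip(*np.nonzero(matrix)):
            fh.write(f"{i},{j},{matrix[i, j]:.12g}\n")
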