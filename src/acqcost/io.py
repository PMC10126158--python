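"""Reading and writing the tidy CSV formats used across the pipeline.

Curves CSV (long format): colony_id, population, plasmid_id, replicate_id,
time_h, value.  Phenotypes CSV: colony_id, population, plasmid_id, lag_h,
growth_rate_per_h, ttt_h, qc_pass, qc_reason.  Files may carry ``#``-prefixed
metadata header lines (seed, config hash) which readers skip.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import GrowthCurve

__all__ = [
    "CURVE_COLUMNS",
    "read_curves",
    "write_curves",
    "curves_to_frame",
    "frame_to_curves",
    "write_table",
    "wide_to_long",
    "load_run_config",
    "config_hash",
]

CURVE_COLUMNS = ["colony_id", "population", "plasmid_id", "replicate_id",
                 "time_h", "value"]
PHENOTYPE_COLUMNS = ["colony_id", "population", "plasmid_id", "lag_h",
                     "growth_rate_per_h", "ttt_h", "qc_pass", "qc_reason"]


class CurveParseError(ValueError):
    pass


def curves_to_frame(curves: list[GrowthCurve]) -> pd.DataFrame:
    frames = []
    for c in curves:
        frames.append(pd.DataFrame({
            "colony_id": c.colony_id, "population": c.population,
            "plasmid_id": c.plasmid_id, "replicate_id": c.replicate_id,
            "time_h": c.times, "value": c.values,
        }))
    return pd.concat(frames, ignore_index=True) if frames \
        else pd.DataFrame(columns=CURVE_COLUMNS)


def frame_to_curves(df: pd.DataFrame) -> list[GrowthCurve]:
    missing = [c for c in CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise CurveParseError(f"missing required column(s): {', '.join(missing)}")
    for col in ("time_h", "value"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise CurveParseError(
                f"non-numeric {col} at data row(s) {list(bad[:5])}"
            )
        if coerced.isna().any():
            raise CurveParseError(f"missing {col} values at row(s) "
                                  f"{list(df.index[coerced.isna()][:5])}")
        df = df.assign(**{col: coerced})
    curves = []
    for colony_id, grp in df.groupby("colony_id", sort=True):
        if grp["time_h"].duplicated().any():
            dup = grp.loc[grp["time_h"].duplicated(), "time_h"].iloc[0]
            raise CurveParseError(
                f"duplicate time {dup} for colony {colony_id!r}"
            )
        grp = grp.sort_values("time_h")
        curves.append(GrowthCurve(
            colony_id=str(colony_id),
            population=str(grp["population"].iloc[0]),
            plasmid_id=str(grp["plasmid_id"].iloc[0]),
            replicate_id=str(grp["replicate_id"].iloc[0]),
            times=grp["time_h"].to_numpy(),
            values=grp["value"].to_numpy(),
        ))
    return curves


def read_curves(path) -> list[GrowthCurve]:
    """Load a long-format curves CSV into GrowthCurve objects."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    return frame_to_curves(df)


def _write_with_metadata(df: pd.DataFrame, path, metadata: dict | None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def write_curves(curves: list[GrowthCurve], path, metadata: dict | None = None) -> None:
    _write_with_metadata(curves_to_frame(curves), path, metadata)


def write_table(df: pd.DataFrame, path, metadata: dict | None = None) -> None:
    _write_with_metadata(df, path, metadata)


def wide_to_long(wide: pd.DataFrame, population: str, plasmid_id: str,
                 replicate_id: str, time_col: str = "time_h") -> pd.DataFrame:
    """Convert a plate-reader style wide table (time column + one column per
    well) to the long curves format; well names become colony ids."""
    if time_col not in wide.columns:
        raise CurveParseError(f"missing time column {time_col!r}")
    long = wide.melt(id_vars=[time_col], var_name="colony_id", value_name="value")
    long["population"] = population
    long["plasmid_id"] = plasmid_id
    long["replicate_id"] = replicate_id
    long = long.rename(columns={time_col: "time_h"})
    return long[CURVE_COLUMNS]


def load_run_config(path) -> dict:
    """Read a YAML/JSON run configuration into a plain dict."""
    text = Path(path).read_text(encoding="utf-8")
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError("run config must be a mapping at top level")
    return cfg


def config_hash(config: dict) -> str:
    """Stable short hash of a config dict, embedded in output metadata."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
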