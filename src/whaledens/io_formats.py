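"""CSV readers/writers for the four input schemas.

Single source of truth for column names, units and validation.  All files
are comma-separated UTF-8 with a mandatory header row and "." decimals.

Schemas
-------
sightings : perp_distance (km), group_size, species, beaufort (0-5),
            visibility (Good/Fair/Poor), sightability (0-3)
effort    : transect_id, length (km)
foi       : foi_id, psi1..psi13 (each 0/1/2), sea_state, stratum, observer
tag depth : deployment_id, t (s), depth (m), daylight (bool)
tag summary : deployment_id, time_above_s, time_below_s, total_daylight_s
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from whaledens.errors import SchemaError, ValidationError
from whaledens.foi_scoring import FOIRecord, SEA_STATES, STRATA, classify, score_foi

logger = logging.getLogger(__name__)

SIGHTING_COLUMNS = [
    "perp_distance",
    "group_size",
    "species",
    "beaufort",
    "visibility",
    "sightability",
]
EFFORT_COLUMNS = ["transect_id", "length"]
PSI_COLUMNS = [f"psi{i}" for i in range(1, 14)]
FOI_COLUMNS = ["foi_id", *PSI_COLUMNS, "sea_state", "stratum", "observer"]
TAG_DEPTH_COLUMNS = ["deployment_id", "t", "depth", "daylight"]
TAG_SUMMARY_COLUMNS = [
    "deployment_id",
    "time_above_s",
    "time_below_s",
    "total_daylight_s",
]

VISIBILITY_LEVELS = ["Good", "Fair", "Poor"]


def _require_columns(df: pd.DataFrame, columns: Iterable[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} file is missing column(s): {missing}")


def _bad_rows(msg: str, mask: pd.Series) -> str:
    rows = [int(i) for i in np.flatnonzero(mask.to_numpy())]
    return f"{msg} at row(s) {rows}"


def read_sightings(path: str | Path) -> pd.DataFrame:
    """Read and validate a ship-survey sightings table."""
    df = pd.read_csv(path)
    _require_columns(df, SIGHTING_COLUMNS, "sightings")
    df = df[SIGHTING_COLUMNS].copy()
    if df[["perp_distance", "group_size"]].isna().any().any():
        mask = df[["perp_distance", "group_size"]].isna().any(axis=1)
        raise ValidationError(_bad_rows("missing mandatory field", mask))
    if not np.isfinite(df["perp_distance"]).all() or (df["perp_distance"] < 0).any():
        mask = ~np.isfinite(df["perp_distance"]) | (df["perp_distance"] < 0)
        raise ValidationError(_bad_rows("perp_distance must be finite and >= 0", mask))
    if (df["group_size"] < 1).any():
        raise ValidationError(_bad_rows("group_size must be >= 1", df["group_size"] < 1))
    df["group_size"] = df["group_size"].astype(int)
    if not df["beaufort"].between(0, 5).all():
        raise ValidationError(
            _bad_rows("beaufort must be in 0..5", ~df["beaufort"].between(0, 5))
        )
    bad_vis = ~df["visibility"].isin(VISIBILITY_LEVELS)
    if bad_vis.any():
        raise ValidationError(
            _bad_rows(f"visibility must be one of {VISIBILITY_LEVELS}", bad_vis)
        )
    if not df["sightability"].between(0, 3).all():
        raise ValidationError(
            _bad_rows("sightability must be in 0..3", ~df["sightability"].between(0, 3))
        )
    return df


def write_sightings(df: pd.DataFrame, path: str | Path) -> None:
    df[SIGHTING_COLUMNS].to_csv(path, index=False)


def read_effort(path: str | Path) -> pd.DataFrame:
    """Read and validate a transect effort table (lengths in km)."""
    df = pd.read_csv(path)
    _require_columns(df, EFFORT_COLUMNS, "effort")
    df = df[EFFORT_COLUMNS].copy()
    if (df["length"] <= 0).any() or df["length"].isna().any():
        mask = (df["length"] <= 0) | df["length"].isna()
        raise ValidationError(_bad_rows("transect length must be > 0", mask))
    return df


def write_effort(df: pd.DataFrame, path: str | Path) -> None:
    df[EFFORT_COLUMNS].to_csv(path, index=False)


def read_foi_table(
    path: str | Path, weights: Iterable[int] | None = None
) -> list[FOIRecord]:
    """Read an FOI criterion-score table into validated :class:`FOIRecord` s.

    The total score ``C_s`` and the class label are always recomputed from
    the 13 criterion columns; any stored total that disagrees is logged and
    overridden.
    """
    df = pd.read_csv(path)
    _require_columns(df, FOI_COLUMNS, "FOI")
    for col in PSI_COLUMNS:
        bad = ~df[col].isin([0, 1, 2])
        if bad.any():
            raise ValidationError(
                _bad_rows(f"criterion {col} must be in {{0,1,2}}", bad)
            )
    bad_sea = ~df["sea_state"].isin(SEA_STATES)
    if bad_sea.any():
        raise ValidationError(_bad_rows(f"sea_state must be in {SEA_STATES}", bad_sea))
    bad_str = ~df["stratum"].isin(STRATA)
    if bad_str.any():
        raise ValidationError(_bad_rows(f"stratum must be in {STRATA}", bad_str))

    records = []
    for idx, row in df.iterrows():
        psi = tuple(int(row[c]) for c in PSI_COLUMNS)
        c_s = score_foi(psi, weights=weights)
        if "c_s" in df.columns and not pd.isna(row.get("c_s")) and row["c_s"] != c_s:
            logger.warning(
                "FOI %s row %d: stored C_s=%s disagrees with recomputed %d; overriding",
                row["foi_id"], idx, row["c_s"], c_s,
            )
        records.append(
            FOIRecord(
                foi_id=str(row["foi_id"]),
                psi=psi,
                c_s=c_s,
                label=classify(c_s),
                sea_state=str(row["sea_state"]),
                stratum=str(row["stratum"]),
                observer=str(row["observer"]),
            )
        )
    return records


def write_foi_table(records: list[FOIRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row = {"foi_id": r.foi_id}
        row.update({f"psi{i + 1}": v for i, v in enumerate(r.psi)})
        row.update(
            {
                "sea_state": r.sea_state,
                "stratum": r.stratum,
                "observer": r.observer,
                "c_s": r.c_s,
                "label": r.label,
            }
        )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_tag_depths(path: str | Path) -> dict[str, pd.DataFrame]:
    """Read per-deployment depth series, clamping sensor noise above surface.

    Negative depths (pressure-sensor offsets) are clamped to 0 so they can
    never register as deep.  Time must be strictly increasing within each
    deployment.
    """
    df = pd.read_csv(path)
    _require_columns(df, TAG_DEPTH_COLUMNS, "tag depth")
    df = df[TAG_DEPTH_COLUMNS].copy()
    df["depth"] = df["depth"].clip(lower=0.0)
    df["daylight"] = df["daylight"].astype(bool)
    series: dict[str, pd.DataFrame] = {}
    for dep, grp in df.groupby("deployment_id", sort=True):
        t = grp["t"].to_numpy()
        if not np.all(np.diff(t) > 0):
            raise ValidationError(
                f"deployment {dep}: time stamps are not strictly increasing"
            )
        series[str(dep)] = grp.reset_index(drop=True)
    return series


def write_tag_depths(series: dict[str, pd.DataFrame], path: str | Path) -> None:
    pd.concat(series.values(), ignore_index=True)[TAG_DEPTH_COLUMNS].to_csv(
        path, index=False
    )


def read_tag_summaries(path: str | Path) -> pd.DataFrame:
    """Read pre-summarised per-tag daylight second totals.

    Accepted as an alternative to raw depth series when only per-deployment
    totals (seconds above / below the surface threshold) are available.
    """
    df = pd.read_csv(path)
    _require_columns(df, TAG_SUMMARY_COLUMNS, "tag summary")
    df = df[TAG_SUMMARY_COLUMNS].copy()
    if (df[["time_above_s", "time_below_s"]] < 0).any().any():
        raise ValidationError("tag summary times must be >= 0")
    resid = (df["time_above_s"] + df["time_below_s"] - df["total_daylight_s"]).abs()
    if (resid > 0.11).any():  # one 10 Hz sample period of slack
        mask = resid > 0.11
        raise ValidationError(
            _bad_rows("time_above_s + time_below_s must equal total_daylight_s", mask)
        )
    return df


def write_tag_summaries(df: pd.DataFrame, path: str | Path) -> None:
    df[TAG_SUMMARY_COLUMNS].to_csv(path, index=False)
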