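"""Readers and writers for the study's tabular and spatial formats."""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .homerange import FixSeries

__all__ = [
    "read_fixes",
    "read_packs",
    "read_dyads",
    "split_series",
    "write_geojson",
    "lonlat_to_planar",
]

EARTH_RADIUS_M = 6_371_000.0


def lonlat_to_planar(lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Local equirectangular projection about the fix centroid (metres).

    Adequate at study extents well under 100 km, where distortion is
    negligible compared with kernel smoothing scales.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    lon0, lat0 = lon.mean(), lat.mean()
    x = np.radians(lon - lon0) * EARTH_RADIUS_M * math.cos(math.radians(lat0))
    y = np.radians(lat - lat0) * EARTH_RADIUS_M
    return x, y


def read_fixes(path: str | Path) -> pd.DataFrame:
    """Read a fix table (pack_id, timestamp, x_m/y_m or lon/lat).

    Timestamps are parsed to UTC; an unparseable timestamp raises with its
    1-based data row number.  Lon/lat input is projected to planar metres.
    """
    df = pd.read_csv(path)
    if "pack_id" not in df.columns:
        raise ValueError(f"{path}: missing pack_id column")
    if "timestamp" not in df.columns:
        raise ValueError(f"{path}: missing timestamp column")
    parsed = pd.to_datetime(df["timestamp"], utc=True, errors="coerce")
    if parsed.isna().any():
        row = int(parsed.index[parsed.isna()][0]) + 1
        raise ValueError(f"{path}: unparseable timestamp at data row {row}")
    df = df.copy()
    df["timestamp"] = parsed
    if {"x_m", "y_m"} <= set(df.columns):
        pass
    elif {"lon", "lat"} <= set(df.columns):
        x, y = lonlat_to_planar(df["lon"], df["lat"])
        df["x_m"], df["y_m"] = x, y
    else:
        raise ValueError(f"{path}: need x_m/y_m or lon/lat columns")
    return df[["pack_id", "timestamp", "x_m", "y_m"]]


def split_series(fixes: pd.DataFrame) -> dict[str, FixSeries]:
    """Split a long fix table into per-pack FixSeries."""
    out: dict[str, FixSeries] = {}
    for pid, sub in fixes.groupby("pack_id", sort=True):
        sub = sub.sort_values("timestamp").reset_index(drop=True)
        out[str(pid)] = FixSeries(str(pid), sub[["timestamp", "x_m", "y_m"]])
    return out


def read_packs(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"pack_id", "n_adults", "n_yearlings", "n_pups"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_dyads(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"focal_pack", "neighbour_pack", "relatedness"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = ~df["relatedness"].isin(["related", "unrelated"])
    if bad.any():
        raise ValueError(
            f"{path}: bad relatedness value at data row {int(df.index[bad][0]) + 1}"
        )
    return df


def write_geojson(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj) + "\n")
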