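"""Dyadic territory-overlap metrics on raster isopleths.

Three quantities per neighbouring-pack pair (dyad):

* directional overlap — the percentage of the focal pack's level-p kernel
  area covered by the neighbour's same-level kernel; two values per dyad;
* exclusive-kernel utilisation intensity — percent of a pack's fixes in
  each annulus (50%, 75% minus 50%, 95% minus 75%) divided by the annulus
  area in km^2;
* overlap-zone occupancy — the fraction of the focal pack's fixes inside
  the intersection of the two 95% kernels.

All areas and intersections are computed on rasters.  For a dyad the two
masks are resampled onto a shared grid (union bounding box, finest common
cell size, cell-centre membership), so intersection areas and kernel areas
are mutually consistent by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .homerange import FixSeries, IsoplethSet

__all__ = [
    "DyadOverlapRecord",
    "OverlapZoneOccupancy",
    "directional_overlap",
    "exclusive_kernels",
    "utilisation_intensity",
    "time_in_overlap_zone",
    "overlap_zone_geojson",
    "dyad_table",
    "intensity_ratio",
]


@dataclass
class DyadOverlapRecord:
    """Directional overlap for one ordered pack pair at one isopleth level."""

    focal_pack: str
    neighbour_pack: str
    level: float
    overlap_area_km2: float
    pct_of_focal: float
    relatedness: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_of_focal <= 100.0 + 1e-9):
            raise ValueError(f"pct_of_focal out of range: {self.pct_of_focal}")


@dataclass
class OverlapZoneOccupancy:
    """Fraction of the focal pack's fixes inside the 95%-95% overlap zone."""

    focal_pack: str
    neighbour_pack: str
    proportion_time: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.proportion_time <= 1.0):
            raise ValueError("proportion_time must lie in [0, 1]")


def _mask_lookup(iso: IsoplethSet, level: float, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Membership of world points in an isopleth mask (half-open cells)."""
    m = iso.mask(level)
    ny, nx = m.shape
    ix = np.floor((x - iso.origin[0]) / iso.cell_size).astype(int)
    iy = np.floor((y - iso.origin[1]) / iso.cell_size).astype(int)
    ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
    out = np.zeros(x.shape, dtype=bool)
    out[ok] = m[iy[ok], ix[ok]]
    return out


def _bbox(iso: IsoplethSet) -> tuple[float, float, float, float]:
    ny, nx = next(iter(iso.masks.values())).shape
    x0, y0 = iso.origin
    return x0, y0, x0 + nx * iso.cell_size, y0 + ny * iso.cell_size


def directional_overlap(
    iso_focal: IsoplethSet,
    iso_neighbour: IsoplethSet,
    level: float,
    relatedness: str | None = None,
) -> tuple[DyadOverlapRecord, DyadOverlapRecord]:
    """Same-level kernel overlap in both directions of a dyad.

    Both masks are resampled onto a shared grid covering the union of the
    two bounding boxes at the finest common cell size; the intersection
    area and each pack's kernel area are counted on that grid, and each
    direction's percentage is the intersection over the focal area.
    """
    if level not in iso_focal.masks or level not in iso_neighbour.masks:
        raise ValueError(f"both isopleth sets must contain level {level}")

    ax0, ay0, ax1, ay1 = _bbox(iso_focal)
    bx0, by0, bx1, by1 = _bbox(iso_neighbour)
    cell = min(iso_focal.cell_size, iso_neighbour.cell_size)
    cell_km2 = (cell / 1000.0) ** 2

    disjoint = ax1 <= bx0 or bx1 <= ax0 or ay1 <= by0 or by1 <= ay0
    if disjoint:
        inter_area = 0.0
        area_a = iso_focal.area_km2(level)
        area_b = iso_neighbour.area_km2(level)
        pct_a = pct_b = 0.0
    else:
        x0, y0 = min(ax0, bx0), min(ay0, by0)
        x1, y1 = max(ax1, bx1), max(ay1, by1)
        nx = int(math.ceil((x1 - x0) / cell))
        ny = int(math.ceil((y1 - y0) / cell))
        xc = x0 + (np.arange(nx) + 0.5) * cell
        yc = y0 + (np.arange(ny) + 0.5) * cell
        gx, gy = np.meshgrid(xc, yc)
        in_a = _mask_lookup(iso_focal, level, gx, gy)
        in_b = _mask_lookup(iso_neighbour, level, gx, gy)
        area_a = in_a.sum() * cell_km2
        area_b = in_b.sum() * cell_km2
        inter_area = float((in_a & in_b).sum()) * cell_km2
        pct_a = 100.0 * inter_area / area_a if area_a > 0 else 0.0
        pct_b = 100.0 * inter_area / area_b if area_b > 0 else 0.0

    rec_a = DyadOverlapRecord(
        iso_focal.pack_id, iso_neighbour.pack_id, level, inter_area,
        min(pct_a, 100.0), relatedness,
    )
    rec_b = DyadOverlapRecord(
        iso_neighbour.pack_id, iso_focal.pack_id, level, inter_area,
        min(pct_b, 100.0), relatedness,
    )
    return rec_a, rec_b


def exclusive_kernels(iso: IsoplethSet) -> dict[float, np.ndarray]:
    """Split a nested 50/75/95 isopleth set into exclusive annuli.

    E50 = K50; E75 = K75 minus K50; E95 = K95 minus K75.  Their areas sum
    exactly to area(K95) on the raster.
    """
    for lv in (0.50, 0.75, 0.95):
        if lv not in iso.masks:
            raise ValueError("exclusive kernels need levels 50/75/95")
    k50, k75, k95 = iso.mask(0.50), iso.mask(0.75), iso.mask(0.95)
    if (k50 & ~k75).any() or (k75 & ~k95).any():
        raise ValueError("isopleth masks are not nested")
    return {0.50: k50, 0.75: k75 & ~k50, 0.95: k95 & ~k75}


def utilisation_intensity(series: FixSeries, iso: IsoplethSet) -> pd.DataFrame:
    """Per-annulus time budget and utilisation intensity for one pack.

    ``pct_time`` is the percentage of the pack's fixes inside each
    exclusive kernel; ``intensity`` divides it by the annulus area (km^2),
    i.e. percent of time per km^2.  Annuli with zero area report NaN
    intensity rather than infinity.
    """
    if series.n_fixes == 0:
        raise ValueError("empty fix series")
    excl = exclusive_kernels(iso)
    xy = series.xy
    cell_km2 = (iso.cell_size / 1000.0) ** 2
    rows = []
    for lv in (0.50, 0.75, 0.95):
        m = excl[lv]
        tmp = IsoplethSet(
            iso.pack_id, iso.origin, iso.cell_size, (lv,), {lv: m}
        )
        inside = tmp.contains(lv, xy)
        area = float(m.sum()) * cell_km2
        pct_time = 100.0 * inside.sum() / series.n_fixes
        rows.append(
            {
                "pack_id": series.pack_id,
                "level": int(round(lv * 100)),
                "exclusive_area_km2": area,
                "pct_time": pct_time,
                "intensity": pct_time / area if area > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def intensity_ratio(mean_a: float, mean_b: float) -> float:
    """Ratio of two mean utilisation intensities (e.g. core vs periphery)."""
    if mean_b == 0:
        raise ValueError("denominator intensity is zero")
    return mean_a / mean_b


def time_in_overlap_zone(
    series_focal: FixSeries,
    iso_focal: IsoplethSet,
    iso_neighbour: IsoplethSet,
    level: float = 0.95,
) -> OverlapZoneOccupancy:
    """Fraction of focal fixes inside the intersection of the two level-p
    kernels, each fix counted as an equal unit of time."""
    if series_focal.n_fixes == 0:
        raise ValueError("empty focal fix series")
    xy = series_focal.xy
    in_own = iso_focal.contains(level, xy)
    in_other = iso_neighbour.contains(level, xy)
    prop = float((in_own & in_other).sum()) / series_focal.n_fixes
    return OverlapZoneOccupancy(
        iso_focal.pack_id, iso_neighbour.pack_id, prop
    )


def overlap_zone_geojson(
    iso_a: IsoplethSet, iso_b: IsoplethSet, level: float = 0.95
) -> dict:
    """GeoJSON of a dyad's level-p overlap zone, for visual inspection."""
    ax0, ay0, ax1, ay1 = _bbox(iso_a)
    bx0, by0, bx1, by1 = _bbox(iso_b)
    cell = min(iso_a.cell_size, iso_b.cell_size)
    x0, y0 = min(ax0, bx0), min(ay0, by0)
    x1, y1 = max(ax1, bx1), max(ay1, by1)
    nx = int(math.ceil((x1 - x0) / cell))
    ny = int(math.ceil((y1 - y0) / cell))
    xc = x0 + (np.arange(nx) + 0.5) * cell
    yc = y0 + (np.arange(ny) + 0.5) * cell
    gx, gy = np.meshgrid(xc, yc)
    zone = _mask_lookup(iso_a, level, gx, gy) & _mask_lookup(iso_b, level, gx, gy)
    tmp = IsoplethSet(
        f"{iso_a.pack_id}-{iso_b.pack_id}", (x0, y0), cell, (level,),
        {level: zone},
    )
    return tmp.to_geojson()


def dyad_table(
    isopleths: dict[str, IsoplethSet],
    series: dict[str, FixSeries],
    dyads: pd.DataFrame,
    packs: pd.DataFrame | None = None,
    levels: tuple[float, ...] = (0.50, 0.75, 0.95),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the long-format dyadic tables for a whole study.

    Returns ``(overlap_long, occupancy)``: two rows per dyad per level
    (both directions) joined with relatedness and pack sizes, and one
    95%-zone occupancy row per direction.  Rows are sorted by
    (focal, neighbour, level) for reproducibility.
    """
    sizes: dict[str, int] = {}
    if packs is not None:
        for _, r in packs.iterrows():
            sizes[str(r["pack_id"])] = (
                int(r["n_adults"]) + int(r["n_yearlings"]) + int(r["n_pups"])
            )
    overlap_rows = []
    occ_rows = []
    for _, dy in dyads.iterrows():
        fa, fb = str(dy["focal_pack"]), str(dy["neighbour_pack"])
        rel = str(dy["relatedness"])
        for pid in (fa, fb):
            if pid not in isopleths:
                raise KeyError(f"dyad references unknown pack {pid!r}")
        for lv in sorted(levels):
            rec_a, rec_b = directional_overlap(
                isopleths[fa], isopleths[fb], lv, relatedness=rel
            )
            for rec in (rec_a, rec_b):
                row = {
                    "focal_pack": rec.focal_pack,
                    "neighbour_pack": rec.neighbour_pack,
                    "level": int(round(lv * 100)),
                    "overlap_area_km2": rec.overlap_area_km2,
                    "pct_of_focal": rec.pct_of_focal,
                    "relatedness": rel,
                }
                if sizes:
                    row["focal_size"] = sizes.get(rec.focal_pack)
                    row["neighbour_size"] = sizes.get(rec.neighbour_pack)
                    row["pack_size_ratio"] = (
                        row["focal_size"] / row["neighbour_size"]
                        if row["neighbour_size"]
                        else np.nan
                    )
                overlap_rows.append(row)
        for focal, other in ((fa, fb), (fb, fa)):
            occ = time_in_overlap_zone(
                series[focal], isopleths[focal], isopleths[other]
            )
            occ_rows.append(
                {
                    "focal_pack": focal,
                    "neighbour_pack": other,
                    "proportion_time": occ.proportion_time,
                    "relatedness": rel,
                }
            )
    overlap_cols = [
        "focal_pack", "neighbour_pack", "level", "overlap_area_km2",
        "pct_of_focal", "relatedness",
    ] + (["focal_size", "neighbour_size", "pack_size_ratio"] if sizes else [])
    overlap_long = pd.DataFrame(overlap_rows, columns=overlap_cols)
    occupancy = pd.DataFrame(
        occ_rows,
        columns=["focal_pack", "neighbour_pack", "proportion_time", "relatedness"],
    )
    if len(overlap_long):
        overlap_long = overlap_long.sort_values(
            ["focal_pack", "neighbour_pack", "level"], kind="stable"
        ).reset_index(drop=True)
    if len(occupancy):
        occupancy = occupancy.sort_values(
            ["focal_pack", "neighbour_pack"], kind="stable"
        ).reset_index(drop=True)
    return overlap_long, occupancy
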