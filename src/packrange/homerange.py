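"""Kernel home-range estimation: fix filtering, reference bandwidth,
gridded utilisation distributions and probability isopleths.

The estimator is the classic fixed-kernel utilisation distribution
(Worton 1989): a bivariate Gaussian product kernel with the reference
(plug-in) bandwidth h_i = s_i * n**(-1/6) applied per axis, evaluated on a
regular grid and renormalised to unit probability mass.  Isopleths are
highest-density regions: the smallest set of grid cells whose summed mass
reaches the requested level.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import timedelta

import numpy as np
import pandas as pd

__all__ = [
    "FixSeries",
    "UtilizationDistribution",
    "IsoplethSet",
    "subsample_two_daily",
    "exclude_window",
    "reference_bandwidth",
    "estimate_ud",
    "extract_isopleths",
    "DEFAULT_MORNING_CANDIDATES",
    "DEFAULT_LEVELS",
]

DEFAULT_MORNING_CANDIDATES = ("05:00", "06:00", "06:30")
DEFAULT_LEVELS = (0.50, 0.75, 0.95)

#: tolerance (minutes) around a scheduled clock slot when subsampling
SLOT_TOLERANCE_MIN = 30

#: hard cap on grid cells per axis; guards memory on degenerate configs
MAX_CELLS_PER_AXIS = 512

#: default number of cells along the longer grid axis when cell_size is
#: not given; leaves the 95% range resolved by >= ~100 cells per axis
DEFAULT_CELLS_LONG_AXIS = 256


@dataclass
class FixSeries:
    """One pack's time-ordered GPS fixes over an analysis window.

    ``fixes`` holds columns ``timestamp`` (tz-aware UTC), ``x_m`` and
    ``y_m`` (planar metres).
    """

    pack_id: str
    fixes: pd.DataFrame
    window: tuple | None = None

    def __post_init__(self) -> None:
        df = self.fixes
        required = {"timestamp", "x_m", "y_m"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"fix table missing columns: {sorted(missing)}")
        if len(df) == 0:
            raise ValueError(f"pack {self.pack_id}: empty fix series")
        ts = pd.to_datetime(df["timestamp"])
        if not ts.is_monotonic_increasing or ts.duplicated().any():
            raise ValueError(f"pack {self.pack_id}: timestamps must be strictly increasing")
        xy = df[["x_m", "y_m"]].to_numpy(dtype=float)
        if not np.isfinite(xy).all():
            raise ValueError(f"pack {self.pack_id}: non-finite coordinates")

    @property
    def n_fixes(self) -> int:
        return len(self.fixes)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of planar coordinates in metres."""
        return self.fixes[["x_m", "y_m"]].to_numpy(dtype=float)

    def replace_fixes(self, df: pd.DataFrame) -> "FixSeries":
        return FixSeries(self.pack_id, df.reset_index(drop=True), self.window)


@dataclass
class UtilizationDistribution:
    """Gridded kernel density surface normalised to unit probability mass.

    The grid origin is the lower-left corner; ``density[iy, ix]`` is the
    probability density (per m^2) at the centre of cell (ix, iy).
    """

    pack_id: str
    origin: tuple[float, float]
    cell_size: float
    nx: int
    ny: int
    density: np.ndarray
    bandwidth: tuple[float, float]
    n_fixes: int

    def __post_init__(self) -> None:
        if self.density.shape != (self.ny, self.nx):
            raise ValueError("density shape does not match (ny, nx)")
        if (self.density < 0).any():
            raise ValueError("negative density")
        mass = float(self.density.sum()) * self.cell_area
        if abs(mass - 1.0) > 1e-6:
            raise ValueError(f"UD mass {mass} deviates from 1 by more than 1e-6")

    @property
    def cell_area(self) -> float:
        return self.cell_size**2

    @property
    def x_centers(self) -> np.ndarray:
        return self.origin[0] + (np.arange(self.nx) + 0.5) * self.cell_size

    @property
    def y_centers(self) -> np.ndarray:
        return self.origin[1] + (np.arange(self.ny) + 0.5) * self.cell_size

    def mean_location(self) -> tuple[float, float]:
        """Probability-weighted mean of the surface (metres)."""
        w = self.density * self.cell_area
        mx = float((w.sum(axis=0) * self.x_centers).sum())
        my = float((w.sum(axis=1) * self.y_centers).sum())
        return mx, my

    def to_esri_ascii(self) -> str:
        """Render the density grid in the ESRI ASCII raster dialect."""
        lines = [
            f"ncols {self.nx}",
            f"nrows {self.ny}",
            f"xllcorner {self.origin[0]:.3f}",
            f"yllcorner {self.origin[1]:.3f}",
            f"cellsize {self.cell_size:.6f}",
            "NODATA_value -9999",
        ]
        # ESRI rasters are written top row first
        for row in self.density[::-1]:
            lines.append(" ".join(f"{v:.8e}" for v in row))
        return "\n".join(lines) + "\n"


@dataclass
class IsoplethSet:
    """Nested highest-density regions of a UD at a set of mass levels.

    Masks share the parent UD's grid; areas follow the raster convention
    (cell count times cell area) so that areas and intersections computed
    downstream are mutually consistent.
    """

    pack_id: str
    origin: tuple[float, float]
    cell_size: float
    levels: tuple[float, ...]
    masks: dict[float, np.ndarray]
    areas_km2: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.areas_km2:
            cell_km2 = (self.cell_size / 1000.0) ** 2
            self.areas_km2 = {
                lv: float(m.sum()) * cell_km2 for lv, m in self.masks.items()
            }
        prev = None
        for lv in sorted(self.levels):
            m = self.masks[lv]
            if prev is not None and (prev & ~m).any():
                raise ValueError("isopleth masks are not nested")
            prev = m

    def mask(self, level: float) -> np.ndarray:
        if level not in self.masks:
            raise KeyError(f"no isopleth at level {level}")
        return self.masks[level]

    def area_km2(self, level: float) -> float:
        return self.areas_km2[level]

    def contains(self, level: float, xy: np.ndarray) -> np.ndarray:
        """Half-open cell membership of points (metres) in the level mask."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        m = self.mask(level)
        ny, nx = m.shape
        ix = np.floor((xy[:, 0] - self.origin[0]) / self.cell_size).astype(int)
        iy = np.floor((xy[:, 1] - self.origin[1]) / self.cell_size).astype(int)
        inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        out = np.zeros(len(xy), dtype=bool)
        out[inside] = m[iy[inside], ix[inside]]
        return out

    def boundary_polygons(self, level: float) -> list:
        """Boundary polygons of the level mask in world coordinates.

        Traced with marching squares on the binary mask; intended for
        display/export only — areas and intersections stay on the raster.
        """
        from skimage import measure

        m = self.mask(level).astype(float)
        padded = np.pad(m, 1, constant_values=0.0)
        contours = measure.find_contours(padded, 0.5)
        polys = []
        for c in contours:
            # contour rows are (row=y_index, col=x_index) in padded coords
            xs = self.origin[0] + (c[:, 1] - 1 + 0.5) * self.cell_size
            ys = self.origin[1] + (c[:, 0] - 1 + 0.5) * self.cell_size
            if len(xs) >= 4:
                polys.append(np.column_stack([xs, ys]))
        return polys

    def to_geojson(self) -> dict:
        features = []
        for lv in sorted(self.levels):
            rings = [
                [[float(x), float(y)] for x, y in poly]
                for poly in self.boundary_polygons(lv)
            ]
            features.append(
                {
                    "type": "Feature",
                    "properties": {
                        "pack_id": self.pack_id,
                        "level": lv,
                        "area_km2": self.areas_km2[lv],
                    },
                    "geometry": {
                        "type": "MultiPolygon",
                        "coordinates": [[ring] for ring in rings],
                    },
                }
            )
        return {"type": "FeatureCollection", "features": features}

    def to_geojson_str(self) -> str:
        return json.dumps(self.to_geojson())


def _parse_clock(s: str) -> timedelta:
    h, m = s.split(":")
    return timedelta(hours=int(h), minutes=int(m))


def subsample_two_daily(
    series: FixSeries,
    morning_candidates: tuple[str, ...] = DEFAULT_MORNING_CANDIDATES,
) -> FixSeries:
    """Thin a raw fix table to at most two fixes per calendar day.

    The first retained fix is the earliest one within +/-30 min of any
    morning candidate clock time; the second is the fix nearest 12 h after
    the matched candidate (+/-30 min).  Days lacking one slot contribute
    the other alone.
    """
    if not morning_candidates:
        raise ValueError("morning_candidates must be non-empty")
    df = series.fixes
    ts = pd.to_datetime(df["timestamp"])
    tol = pd.Timedelta(minutes=SLOT_TOLERANCE_MIN)
    cand = [pd.Timedelta(_parse_clock(c)) for c in morning_candidates]

    keep: list[int] = []
    for _, day_idx in ts.groupby(ts.dt.date).groups.items():
        day_ts = ts.loc[day_idx]
        midnight = day_ts.iloc[0].normalize()
        morning_i = None
        morning_cand = None
        for c in sorted(cand):
            target = midnight + c
            ok = day_ts[(day_ts >= target - tol) & (day_ts <= target + tol)]
            if len(ok):
                i = ok.index[0]
                if morning_i is None or ts.loc[i] < ts.loc[morning_i]:
                    morning_i, morning_cand = i, c
        if morning_i is not None:
            keep.append(morning_i)
            targets = [midnight + morning_cand + pd.Timedelta(hours=12)]
        else:
            targets = [midnight + c + pd.Timedelta(hours=12) for c in sorted(cand)]
        evening_i = None
        evening_dist = None
        for target in targets:
            ok = day_ts[(day_ts >= target - tol) & (day_ts <= target + tol)]
            for i in ok.index:
                d = abs(ts.loc[i] - target)
                if evening_i is None or d < evening_dist:
                    evening_i, evening_dist = i, d
        if evening_i is not None and evening_i != morning_i:
            keep.append(evening_i)

    keep.sort(key=lambda i: ts.loc[i])
    if not keep:
        raise ValueError(
            f"pack {series.pack_id}: no fixes match the two-daily schedule"
        )
    return series.replace_fixes(df.loc[keep])


def exclude_window(series: FixSeries, exclusion: tuple) -> FixSeries:
    """Drop all fixes inside a closed date interval (e.g. a denning period)."""
    start, end = pd.to_datetime(exclusion[0]), pd.to_datetime(exclusion[1])
    if pd.isna(start) or pd.isna(end) or start > end:
        raise ValueError(f"malformed exclusion interval {exclusion!r}")
    ts = pd.to_datetime(series.fixes["timestamp"])
    if start.tzinfo is None and ts.dt.tz is not None:
        start = start.tz_localize(ts.dt.tz)
        end = end.tz_localize(ts.dt.tz)
    inside = (ts >= start) & (ts <= end)
    out = series.fixes[~inside.to_numpy()]
    if len(out) == 0:
        raise ValueError(
            f"pack {series.pack_id}: exclusion window removes every fix"
        )
    return series.replace_fixes(out)


def reference_bandwidth(series: FixSeries) -> tuple[float, float]:
    """Reference (plug-in) smoothing parameter per axis, in metres.

    h_i = s_i * n**(-1/6) with s_i the per-axis sample standard deviation
    (denominator n-1).  Equivalent to rescaling each axis to unit SD,
    smoothing with n**(-1/6), and mapping back.
    """
    n = series.n_fixes
    if n < 5:
        raise ValueError(f"pack {series.pack_id}: need >= 5 fixes, got {n}")
    xy = series.xy
    s = xy.std(axis=0, ddof=1)
    if (s <= 0).any():
        raise ValueError(f"pack {series.pack_id}: zero coordinate variance")
    h = s * n ** (-1.0 / 6.0)
    return float(h[0]), float(h[1])


def estimate_ud(
    series: FixSeries,
    cell_size: float | None = None,
    margin_factor: float = 3.0,
    bandwidth: tuple[float, float] | None = None,
    max_cells: int = MAX_CELLS_PER_AXIS,
) -> UtilizationDistribution:
    """Fixed-bandwidth Gaussian kernel density of a fix series on a grid.

    The grid covers the fix bounding box expanded by
    ``margin_factor * max(h)`` on every side.  When ``cell_size`` is None a
    size is chosen so the longer axis spans ``DEFAULT_CELLS_LONG_AXIS``
    cells.  The surface is renormalised so that cell masses sum to one.
    """
    if bandwidth is None:
        bandwidth = reference_bandwidth(series)
    hx, hy = bandwidth
    if not (hx > 0 and hy > 0):
        raise ValueError("bandwidth must be positive")
    xy = series.xy
    margin = margin_factor * max(hx, hy)
    x0, x1 = xy[:, 0].min() - margin, xy[:, 0].max() + margin
    y0, y1 = xy[:, 1].min() - margin, xy[:, 1].max() + margin
    span = max(x1 - x0, y1 - y0)
    if cell_size is None:
        cell_size = span / DEFAULT_CELLS_LONG_AXIS
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    nx = max(1, math.ceil((x1 - x0) / cell_size))
    ny = max(1, math.ceil((y1 - y0) / cell_size))
    if nx > max_cells or ny > max_cells:
        raise ValueError(
            f"grid {nx}x{ny} exceeds {max_cells} cells per axis; "
            "increase cell_size"
        )
    xc = x0 + (np.arange(nx) + 0.5) * cell_size
    yc = y0 + (np.arange(ny) + 0.5) * cell_size
    # separable product kernel: density = Ky^T @ Kx summed over fixes
    kx = np.exp(-0.5 * ((xc[None, :] - xy[:, 0][:, None]) / hx) ** 2)
    ky = np.exp(-0.5 * ((yc[None, :] - xy[:, 1][:, None]) / hy) ** 2)
    density = ky.T @ kx
    total = density.sum() * cell_size**2
    if total <= 0:
        raise ValueError("degenerate density surface")
    density /= total
    return UtilizationDistribution(
        pack_id=series.pack_id,
        origin=(float(x0), float(y0)),
        cell_size=float(cell_size),
        nx=nx,
        ny=ny,
        density=density,
        bandwidth=(float(hx), float(hy)),
        n_fixes=series.n_fixes,
    )


def extract_isopleths(
    ud: UtilizationDistribution, levels: tuple[float, ...] = DEFAULT_LEVELS
) -> IsoplethSet:
    """Highest-density regions of a UD at the requested mass levels.

    Cells are admitted in order of decreasing density; among equal-density
    cells, ascending row-major cell index (deterministic tie-break).  The
    mask at each level is the smallest prefix whose mass reaches the level.
    """
    levels = tuple(sorted(float(lv) for lv in levels))
    if any(not (0.0 < lv < 1.0) for lv in levels):
        raise ValueError("levels must lie strictly between 0 and 1")
    flat = ud.density.ravel()
    mass = flat * ud.cell_area
    order = np.argsort(-flat, kind="stable")  # ties resolved by cell index
    cum = np.cumsum(mass[order])
    total = cum[-1]
    masks: dict[float, np.ndarray] = {}
    for lv in levels:
        if lv >= total + 1e-12:
            raise ValueError(
                f"level {lv} exceeds total representable mass {total:.6f}"
            )
        ncells = int(np.searchsorted(cum, lv - 1e-12) + 1)
        m = np.zeros(flat.shape, dtype=bool)
        m[order[:ncells]] = True
        masks[lv] = m.reshape(ud.density.shape)
    return IsoplethSet(
        pack_id=ud.pack_id,
        origin=ud.origin,
        cell_size=ud.cell_size,
        levels=levels,
        masks=masks,
    )
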