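"""End-to-end orchestration: ingest or simulate, filter fixes, estimate
kernels, compute dyadic overlap, run the rank tests and the multimodel
mixed-effects inference, and write the output bundle."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .homerange import (
    DEFAULT_LEVELS,
    DEFAULT_MORNING_CANDIDATES,
    FixSeries,
    estimate_ud,
    exclude_window,
    extract_isopleths,
    subsample_two_daily,
)
from .io import read_dyads, read_fixes, read_packs, split_series, write_geojson
from .mixedlm import dredge, model_average, predict_interaction_surface
from .overlap import dyad_table, overlap_zone_geojson, utilisation_intensity
from .ranktests import kruskal_wallis, mann_whitney, pairwise_tukey_on_ranks
from .simulate import make_fixtures

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]

logger = logging.getLogger("packrange")

#: packs with fewer post-filter fixes than this are skipped with a warning
MIN_FIXES = 5


@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on.

    Provide either the three input CSV paths or a synthetic ``preset``
    (not neither).  ``denning_exclusions`` maps pack id to a (start, end)
    date pair removed from that pack's series before kernel estimation.
    """

    fixes_path: str | None = None
    packs_path: str | None = None
    dyads_path: str | None = None
    preset: str | None = None
    seed: int = 0
    outdir: str = "packrange_out"
    levels: tuple[float, ...] = DEFAULT_LEVELS
    cell_size_m: float | None = None
    margin_factor: float = 3.0
    morning_candidates: tuple[str, ...] = DEFAULT_MORNING_CANDIDATES
    subsample: bool = False
    denning_exclusions: dict = field(default_factory=dict)
    cum_weight: float = 0.95
    write_rasters: bool = True
    write_geojson: bool = True

    def __post_init__(self) -> None:
        has_paths = self.fixes_path and self.dyads_path
        if not has_paths and not self.preset:
            raise ValueError("config needs input paths or a synthetic preset")
        self.levels = tuple(sorted(self.levels))

    def config_hash(self) -> str:
        payload = {k: str(v) for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record emitted by every run, success or failure."""

    config_hash: str
    version: str
    seed: int
    stage_counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


@dataclass
class RunResult:
    """In-memory bundle of a pipeline run's outputs."""

    series: dict
    isopleths: dict
    areas: pd.DataFrame
    overlap_long: pd.DataFrame
    occupancy: pd.DataFrame
    intensity: pd.DataFrame
    stats_report: pd.DataFrame
    model_table: pd.DataFrame | None
    averaged_effects: pd.DataFrame | None
    prediction_surface: pd.DataFrame | None
    manifest: RunManifest


def _load_inputs(config: PipelineConfig):
    if config.preset:
        study = make_fixtures(config.preset, config.seed)
        return study.series, study.packs, study.dyads
    fixes = read_fixes(config.fixes_path)
    packs = read_packs(config.packs_path) if config.packs_path else None
    dyads = read_dyads(config.dyads_path)
    return split_series(fixes), packs, dyads


def _stats_stage(
    overlap_long: pd.DataFrame,
    occupancy: pd.DataFrame,
    intensity: pd.DataFrame,
) -> pd.DataFrame:
    rows = []

    def add(comparison, result, groups):
        rows.append(
            {
                "comparison": comparison,
                "method": result.method,
                "U": result.statistic_U,
                "T": result.statistic_T,
                "H": result.statistic_H,
                "df": result.df,
                "p_value": result.p_value,
                "n_per_group": "/".join(str(n) for n in result.n_per_group),
                "groups": groups,
            }
        )

    o95 = overlap_long[overlap_long["level"] == 95]
    rel = o95.loc[o95["relatedness"] == "related", "pct_of_focal"].to_numpy()
    unrel = o95.loc[o95["relatedness"] == "unrelated", "pct_of_focal"].to_numpy()
    if len(rel) and len(unrel):
        add("overlap95_related_vs_unrelated", mann_whitney(rel, unrel),
            "related/unrelated")
    occ_rel = occupancy.loc[
        occupancy["relatedness"] == "related", "proportion_time"
    ].to_numpy()
    occ_unrel = occupancy.loc[
        occupancy["relatedness"] == "unrelated", "proportion_time"
    ].to_numpy()
    if len(occ_rel) and len(occ_unrel):
        add("occupancy95_related_vs_unrelated", mann_whitney(occ_rel, occ_unrel),
            "related/unrelated")
    groups = [
        intensity.loc[intensity["level"] == lv, "intensity"].dropna().to_numpy()
        for lv in (50, 75, 95)
    ]
    if all(len(g) for g in groups):
        add("intensity_by_kernel", kruskal_wallis(groups), "50/75/95")
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> RunResult:
    """Execute the full analysis; deterministic given config + seed."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config.config_hash(), __version__, config.seed)
    warns = manifest.warnings

    series, packs, dyads = _load_inputs(config)
    manifest.stage_counts["input_packs"] = len(series)
    manifest.stage_counts["input_dyads"] = len(dyads)

    # fix filtering -------------------------------------------------------
    kept: dict[str, FixSeries] = {}
    for pid in sorted(series):
        fs = series[pid]
        try:
            if config.subsample:
                fs = subsample_two_daily(fs, config.morning_candidates)
            if pid in config.denning_exclusions:
                fs = exclude_window(fs, config.denning_exclusions[pid])
        except ValueError as exc:
            warns.append(f"pack {pid} skipped: {exc}")
            logger.warning("pack %s skipped: %s", pid, exc)
            continue
        if fs.n_fixes < MIN_FIXES:
            warns.append(f"pack {pid} skipped: only {fs.n_fixes} fixes")
            logger.warning("pack %s skipped: only %d fixes", pid, fs.n_fixes)
            continue
        kept[pid] = fs
    manifest.stage_counts["packs_analysed"] = len(kept)

    ok_dyads = dyads[
        dyads["focal_pack"].astype(str).isin(kept)
        & dyads["neighbour_pack"].astype(str).isin(kept)
    ].reset_index(drop=True)
    dropped = len(dyads) - len(ok_dyads)
    if dropped:
        warns.append(f"{dropped} dyads dropped (member pack skipped)")
    manifest.stage_counts["dyads_analysed"] = len(ok_dyads)

    # kernels -------------------------------------------------------------
    isopleths = {}
    area_rows = []
    for pid, fs in kept.items():
        ud = estimate_ud(fs, config.cell_size_m, config.margin_factor)
        iso = extract_isopleths(ud, config.levels)
        isopleths[pid] = iso
        for lv in config.levels:
            area_rows.append(
                {"pack_id": pid, "level": int(round(lv * 100)),
                 "area_km2": iso.area_km2(lv), "n_fixes": fs.n_fixes,
                 "h_x_m": ud.bandwidth[0], "h_y_m": ud.bandwidth[1]}
            )
        if config.write_rasters:
            (outdir / f"ud_{pid}.asc").write_text(ud.to_esri_ascii())
        if config.write_geojson:
            write_geojson(iso.to_geojson(), outdir / f"isopleths_{pid}.geojson")
    areas = pd.DataFrame(area_rows)

    # overlap metrics ------------------------------------------------------
    overlap_long, occupancy = dyad_table(
        isopleths, kept, ok_dyads, packs, config.levels
    )
    intensity = (
        pd.concat(
            [utilisation_intensity(kept[pid], isopleths[pid]) for pid in sorted(kept)],
            ignore_index=True,
        )
        if kept
        else pd.DataFrame(
            columns=["pack_id", "level", "exclusive_area_km2", "pct_time", "intensity"]
        )
    )
    if config.write_geojson:
        for _, dy in ok_dyads.iterrows():
            fa, fb = str(dy["focal_pack"]), str(dy["neighbour_pack"])
            write_geojson(
                overlap_zone_geojson(isopleths[fa], isopleths[fb]),
                outdir / f"zone95_{fa}_{fb}.geojson",
            )
    manifest.stage_counts["overlap_rows"] = len(overlap_long)

    # rank statistics ------------------------------------------------------
    stats_report = _stats_stage(overlap_long, occupancy, intensity)
    tukey = None
    groups = [
        intensity.loc[intensity["level"] == lv, "intensity"].dropna().to_numpy()
        for lv in (50, 75, 95)
    ]
    if all(len(g) > 1 for g in groups):
        tukey = pairwise_tukey_on_ranks(groups, labels=["E50", "E75", "E95"])

    # mixed models ---------------------------------------------------------
    model_table = averaged_effects = surface = None
    o95 = overlap_long[overlap_long["level"] == 95].copy()
    if "pack_size_ratio" in o95.columns and o95["relatedness"].nunique() == 2:
        try:
            mset = dredge(o95)
            avg = model_average(mset, config.cum_weight)
            model_table = mset.table()
            averaged_effects = avg.table().reset_index(names="parameter")
            surface = predict_interaction_surface(avg)
        except ValueError as exc:
            warns.append(f"model stage skipped: {exc}")
            logger.warning("model stage skipped: %s", exc)
    else:
        warns.append("model stage skipped: needs pack sizes and both classes")

    # outputs --------------------------------------------------------------
    areas.to_csv(outdir / "areas.csv", index=False)
    overlap_long.to_csv(outdir / "overlap_long.csv", index=False)
    occupancy.to_csv(outdir / "occupancy.csv", index=False)
    intensity.to_csv(outdir / "intensity.csv", index=False)
    stats_report.to_csv(outdir / "stats_report.csv", index=False)
    if tukey is not None:
        tukey.to_csv(outdir / "tukey_intensity.csv", index=False)
    if model_table is not None:
        model_table.to_csv(outdir / "model_table.csv", index=False)
        averaged_effects.to_csv(outdir / "averaged_effects.csv", index=False)
        surface.to_csv(outdir / "prediction_surface.csv", index=False)
    manifest.write(outdir / "manifest.json")

    return RunResult(
        series=kept,
        isopleths=isopleths,
        areas=areas,
        overlap_long=overlap_long,
        occupancy=occupancy,
        intensity=intensity,
        stats_report=stats_report,
        model_table=model_table,
        averaged_effects=averaged_effects,
        prediction_surface=surface,
        manifest=manifest,
    )
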