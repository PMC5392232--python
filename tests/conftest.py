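import numpy as np
import pandas as pd
import pytest

from packrange.homerange import FixSeries, estimate_ud, extract_isopleths
from packrange.pipeline import PipelineConfig, run_pipeline
from packrange.simulate import FixSchedule, PackScenario, simulate_pack_track


def long_schedule(seed: int, end: str = "2007-10-01") -> FixSchedule:
    """A multi-year gapless schedule (~2000 slots) for convergence checks."""
    return FixSchedule(
        "2005-01-01", end, missingness=0.0, seed=seed, strict_window=False
    )


def simulate_big_track(sigma_km: float = 5.0, seed: int = 0, tau: float = 24.0,
                       center=(0.0, 0.0), pack_id: str = "P",
                       end: str = "2007-10-01") -> FixSeries:
    scen = PackScenario(pack_id, center, sigma_km, tau=tau)
    return simulate_pack_track(scen, long_schedule(seed, end))


def series_from_xy(xy: np.ndarray, pack_id: str = "P") -> FixSeries:
    """Wrap bare coordinates (metres) in a FixSeries with synthetic times."""
    ts = pd.date_range("2020-01-01", periods=len(xy), freq="12h", tz="UTC")
    return FixSeries(
        pack_id, pd.DataFrame({"timestamp": ts, "x_m": xy[:, 0], "y_m": xy[:, 1]})
    )


def analytic_circular_ud(sigma_m: float, ncells: int = 301, extent_sigmas: float = 4.5):
    """A UD built from the exact circular-normal density (no estimation)."""
    half = extent_sigmas * sigma_m
    cell = 2 * half / ncells
    from packrange.homerange import UtilizationDistribution

    xc = -half + (np.arange(ncells) + 0.5) * cell
    gx, gy = np.meshgrid(xc, xc)
    dens = np.exp(-(gx**2 + gy**2) / (2 * sigma_m**2))
    dens /= dens.sum() * cell**2
    return UtilizationDistribution(
        "analytic", (-half, -half), cell, ncells, ncells, dens,
        (sigma_m / 10, sigma_m / 10), 1,
    )


@pytest.fixture(scope="session")
def paper_run(tmp_path_factory):
    """One paper-like synthetic study run end-to-end (21 packs, 20 dyads)."""
    out = tmp_path_factory.mktemp("paper_run")
    cfg = PipelineConfig(
        preset="paper_like", seed=7, outdir=str(out),
        write_rasters=False, write_geojson=False,
    )
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def big_isopleths():
    """Isopleths of one sigma = 5 km pack with ~2000 fixes (seed 0)."""
    fs = simulate_big_track(seed=0)
    ud = estimate_ud(fs)
    return fs, ud, extract_isopleths(ud)
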