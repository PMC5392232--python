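"""Synthetic GPS studies of territorial packs, with analytic ground truth.

Movement is a stationary isotropic Ornstein-Uhlenbeck (OU) process around a
fixed territory centre.  Its stationary utilisation distribution is a
circular bivariate normal, so isopleth radii and dyadic kernel overlaps
have closed forms that serve as oracles for the estimation pipeline:

    R(p)   = sigma * sqrt(-2 ln(1 - p))          (isopleth radius)
    A(p,q) = circle-circle lens area of the two isopleth discs

Fix schedules emulate a twice-daily GPS collar programme: one morning fix
(05:00, 06:00 or 06:30) and a second fix 12 h later, over a four-month
(122-day) window, with i.i.d. Bernoulli dropouts.  The default dropout
probability of 0.113 yields a mean of about 216 retained fixes from the
244 scheduled slots, matching typical collar yield in such programmes.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .homerange import DEFAULT_LEVELS, FixSeries

__all__ = [
    "PackScenario",
    "DyadScenario",
    "FixSchedule",
    "StudyData",
    "simulate_pack_track",
    "analytic_isopleth_radius",
    "analytic_directional_overlap",
    "circle_lens_area",
    "generate_study",
    "make_fixtures",
    "preset_scenarios",
    "PRESETS",
    "DEFAULT_MISSINGNESS",
    "RELATED_SEPARATION_BAND",
    "UNRELATED_SEPARATION_BAND",
]

#: Bernoulli dropout probability per scheduled slot (244 slots -> ~216 fixes)
DEFAULT_MISSINGNESS = 0.113

#: centre separation bands, as multiples of the dyad-mean 95% isopleth radius
RELATED_SEPARATION_BAND = (0.8, 1.6)
UNRELATED_SEPARATION_BAND = (1.6, 2.4)

#: 95% range areas of 200-700 km^2 correspond to sigma of ~3.3-6.1 km
SIGMA_BAND_KM = (3.3, 6.1)

DEFAULT_TAU_HOURS = 24.0


@dataclass
class PackScenario:
    """Ground-truth movement parameters for one simulated pack.

    ``center`` is in planar km; ``sigma`` is the stationary positional SD
    per axis (km); ``tau`` the OU relaxation time (hours).  Pack size
    counts adults (>24 mo), yearlings (12-24 mo) and pups (<12 mo).
    """

    pack_id: str
    center: tuple[float, float]
    sigma: float
    tau: float = DEFAULT_TAU_HOURS
    n_adults: int = 4
    n_yearlings: int = 0
    n_pups: int = 0
    site: str = "siteA"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.sigma) and self.sigma > 0):
            raise ValueError(f"{self.pack_id}: sigma must be finite and > 0")
        if not (math.isfinite(self.tau) and self.tau > 0):
            raise ValueError(f"{self.pack_id}: tau must be finite and > 0")
        if not all(map(math.isfinite, self.center)):
            raise ValueError(f"{self.pack_id}: non-finite centre")
        if self.pack_size < 2:
            raise ValueError(
                f"{self.pack_id}: a pack needs at least two individuals"
            )

    @property
    def pack_size(self) -> int:
        return self.n_adults + self.n_yearlings + self.n_pups


@dataclass
class DyadScenario:
    """A pair of neighbouring packs and their relatedness label."""

    pack_a: PackScenario
    pack_b: PackScenario
    relatedness: str  # "related" | "unrelated"
    relationship_type: str | None = None  # related only

    def __post_init__(self) -> None:
        if self.relatedness not in ("related", "unrelated"):
            raise ValueError(f"bad relatedness {self.relatedness!r}")
        if (self.relatedness == "related") != (self.relationship_type is not None):
            raise ValueError(
                "relationship_type must be present iff relatedness == 'related'"
            )

    @property
    def separation_km(self) -> float:
        (xa, ya), (xb, yb) = self.pack_a.center, self.pack_b.center
        return math.hypot(xa - xb, ya - yb)


@dataclass
class FixSchedule:
    """Twice-daily GPS schedule over an analysis window.

    Slots run from ``window_start`` (inclusive) to ``window_end``
    (exclusive) with a morning fix at ``morning_hour`` and a second fix
    12 h later.  Each slot is dropped independently with probability
    ``missingness``.
    """

    window_start: str = "2010-10-01"
    window_end: str = "2011-01-31"
    morning_hour: str = "06:00"
    missingness: float = DEFAULT_MISSINGNESS
    seed: int = 0
    #: analysis windows are capped at four months; long-run convergence
    #: simulations may lift the cap since the process is stationary
    strict_window: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.missingness < 1.0):
            raise ValueError("missingness must be in [0, 1)")
        start = pd.Timestamp(self.window_start)
        end = pd.Timestamp(self.window_end)
        if end <= start:
            raise ValueError("window_end must be after window_start")
        if self.strict_window and (end - start) > pd.Timedelta(days=124):
            raise ValueError("analysis window must not exceed four months")

    def slots(self) -> pd.DatetimeIndex:
        days = pd.date_range(
            self.window_start, self.window_end, freq="D", inclusive="left", tz="UTC"
        )
        h, m = (int(p) for p in self.morning_hour.split(":"))
        morning = days + pd.Timedelta(hours=h, minutes=m)
        evening = morning + pd.Timedelta(hours=12)
        out = morning.append(evening).sort_values()
        if len(out) == 0:
            raise ValueError("schedule produced no slots")
        return out


def _pack_rng(seed: int, pack_id: str) -> np.random.Generator:
    # stable per-pack substream: adding packs never perturbs existing tracks
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(pack_id.encode())])
    )


def simulate_pack_track(
    scenario: PackScenario, schedule: FixSchedule
) -> FixSeries:
    """Simulate one pack's fix series by the exact OU transition.

    Per axis, x_{t+dt} = mu + (x_t - mu) e^{-dt/tau}
    + N(0, sigma^2 (1 - e^{-2 dt/tau})); the first fix is drawn from the
    stationary N(mu, sigma^2), so every fix is marginally stationary.
    Coordinates are emitted in metres.
    """
    slots = schedule.slots()
    n = len(slots)
    rng = _pack_rng(schedule.seed, scenario.pack_id)
    mu = np.asarray(scenario.center, dtype=float)
    sigma = scenario.sigma
    pos = np.empty((n, 2))
    pos[0] = mu + sigma * rng.standard_normal(2)
    dts = np.diff(slots.view("int64")) / 3.6e12  # hours
    for i, dt in enumerate(dts, start=1):
        rho = math.exp(-dt / scenario.tau)
        innov_sd = sigma * math.sqrt(max(0.0, 1.0 - rho * rho))
        pos[i] = mu + rho * (pos[i - 1] - mu) + innov_sd * rng.standard_normal(2)
    keep = rng.random(n) >= schedule.missingness
    if not keep.any():  # pathological missingness draw; keep first slot
        keep[0] = True
    df = pd.DataFrame(
        {
            "timestamp": slots[keep],
            "x_m": pos[keep, 0] * 1000.0,
            "y_m": pos[keep, 1] * 1000.0,
        }
    )
    return FixSeries(scenario.pack_id, df, window=(slots[0], slots[-1]))


def analytic_isopleth_radius(sigma: float, level: float) -> float:
    """Radius enclosing ``level`` of a circular normal's mass.

    For X ~ N(mu, sigma^2 I_2), P(|X - mu| <= R) = 1 - exp(-R^2/(2 sigma^2)),
    hence R = sigma * sqrt(-2 ln(1 - level)).
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie strictly between 0 and 1")
    if not (sigma > 0):
        raise ValueError("sigma must be positive")
    return sigma * math.sqrt(-2.0 * math.log1p(-level))


def circle_lens_area(r1: float, r2: float, d: float) -> float:
    """Area of intersection of two discs with radii r1, r2 at distance d."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        r = min(r1, r2)
        return math.pi * r * r
    a1 = r1 * r1 * math.acos((d * d + r1 * r1 - r2 * r2) / (2.0 * d * r1))
    a2 = r2 * r2 * math.acos((d * d + r2 * r2 - r1 * r1) / (2.0 * d * r2))
    tri = 0.5 * math.sqrt(
        (-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2)
    )
    return a1 + a2 - tri


def analytic_directional_overlap(
    dyad: DyadScenario, level: float
) -> tuple[float, float]:
    """True directional overlap (percent) between two stationary OU packs.

    The level-p kernels are the discs of radius R_i(p); the overlap onto
    pack i is 100 * lens_area / (pi R_i^2).  Returns (onto_a, onto_b).
    """
    ra = analytic_isopleth_radius(dyad.pack_a.sigma, level)
    rb = analytic_isopleth_radius(dyad.pack_b.sigma, level)
    lens = circle_lens_area(ra, rb, dyad.separation_km)
    pct_a = 100.0 * lens / (math.pi * ra * ra)
    pct_b = 100.0 * lens / (math.pi * rb * rb)
    return pct_a, pct_b


@dataclass
class StudyData:
    """The synthetic study bundle: input tables plus analytic truth."""

    fixes: pd.DataFrame
    packs: pd.DataFrame
    dyads: pd.DataFrame
    truth: pd.DataFrame
    series: dict[str, FixSeries] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.fixes.to_csv(outdir / "fixes.csv", index=False)
        self.packs.to_csv(outdir / "packs.csv", index=False)
        self.dyads.to_csv(outdir / "dyads.csv", index=False)
        self.truth.to_csv(outdir / "truth.csv", index=False)


def generate_study(
    scenarios: list[DyadScenario],
    schedule: FixSchedule,
    levels: tuple[float, ...] = DEFAULT_LEVELS,
) -> StudyData:
    """Simulate every pack in a dyad list and assemble the input tables.

    Packs shared between dyads are simulated once.  The truth table holds
    the analytic directional overlap for both directions of every dyad at
    every level.
    """
    packs: dict[str, PackScenario] = {}
    for dy in scenarios:
        for p in (dy.pack_a, dy.pack_b):
            prev = packs.get(p.pack_id)
            if prev is not None and prev is not p and prev != p:
                raise ValueError(f"duplicate pack id {p.pack_id!r}")
            packs[p.pack_id] = p

    series: dict[str, FixSeries] = {}
    fix_frames = []
    for pid in sorted(packs):
        fs = simulate_pack_track(packs[pid], schedule)
        series[pid] = fs
        frame = fs.fixes.copy()
        frame.insert(0, "pack_id", pid)
        fix_frames.append(frame)
    fixes = (
        pd.concat(fix_frames, ignore_index=True)
        if fix_frames
        else pd.DataFrame(columns=["pack_id", "timestamp", "x_m", "y_m"])
    )
    if len(fixes):
        fixes["timestamp"] = fixes["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")

    packs_df = pd.DataFrame(
        [
            {
                "pack_id": p.pack_id,
                "n_adults": p.n_adults,
                "n_yearlings": p.n_yearlings,
                "n_pups": p.n_pups,
                "site": p.site,
            }
            for p in (packs[pid] for pid in sorted(packs))
        ],
        columns=["pack_id", "n_adults", "n_yearlings", "n_pups", "site"],
    )
    dyads_df = pd.DataFrame(
        [
            {
                "focal_pack": dy.pack_a.pack_id,
                "neighbour_pack": dy.pack_b.pack_id,
                "relatedness": dy.relatedness,
                "relationship_type": dy.relationship_type or "",
            }
            for dy in scenarios
        ],
        columns=["focal_pack", "neighbour_pack", "relatedness", "relationship_type"],
    )
    truth_rows = []
    for dy in scenarios:
        for lv in sorted(levels):
            pa, pb = analytic_directional_overlap(dy, lv)
            truth_rows.append(
                {
                    "focal_pack": dy.pack_a.pack_id,
                    "neighbour_pack": dy.pack_b.pack_id,
                    "level": lv,
                    "analytic_overlap_pct": pa,
                }
            )
            truth_rows.append(
                {
                    "focal_pack": dy.pack_b.pack_id,
                    "neighbour_pack": dy.pack_a.pack_id,
                    "level": lv,
                    "analytic_overlap_pct": pb,
                }
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=["focal_pack", "neighbour_pack", "level", "analytic_overlap_pct"],
    )
    return StudyData(fixes, packs_df, dyads_df, truth, series)


def _draw_pack(
    rng: np.random.Generator, pack_id: str, center: tuple[float, float], site: str
) -> PackScenario:
    return PackScenario(
        pack_id=pack_id,
        center=center,
        sigma=float(rng.uniform(*SIGMA_BAND_KM)),
        tau=DEFAULT_TAU_HOURS,
        n_adults=int(rng.integers(2, 13)),
        n_yearlings=int(rng.integers(0, 7)),
        n_pups=int(rng.integers(0, 11)),
        site=site,
    )


def _mean_r95(a: PackScenario, b: PackScenario) -> float:
    return 0.5 * (
        analytic_isopleth_radius(a.sigma, 0.95)
        + analytic_isopleth_radius(b.sigma, 0.95)
    )


def _chain_site(
    rng: np.random.Generator,
    n_packs: int,
    prefix: str,
    site: str,
    origin: tuple[float, float],
    relatedness: str,
    band: tuple[float, float] | None = None,
) -> tuple[list[PackScenario], list[DyadScenario]]:
    """Place packs along a meandering path; adjacent packs form dyads."""
    packs = [_draw_pack(rng, f"{prefix}01", origin, site)]
    dyads: list[DyadScenario] = []
    heading = rng.uniform(0, 2 * math.pi)
    sep_band = band or (
        RELATED_SEPARATION_BAND
        if relatedness == "related"
        else UNRELATED_SEPARATION_BAND
    )
    for i in range(1, n_packs):
        prev = packs[-1]
        nxt = _draw_pack(
            rng, f"{prefix}{i + 1:02d}", (0.0, 0.0), site
        )
        sep = rng.uniform(*sep_band) * _mean_r95(prev, nxt)
        heading += rng.uniform(-0.6, 0.6)
        cx = prev.center[0] + sep * math.cos(heading)
        cy = prev.center[1] + sep * math.sin(heading)
        nxt.center = (cx, cy)
        packs.append(nxt)
        rel_type = None
        if relatedness == "related":
            rel_type = "female-female" if rng.random() < 10.0 / 12.0 else "male-female"
        dyads.append(DyadScenario(prev, nxt, relatedness, rel_type))
    return packs, dyads


def _ring_site(
    rng: np.random.Generator,
    n_packs: int,
    prefix: str,
    site: str,
    origin: tuple[float, float],
    relatedness: str,
    band: tuple[float, float] | None = None,
) -> tuple[list[PackScenario], list[DyadScenario]]:
    """Place packs on a jittered ring; the cycle yields n_packs dyads."""
    packs = [
        _draw_pack(rng, f"{prefix}{i + 1:02d}", (0.0, 0.0), site)
        for i in range(n_packs)
    ]
    sep_band = band or (
        RELATED_SEPARATION_BAND
        if relatedness == "related"
        else UNRELATED_SEPARATION_BAND
    )
    mean_r95 = sum(analytic_isopleth_radius(p.sigma, 0.95) for p in packs) / n_packs
    side = rng.uniform(*sep_band) * mean_r95
    radius = side / (2.0 * math.sin(math.pi / n_packs))
    for i, p in enumerate(packs):
        ang = 2.0 * math.pi * i / n_packs
        r = radius * (1.0 + rng.uniform(-0.03, 0.03))
        p.center = (origin[0] + r * math.cos(ang), origin[1] + r * math.sin(ang))
    dyads = []
    for i in range(n_packs):
        a, b = packs[i], packs[(i + 1) % n_packs]
        rel_type = "female-female" if relatedness == "related" else None
        dyads.append(DyadScenario(a, b, relatedness, rel_type))
    return packs, dyads


def preset_scenarios(preset: str, seed: int) -> list[DyadScenario]:
    """Build the dyad scenarios for a named study preset.

    ``paper_like``: two study sites — a path of 13 packs giving 12 related
    dyads and, far away, a ring of 8 packs giving 8 unrelated dyads
    (21 packs, 20 dyads in total).  ``tiny``: one related and one
    unrelated dyad.  ``null``: the paper_like layout but with every centre
    separation drawn from one common band regardless of label, so
    relatedness has no true effect.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xD065]))
    if preset == "paper_like":
        _, rel = _chain_site(rng, 13, "B", "botswana", (0.0, 0.0), "related")
        _, unrel = _ring_site(rng, 8, "Z", "zimbabwe", (500.0, 0.0), "unrelated")
        return rel + unrel
    if preset == "null":
        # calibration preset: 20 mutually distant, independent dyads whose
        # separations are iid from one common band and whose relatedness
        # labels are randomly permuted -> labels carry no information
        common = (RELATED_SEPARATION_BAND[0], UNRELATED_SEPARATION_BAND[1])
        labels = ["related"] * 12 + ["unrelated"] * 8
        labels = [labels[i] for i in rng.permutation(20)]
        dyads: list[DyadScenario] = []
        for i, lab in enumerate(labels):
            origin = (250.0 * (i % 5), 250.0 * (i // 5))
            _, pair = _chain_site(
                rng, 2, f"N{i + 1:02d}", "null", origin, lab, band=common
            )
            dyads.append(pair[0])
        return dyads
    if preset == "tiny":
        _, rel = _chain_site(rng, 2, "T", "tiny", (0.0, 0.0), "related")
        _, unrel = _chain_site(rng, 2, "U", "tiny", (120.0, 0.0), "unrelated")
        return rel + unrel
    raise ValueError(
        f"unknown preset {preset!r}; available: paper_like, tiny, null"
    )


PRESETS = ("paper_like", "tiny", "null")


def make_fixtures(
    preset: str, seed: int, outdir: str | Path | None = None
) -> StudyData:
    """Generate a named preset study and optionally write its CSV bundle."""
    scenarios = preset_scenarios(preset, seed)
    schedule = FixSchedule(seed=seed)
    study = generate_study(scenarios, schedule)
    if outdir is not None:
        study.write(outdir)
    return study
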