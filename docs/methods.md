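# Methods

This note documents the models, estimators, numerical choices and known
limitations of `packrange`.

## Movement model and synthetic studies

Each simulated pack moves as a stationary isotropic Ornstein–Uhlenbeck
(OU) process around a fixed territory centre μ, per axis:

    x_{t+Δt} = μ + (x_t − μ)·e^(−Δt/τ) + N(0, σ²(1 − e^(−2Δt/τ)))

with the first fix drawn from the stationary N(μ, σ²). The transition is
exact, so every fix is marginally stationary regardless of the sampling
interval. The OU choice is deliberate: its stationary utilisation
distribution is a circular bivariate normal, which gives closed-form
isopleth radii R(p) = σ√(−2 ln(1−p)) and closed-form dyadic overlaps
(circle–circle lens areas) that serve as independent oracles for the
whole estimation pipeline.

Parameters and defaults:

* **σ (km)** — stationary positional SD per axis. Preset packs draw
  σ ~ U(3.3, 6.1), which maps 95% range areas onto 200–700 km², the
  range typical of the study system.
* **τ (hours)** — relaxation time; default 24 h. Real collar data give
  no direct estimate, so this is a modelling choice: with 12-h sampling
  it yields a lag-1 autocorrelation of e^(−1/2) ≈ 0.61, i.e. visibly
  autocorrelated but mixing within a few days. Note that this leaves an
  *effective* sample size of roughly n/4 independent fixes, which
  matters when sizing test tolerances (below).
* **Schedule** — one morning fix (05:00, 06:00 or 06:30) and a second
  fix 12 h later, over a 122-day (four-month) window: 244 slots. Each
  slot is dropped independently with probability 0.113, so the mean
  retained count is ≈ 216 fixes, matching typical collar yield for this
  protocol. Longer windows are allowed only with `strict_window=False`,
  used by convergence tests that need ~2000 fixes; the process being
  stationary, this changes information content but not the target law.
* **Seeding** — a single global seed fans out to per-pack substreams
  keyed by (seed, CRC32(pack_id)), so adding a pack or dyad never
  perturbs existing tracks and regenerated CSVs are byte-identical.

### Study presets

* `paper_like` — 21 packs, 20 dyads in two distant sites: a meandering
  path of 13 packs (12 related dyads) and a ring of 8 packs (8 unrelated
  dyads). A 21-node dyad graph with 20 edges requires one cycle once the
  sites are separate components; the ring supplies it. Related centre
  separations are drawn from U(0.8, 1.6)·R̄95 and unrelated from
  U(1.6, 2.4)·R̄95 (R̄95 the dyad-mean 95% radius), so related dyads
  overlap substantially at the 95% level and sometimes into 50% cores,
  while unrelated dyads overlap only peripherally or not at all —
  50%-kernel contact is geometrically impossible for unrelated dyads
  (2·R50 ≈ 0.96·R95 < 1.6·R95 even after smoothing inflation).
* `tiny` — one related and one unrelated dyad; an end-to-end smoke
  preset that runs in seconds.
* `null` — a calibration preset with **no** relatedness effect: 20
  mutually distant, independent dyads whose separations are iid from the
  pooled band U(0.8, 2.4)·R̄95 and whose related/unrelated labels
  (12/8) are randomly permuted. Independence across dyads is essential:
  a layout that ties geometry to label (or shares draws across dyads)
  breaks exchangeability and wrecks the type-I calibration the preset
  exists to measure.

What the generator deliberately does *not* emulate: behavioural
avoidance or attraction between packs (tolerance is encoded purely as
centre spacing), den-site attraction (denning periods are excluded from
analysis anyway), habitat anisotropy, GPS position error, and
fix-success patterns correlated with behaviour. Passing tests therefore
demonstrate estimator correctness under a stationary, isotropic,
unit-weight ideal — not robustness to the many ways field data deviate
from it.

## Kernel home ranges

Fixes are optionally thinned to at most two per day (earliest fix within
±30 min of a morning candidate time, plus the fix nearest 12 h later),
and closed date intervals (denning periods) can be excised. The
reference bandwidth is computed per axis, h_i = s_i·n^(−1/6) with s_i
the sample SD (denominator n−1); this equals rescaling each axis to unit
SD, smoothing with n^(−1/6), and mapping back. Packs with fewer than 5
post-filter fixes are skipped with a warning rather than failing a whole
study run.

The UD is a Gaussian product-kernel density evaluated at cell centres of
a regular grid covering the fix bounding box expanded by 3·max(h) per
side, then renormalised to unit mass. The default cell size puts 256
cells along the longer axis (hard cap 512 per axis, with an error
advising a larger cell size), which resolves the 95% range by well over
100 cells and keeps discretisation error far below overlap effect
sizes — halving the cell size moves isopleth areas by well under 5%.

Isopleths are highest-density regions: cells sorted by density
(descending), ties broken by ascending row-major index for determinism,
admitted until cumulative mass reaches the level. Masks at increasing
levels are nested by construction. Areas follow the raster convention
(cell count × cell area); boundary polygons (marching squares) are
exported to GeoJSON for display only. Point-in-region tests use
half-open cell membership.

A consequence worth knowing: kernel smoothing inflates the estimated
range. To first order the smoothed surface is N(μ, (σ²+h²)I), and with
h = σn^(−1/6) the 95% area is inflated by a factor 1 + n^(−1/3) (+7.9%
at n = 2000, +17% at n = 216), and the fraction of the pack's own fixes
inside its p-isopleth is ≈ 1 − (1−p)^(1+n^(−1/3)) rather than p (+2.6 pp
at p = 0.75, n = 2000). Oracle-comparison tests use these corrected
expectations where the raw comparison would sit within Monte-Carlo noise
of its own bound; replicate means (not single draws) are compared
wherever a tolerance is of the same order as single-draw noise.

## Overlap metrics

For each dyad and level, both packs' masks are resampled onto a shared
grid (union bounding box, finest common cell size, cell-centre
membership); the intersection area and each kernel area are counted
there, making the two directional percentages and the areas exactly
consistent. Dyads with zero overlap still emit records (0%), since
near-zero overlaps are data, not missing values.

Exclusive kernels partition the 95% kernel: E50 = K50, E75 = K75∖K50,
E95 = K95∖K75, with areas summing exactly to area(K95) on the raster.
Utilisation intensity is (percent of fixes in the annulus)/(annulus area
in km²); zero-area annuli report NaN, never infinity. The divisor is the
*exclusive* area — the natural reading when exclusive kernels are
constructed precisely for this purpose; dividing by the full-contour
area instead is a one-line change and is intentionally not exposed as a
default. "Time" is fix counts with equal weights, on the same
post-filter fix set used for the UD.

Overlap-zone occupancy is the fraction of the focal pack's fixes lying
inside both packs' 95% masks (each tested on its own grid). Note the two
directions of a dyad share geometry and are therefore correlated:
treating all 2×dyads directional values as independent observations
roughly doubles the nominal sample of any test run on them. The
mixed-model stage absorbs part of this through the focal-pack random
intercept; the null-calibration test avoids it by testing one direction
per dyad.

## Rank statistics

Mann–Whitney U is computed from midranks; U is reported for the first
group, T as the rank sum of the smaller group (first group on a size
tie). For n₁n₂ ≤ 20 the two-sided p is exact enumeration over all
C(n₁+n₂, n₁) labellings of the pooled midranks (so ties are handled
exactly); otherwise a tie-corrected normal approximation with continuity
correction is used. Kruskal–Wallis H carries the standard tie
correction, df = k−1, p from χ². All-pairs comparisons use Nemenyi-type
mean-rank statistics referred to the studentized range with infinite df
(equal-α, two-sided, no step-down refinement). All-identical inputs are
legal and return p = 1, not an error.

## Mixed models and multimodel inference

The response is directional 95% overlap (percent, modelled as Gaussian);
the focal pack is a random intercept. Fits are ML, not REML, because
AICc comparisons span different fixed structures; for a random-intercept
model the likelihood profiles analytically down to one dimension: given
λ = σ_b²/σ_e², each group's inverse covariance is I − (λ/(1+n_iλ))J, the
GLS solution and σ̂_e² = RSS/N are closed-form, and
−2logL = N log(2πσ̂_e²) + N + Σᵢ log(1+n_iλ). The profile is maximised
on {0} ∪ a log-spaced grid to λ = 10⁴ refined by bounded scalar search;
λ̂ = 0 fits are flagged as boundary (they equal OLS exactly). The fit
matches both the balanced-case closed form and statsmodels' MixedLM
(ML) to ~1e-7 in logLik.

The candidate set respects marginality: null; ratio; relatedness;
ratio + relatedness; both + interaction (5 models). Parameter count
k = fixed coefficients + 2 variance components; AICc = AIC +
2k(k+1)/(N−k−1), with an explicit error when N−k−1 ≤ 0. Model averaging
takes the smallest AICc-ranked prefix with cumulative weight > 0.95,
renormalises weights, and reports full (zero-substitution) averages with
unconditional SEs, Σ w_m·sqrt(se_m² + (β_m − β̄)²); conditional averages
and relative importances (renormalised weight mass of models containing
each term) are reported alongside. CIs use ±1.96·SE and p-values the
Wald z reference — a df-based reference would be slightly wider at
N = 40 but there is no principled df for averaged estimates. The
interaction surface is predicted over the observed pack-size-ratio range
only (a warning, not an error, outside it), with negative predictions
clamped in a separate reporting column.

## Problem sizes in tests

The default suite simulates at the sizes the analyses target: ~216-fix
packs for pipeline runs, ~2000-fix packs for estimator-convergence
checks, 50 replicate studies for the qualitative-pattern check, 200
replicate datasets for mixed-model recovery and selection-rate checks,
and 60 replicate null studies for type-I calibration. These sizes put
every Monte-Carlo estimate at least ~2 standard errors inside its
asserted bound; the full suite completes in a couple of minutes on one
core.

## Known limitations

* Fixed (non-adaptive) bandwidth only; no LSCV, plug-in refinements,
  local convex hulls or movement-bridge estimators.
* Smoothing inflation (above) biases areas and overlaps upward at field
  sample sizes; comparisons between groups are unaffected to first
  order because both groups inflate alike.
* Percent overlap is modelled as Gaussian for comparability with
  standard LME practice; a beta or fractional model would respect the
  [0, 100] support but is out of scope.
* The two directional observations per dyad are correlated; only the
  random intercept (not a dyad-level term) absorbs this in the model.
* Lon/lat ingestion uses a local equirectangular projection about the
  fix centroid — adequate below ~100 km extents, wrong for larger ones.
* Simulated packs never interact; relatedness-dependent tolerance is
  represented purely by centre spacing.
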