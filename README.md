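# packrange

Territory-overlap analysis for group-living territorial carnivores from
GPS telemetry. Given twice-daily fixes for a set of packs and a list of
neighbouring-pack pairs (dyads) labelled as related or unrelated, the
package estimates each pack's utilisation distribution (UD), extracts
50/75/95% isopleths, and quantifies how neighbours share space:

* **Directional kernel overlap** — the percentage of the focal pack's
  level-*p* kernel area covered by the neighbour's same-level kernel
  (two values per dyad: A onto B and B onto A).
* **Exclusive-kernel utilisation intensity** — the percent of a pack's
  fixes falling in each annulus (the 50% core, 75% minus 50%, 95% minus
  75%) divided by the annulus area, in % km⁻².
* **Overlap-zone occupancy** — the fraction of a pack's fixes inside the
  intersection of the two 95% kernels.
* **Rank-based comparisons** — Mann–Whitney U (exact enumeration for
  small samples, tie-corrected normal approximation otherwise),
  tie-corrected Kruskal–Wallis H, and Nemenyi-type all-pairs mean-rank
  comparisons.
* **Drivers of overlap** — random-intercept linear mixed models of
  percent overlap on relatedness, pack-size ratio and their interaction,
  fitted by profiled maximum likelihood, ranked by AICc, and combined by
  cumulative-weight model averaging with relative importances.

It is aimed at movement and spatial ecologists who want a scriptable,
tested version of this analysis chain, plus a synthetic-data generator
with closed-form oracles to validate every estimator.

## The model in brief

The UD estimator is the classic fixed-kernel density (Worton 1989): a
bivariate Gaussian product kernel with the reference bandwidth applied
per axis,

    h_i = s_i · n^(−1/6),

where `s_i` is the per-axis sample SD of the fixes. The level-*p*
isopleth is the smallest set of grid cells whose probability mass
reaches *p*; areas and intersections are computed on rasters so they are
mutually consistent.

The synthetic generator moves each pack as a stationary isotropic
Ornstein–Uhlenbeck (OU) process with centre μ, per-axis SD σ and
relaxation time τ, sampled on a twice-daily collar schedule with
Bernoulli dropouts. Its stationary UD is a circular bivariate normal,
giving closed forms used as test oracles:

    R(p) = σ · sqrt(−2 ln(1 − p))          (isopleth radius)
    overlap% = 100 · lens(R_a, R_b, d) / (π R_focal²)

with `lens` the circle–circle intersection area at centre distance `d`.

The inference model for directional 95% overlap y_ij (focal pack i,
observation j) is

    y_ij = β₀ + β₁·ratio_ij + β₂·related_ij + β₃·ratio·related + b_i + e_ij,
    b_i ~ N(0, σ_b²),  e_ij ~ N(0, σ_e²),

fitted by ML (so AICc is comparable across fixed structures) via a
profiled likelihood over λ = σ_b²/σ_e². The marginality-respecting
candidate set (null; ratio; relatedness; both; both + interaction) is
ranked by AICc with Akaike weights w_i = exp(−Δ_i/2)/Σexp(−Δ_j/2), and
the smallest top set with cumulative weight > 0.95 is averaged with zero
substitution and unconditional standard errors.

## Worked example

Run the built-in paper-like synthetic study (21 packs, 20 dyads — 12
related, 8 unrelated — twice-daily fixes over a four-month window):

```bash
packrange run --preset paper_like --seed 1 --outdir demo
packrange stats --overlap-table demo/overlap_long.csv
```

which prints

```
packs analysed: 21
overlap rows:   120
overlap95_related_vs_unrelated: p = 6.253e-07
occupancy95_related_vs_unrelated: p = 6.707e-07
intensity_by_kernel: p = 5.2e-12
outputs in demo

Mann-Whitney Rank Sum Test: U = 373; T = 147; P < 0.001
related: n = 24; mean = 36.46; median = 32.84; SD = 16.03; range: 13.78 - 83.14
unrelated: n = 16; mean = 9.19; median = 8.39; SD = 6.17; range: 0.62 - 21.62
```

Related dyads overlap far more at the 95% level than unrelated ones
(36.5% vs 9.2% of the focal kernel on average; the Mann–Whitney test on
the 40 directional values is highly significant), and the three kernel
classes differ strongly in utilisation intensity. The model table
(`demo/model_table.csv`) for the same run:

```
                                                      model  k       AICc     delta   weight
                              pack_size_ratio + relatedness  5 324.214242  0.000000 0.413659
                                                relatedness  4 324.640672  0.426430 0.334229
pack_size_ratio + relatedness + pack_size_ratio:relatedness  6 325.205325  0.991083 0.252018
                                                 Null model  3 341.550878 17.336636 0.000071
                                            pack_size_ratio  4 343.811201 19.596959 0.000023
```

Relatedness appears in every credible model (relative importance 1.0 in
`demo/averaged_effects.csv`, averaged effect ≈ +30 percentage points of
overlap), while pack-size ratio and the interaction carry little weight
— the synthetic study is generated with relatedness, not pack size,
controlling neighbour spacing.

Other outputs per run: per-pack UD rasters (ESRI ASCII) and isopleth
GeoJSON, `overlap_long.csv`, `occupancy.csv`, `intensity.csv`,
`stats_report.csv`, `tukey_intensity.csv`, `prediction_surface.csv`, and
a `manifest.json` with config hash, row counts and warnings.

The library mirrors the CLI: `simulate.make_fixtures` /
`generate_study`, `homerange.estimate_ud` / `extract_isopleths`,
`overlap.dyad_table`, `ranktests.mann_whitney`,
`mixedlm.RandomInterceptLM(...).fit()`, `mixedlm.dredge` /
`model_average`, and `pipeline.run_pipeline`.

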