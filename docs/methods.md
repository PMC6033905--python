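# Methods

## Problem setting

A fixed sun-photometer site records AOD with high temporal coverage;
a polar-orbiting satellite provides gridded AOD with high spatial
coverage but frequent gaps (clouds, snow, heavy haze misclassified as
cloud — a pollution-*dependent* missingness mechanism).  PM2.5 is
measured at a sparse monitor network.  The package (i) transfers the
site's temporal coverage onto the grid through per-cell regressions and
(ii) converts AOD to PM2.5 through a mixed-effects calibration, so that
regional PM2.5 can be mapped on days the satellite misses.

## Fusion model

For cell c and season s, the daily pairs (site AOD x_t, retrieved cell
AOD y_t) are fitted by ordinary least squares

    y_t = a(c,s) · x_t + b(c,s) + e_t,

with the Pearson correlation r(c,s) and pair count n(c,s) retained.
The regression direction is grid-on-site because missing *grid* values
are predicted *from* the site.  Fits are per season (MAM / JJA / SON /
DJF; December belongs to the winter labelled by its own year) because
the site–grid coupling varies with circulation regime.  On a day with a
site value, a missing cell is filled with max(a·x + b, 0) iff
r(c,s) ≥ r_threshold; retrieved values are never altered, and each cell
carries a provenance flag (retrieved / filled / missing).

Parameters that matter:

- `r_threshold` (default 0.5, dimensionless): the representativeness
  gate.  Signed r is used; anti-correlated cells never fill.
- `min_pairs` (default 10 per cell-season): fits on fewer pairs are
  statistically meaningless and are suppressed (the count is kept).
  The value is our choice; there is no canonical minimum.
- Pairing is daily: the site's all-day mean against the daily grid
  value.  An optional overpass time-window filter on the site records
  (off by default) supports stricter collocation.

## PM2.5 mixed model

    PM_ij = (α + u_j) + (β + v_j)·AOD_ij + s_i + ε_ij,
    (u_j, v_j) ~ N(0, Σ),  s_i ~ N(0, σ_s²),  ε_ij ~ N(0, σ²)

Day effects are crossed with site effects, so the model is not a nested
single-factor design; the fitter (src/aodfuse/mixedlm.py) maximises the
restricted likelihood directly.  Implementation: the marginal covariance
is written V = σ²(I + A Aᵀ) with A = Z W, where W is the relative
covariance factor (a 2×2 Cholesky block Λ per day, a scalar per site);
all quantities flow through the q×q capacitance matrix M = I + AᵀA
(q = 2·days + sites), σ² is profiled out analytically, and the free
elements of (Λ, g_s) are optimised by L-BFGS-B (numerical gradients)
followed by a Nelder-Mead polish, from a deterministic method-of-moments
start (per-day OLS spread for Σ, per-site residual means for σ_s²).
Fits are therefore reproducible bit-for-bit.  Variance components
reaching the boundary (~0) are reported with a warning message on the
fit object.  Standard errors of α, β come from σ̂²(XᵀV₀⁻¹X)⁻¹; BLUPs of
u, v, s from G Zᵀ V⁻¹ residuals.  The fitter agrees with R lme4
(`pm ~ aod + (1 + aod | day) + (1 | site)`) to at least four decimals on
test panels, and with statsmodels MixedLM on the day-only reduction;
with all components forced to zero it reduces exactly to pooled OLS.

Prediction on a training day uses that day's (u_j, v_j); site
intercepts apply only at cells hosting a known site (elsewhere the
population level, 0).  A day outside the training set must be requested
explicitly (`new_day=True`) and uses u = v = 0 with correspondingly
wider uncertainty.  Negative predictions are floored at 0 and counted.

Leave-one-site-out cross-validation refits the model without each site
in turn and predicts that site's records with the refitted day effects
and s_k = 0 (the prior mean of an unseen site's intercept — the
standard choice).  Record-level pooled metrics and per-site summaries
are both reported, since site-mean and daily-record correlations answer
different questions.

## Synthetic scenes

The generator emulates the statistical structure the method assumes,
with every parameter exposed and every draw seeded:

- Site AOD: log-normal, median 0.5, log-SD 0.6 (positive, right-skewed,
  SD ≈ 0.4 — typical of a polluted mid-latitude urban site).  No
  distribution is canonical here; this is a documented stand-in.
- Grid AOD at cell c: a(c)·site + b(c) + noise, floored at 0.  Defaults:
  a ∈ [0.9, 1.1] (mild west–east gradient), b ≈ 0.02–0.04, noise SD
  rising linearly from 0.05 at the site to 0.75 in the far corners, so
  the site–grid correlation decays from ≈0.99 to below the 0.5 gate —
  the spatial-representativeness pattern the fusion stage must respect.
- Missingness: each (day, cell) drops with `cloud_miss_prob` (0.4);
  surviving cells whose true AOD exceeds 1.0 drop with `haze_miss_prob`
  (0.6).  This reproduces winter-like ≈45–50 % total missingness with a
  pollution-dependent component; each missing cell records its cause
  (cloud | haze) so the mechanism is directly assertable.  Cloud
  dropout is spatially independent by design — no cloud-field
  autocorrelation is modelled, which is enough to test the method but
  not to emulate real cloud masks.
- PM2.5 at monitor cells: generated from the mixed model applied to the
  TRUE grid AOD (α = 30 µg m⁻³, β = 90 µg m⁻³ per AOD unit,
  Σ = diag(100, 400), σ_s² = 25, σ² = 100), so the value added by
  fusion is measurable against a known truth.  Negative draws are
  floored (rare at these parameters) and seasons are an explicit
  per-day label vector decoupled from the calendar, so small scenes can
  cover all four seasons.

## Numerical choices

- Grid cells are half-open `[edge, edge + cell_size)`; pixels on the
  max boundary are dropped, so cell assignment is a partition.
- Ångström interpolation is the exact two-point power law; two anchors
  admit exactly one, so no fitting choice arises.  Non-positive anchors
  are invalid records (skipped and counted).
- The error-envelope comparison `|Δ| ≤ 0.05 + 0.20·AOD` is inclusive at
  the boundary.
- Zero-variance regression strata and sub-`min_pairs` strata yield no
  fit (NaN) rather than an arbitrary number.
- Histogram comparison bins both samples on the shared range
  [0, max] with a 10 µg m⁻³ default width into percent frequencies.

## Problem sizes

Defaults were sized so every stage runs comfortably on one CPU: the
bundled scenes use a 10 × 10 cell 0.1° grid, 90–180 days and 8–25
monitors; the reproduction script (`scripts/acceptance.py`) uses 180
days.  All sizes are configuration, not constants.

## What passing tests do and do not show

Passing on synthetic scenes shows the pipeline's algebra and mechanics
are right: regressions equal the normal equations, filling respects
gating and provenance, the REML fitter recovers generating parameters
with calibrated uncertainty, and fusion demonstrably repairs the
pollution-dependent undersampling bias of regional means.  It does not
show that real site–grid relationships are linear, seasonally stable,
or as tight as the generator's; those are properties of real data.

Two known limitations deserve emphasis:

1. The generator has **no satellite retrieval error**: observed grid
   AOD equals true AOD wherever present.  Retrieved records are
   therefore *perfect* predictors of the generated PM2.5, while filled
   records carry the cell's regression noise.  As a consequence the
   fused panel's record-level cross-validation correlation sits at or
   below the satellite-only panel's in this synthetic regime, even
   though the fused regional mean is systematically closer to the
   truth.  With real data both datasets carry comparable AOD error
   (the ±0.05 ± 0.20·AOD envelope), and the fused dataset's extra
   coverage of polluted days is what improves CV skill; emulating that
   would require adding a retrieval-error model to the generator.
2. Day effects transfer to unmonitored cells exactly as estimated at
   the monitors; with very few monitors per day this extrapolation is
   optimistic relative to real networks.
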