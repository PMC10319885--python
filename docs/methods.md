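# Methods

This note records the models, conventions, and numerical choices behind
`ecospectra`, and what the synthetic benchmarks do and do not demonstrate.

## Flux record model and filtering

A site record is a strictly increasing, equally spaced half-hourly (or
hourly) series with start-of-interval timestamps in local standard time.
Sentinels (−9999; any value ≤ −9990 in a physically non-negative column,
since archives mix `-9999` and `-9999.0`) become NaN at parse time and no
other value is altered (the reader is round-trip exact, using
`float_precision="round_trip"`).

All filters are pure boolean masks with the thresholds held in
`FilterConfig` and echoed into the run manifest:

* quality: NEE quality flag ∈ {0, 1}; a missing flag excludes the record;
* growing season: a day is in season iff its daily mean GPP, smoothed with
  a 15-day centered moving average, strictly exceeds
  `min + 0.30·(max − min)` of the smoothed daily series.  The scope is per
  site-year by default (pooling is config-switchable) so inter-annual
  climate drift does not move the threshold; smoothing suppresses
  single-day dropouts.  When max = min the rule is vacuous and all days are
  retained rather than rejecting the site.  Both choices matter only in
  degenerate or noisy records;
* rain: any interval with P ≥ 0.1 mm and the following 48 h are excluded,
  windows unioned; if P is absent the filter is skipped with a prominent
  log line;
* turbulence: u* > 0.20 m s⁻¹, strictly;
* radiation: SWin > 100 W m⁻² (light-response stream), SWin < 50 W m⁻²
  (night-time respiration stream), SWin > 200 W m⁻² (energy stream),
  SWin_pot > 200 W m⁻² (water-use stream).  All inequalities are strict as
  stated.

Whether the growing-season mask also gates the energy/water streams is
switchable (`apply_growing_season_to_energy`, default on).

## Ecosystem functional properties

**GPPsat.**  The light response is the rectangular hyperbola
GPP = αQβ/(αQ+β) with photosynthetic photon flux density Q = 2.11·SWin —
the standard saturating form in the flux literature.  Windows span 5 days
with stride 1 day, the estimate assigned to the center day; a window needs
at least 20 day-filtered records (two-parameter fits on fewer points are
unstable).  Nonlinear least squares starts at α = 0.02,
β = max(GPP in window), bounded α ∈ (0, 0.5], β ∈ (0, 100];
non-convergence skips the window.  Window values above 60 µmol m⁻² s⁻¹ are
excluded (not clipped).  The site value is the mean over years of the
yearly 95th percentile.

**RECOmax** is the 90th percentile of retained night-time NEE over the
whole record.  Negative night-time NEE values are used as-is; their count
is logged.

**EF** is the median of LE/(LE+H); records with LE+H ≤ 0 are skipped, not
propagated as NaN.

**Gsmax.**  The aerodynamic conductance uses the Thom empirical form
G_a = (WS/u*² + 6.2·u*^−0.67)⁻¹.  Inverting the big-leaf Penman–Monteith
equation with available energy A ≈ H + LE gives
G_s = LE·γ·G_a / (Δ·A + ρc_p·G_a·VPD − LE·(Δ+γ)).  Psychrometrics: Magnus
saturation pressure e_s = 0.6108·exp(17.27·T/(T+237.3)) kPa,
Δ = 4098·e_s/(T+237.3)², λ = (2.501 − 0.00237·T)·10⁶ J kg⁻¹,
c_p = 1004.834 J kg⁻¹ K⁻¹, γ = c_p·P/(0.622·λ), air density from the
ideal-gas law; missing pressure is estimated from elevation with the
barometric formula.  Records with VPD ≤ 0, a non-positive denominator, or
G_s < 0 are screened out; LE = 0 maps to G_s = 0.  The inversion composed
with the forward model is the identity to 1e-6 relative (property-tested).
Gsmax is the 90th percentile of valid G_s.

**WUEt.**  Day-time records are aggregated to daily GPP (µmol m⁻², sum of
rate × interval length) and T (mm) totals; days with a good-quality
fraction ≤ 0.8 are dropped, and days whose GPP/T ratio exceeds the site
mean by 3 standard deviations are dropped (upper side only — the screen
targets implausibly high efficiency from near-zero T).  WUEt = ΣGPP/ΣT
with 1 mm water ≡ 55 508 mmol m⁻² (molar mass 18.015 g mol⁻¹).

**PNUE** = GPPsat/(wNarea·LAImax), with wNarea = (wNmass/100)·(wLMA·1000)
g N m⁻² (percent → fraction, mg mm⁻² → g m⁻²).

Percentiles interpolate linearly between order statistics throughout
(config-switchable), matching the convention of the original analysis
environment.

## Community-weighted means

Coverage is assessed on known abundances only, *before* the homogeneous
fill (the stricter and more literal reading of the 50% rule); a site needs
known cover ≥ 0.5.  Species with unknown abundance then share
(1 − known cover) equally.  Each trait's CWM renormalizes weights over the
species that have that trait — traits come from heterogeneous sources, so
availability differs per trait and renormalization is the only consistent
choice; it is logged per trait.  Leaf age classes are not modeled.

## Ordination

Variables are z-transformed (sample SD, ddof = 1); a constant column is an
error naming the variable.  The correlation matrix is eigendecomposed;
loadings are variable–component correlations (eigenvector · √λ),
contributions 100·loading²/λ (summing to 100 per component), explained
variance λ/p·100.  Component signs are oriented so each component's
largest-magnitude loading is positive; analyses that need a fixed
orientation re-anchor to a named variable.  Rank deficiency yields
flagged zero components rather than an error.

**Dimensionality.**  The retained-component count comes from a sequential
permutation test: for k = 1, 2, … the k-th eigenvalue of the observed
correlation matrix is compared with its null distribution over matrices
whose columns are permuted independently (999 permutations, α = 0.05,
deterministic under a fixed seed); testing stops at the first
non-significant dimension.  The per-dimension eigenvalue statistic was
chosen over an RV-goodness-of-fit statistic on sequentially deflated
residuals after simulation showed the latter badly over-retains when
residual columns are heteroscedastic (deflated residuals also lose rank
relative to their permuted counterparts, biasing the comparison): on
rank-1 factor matrices (n = 200, noise sd 0.05) the residual-RV scheme
retained 2–5 axes while the eigenvalue statistic retains exactly 1 in
20/20 seeded runs, retains 2 on rank-2 structure in 20/20, and keeps the
nominal 5% false-positive rate on i.i.d. noise.  The test is exact-level
by construction, so on pure noise it retains a spurious first axis in
about 5% of runs — that is its designed size, not a defect.

**Bootstrap.**  499 row-resamples at the original n, re-standardized and
re-decomposed per replicate.  Components are matched to the full-data
solution by eigenvalue rank, signs aligned by the dot product with the
full-data loading vectors; label switching beyond sign is not corrected
(replicates whose matched loading correlation falls below 0.5 are logged).
The standard error of every statistic (explained variances, loadings,
contributions) is the SD over replicates, with the replicate median also
reported.  Per-replicate substreams spawn from the master seed, so
increasing B never reshuffles earlier replicates; a replicate that draws a
constant column is redrawn and logged.  The dimensionality test runs once
on the full data, not per replicate.

When the two leading population eigenvalues are close, axis-rotation
uncertainty (∝ √(λ₁λ₂/n)/(λ₁−λ₂)) dominates loading SEs; this is a real
feature of the estimator, and the test suite's "tight replicate" checks
deliberately use a well-separated spectrum.

## Synthetic data

`simulate_site` builds a noise-free forward year first: a clipped-sinusoid
solar cycle from latitude and day-of-year (no ephemeris — no property
depends on astronomical accuracy), SWin as a fixed transmissivity times
the potential envelope, GPP from the hyperbola, Q10 respiration
(RECO = R_base·Q10^((T−15)/10); only percentiles of night NEE matter
downstream, Q10 is chosen for realism), NEE = RECO − GPP, VPD from a
relative-humidity cycle (guaranteeing forward/inverse Penman–Monteith
consistency), and either forward-PM energy partitioning at a prescribed
G_s or a fixed Bowen ratio.  Transpiration is a fixed fraction of ET so
WUEt has an analytic truth.  Ground truth is derived from the noise-free
series (analytically where possible: the hyperbola at Q = 2000 for GPPsat,
the prescribed conductance for Gsmax, the prescribed partitioning for EF);
then Gaussian noise, precipitation events, and QC-flag corruption are
layered on.  Defaults describe a productive temperate site: α = 0.05,
β = 40 µmol m⁻² s⁻¹, R_base = 2 µmol m⁻² s⁻¹, Q10 = 2, G_s = 12 mm s⁻¹,
flux noise sd 1.5 µmol m⁻² s⁻¹ (GPP) and 15 W m⁻² (LE, H), 10% poor-QC
records, 0.1 rain events per day.

What the generator does **not** emulate: real climatology and weather
autocorrelation, flux footprint variation, energy-balance closure gaps,
seasonal photosynthetic capacity dynamics, and u*-dependent nighttime flux
loss.  Passing recovery tests therefore demonstrates the *internal
consistency* of the estimators (each EFP recovers the quantity the forward
model encodes, under the pipeline's own filters), not their accuracy
against instrument error or structural mismatch in field data.

The latent-model generator draws X = F·Lᵀ + E with standard-normal factors
and Gaussian noise.  `leaf_economics_like_loadings` pairs the published
first-axis correlation pattern of the five-variable economics spectrum
with a weaker second axis (orthogonalized against the first; all variables
but wNmass share a sign) whose scale, together with an isotropic noise sd
of 0.5719, was solved so the population correlation PCA carries 59.2% of
the variance on the first component and 82.3% on the first two.  At
n = 90 a single draw scatters by several percentage points, so reported
summaries average 50 draws.  On such draws the permutation test typically
retains only the first component — the second axis (λ ≈ 1.15) sits at the
noise edge at this sample size.

## Known limitations

* GPPsat's 95th-percentile aggregation is upward-biased by window-fit noise
  when the true capacity is seasonally constant (~2–3% under default noise);
  with real seasonality the percentile instead tracks peak season.
* The u* threshold is fixed at 0.20 m s⁻¹; no change-point estimation.
* No energy-balance-closure correction and no alternative WUE metrics.
* No imputation of missing properties: the ordination is complete-case per
  hypothesis, so effective site counts differ between analyses.
* The dimensionality test's per-axis permutation null is approximate for
  k ≥ 2 (signal in earlier axes is not removed from the permuted data);
  in strong-signal regimes this is conservative rather than liberal.
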