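# Methods

## The question and the design

Monthly net ecosystem exchange (NEE) of a forest reflects both the current
environment and the legacy of past productivity and disturbance. The package
frames this as a model-comparison problem: a recurrent sequence model (LSTM)
that can carry state across months is pitted against ablations that destroy
specific parts of the temporal information — a static random forest and a
within-site permutation (no order at all), a mean-seasonal-cycle variant (no
interannual vegetation signal), and an annual-mean variant (no seasonal
vegetation signal). All models see the same eleven monthly predictors (seven
reflectance bands, four climate drivers) and are scored on held-out sites.
Because real flux-tower/satellite archives cannot ship with a package, every
experiment runs on a synthetic world in which the strength and horizon of the
memory are set by construction — so each qualitative claim ("the sequence
model wins", "the memory reaches about one year back") has ground truth.

## The synthetic world

Per site, monthly, over a configurable period (default 1982–2015):

- **Climate.** T_air and Rg are latitude-dependent sinusoids (southern
  hemisphere phase-shifted 6 months) plus AR(1) noise (defaults: sd 1.5 °C
  and 25 W m⁻², lag-1 correlation 0.7 — persistent anomalies on the scale of
  seasonal droughts). VPD is a fixed saturation-deficit fraction of the
  Magnus saturation pressure at T_air plus noise; precipitation is lognormal
  around a seasonal mean (positivity); rpot is the closed-form
  top-of-atmosphere radiation from latitude and mid-month day of year.
- **Vegetation.** Latent greenness G ∈ [0,1] has a PFT-dependent seasonal
  amplitude (deciduous 0.35 > mixed 0.25 > evergreen 0.08) plus AR(1)
  interannual variability (sd 0.04). A disturbed site (probability 0.25)
  loses half its greenness in one month and recovers exponentially
  (τ = 24 months). Bands are affine in G — NIR increasing, red/SWIR
  decreasing — plus sensor noise (sd 0.01), clipped to [0,1]; TIR is
  T_air + 273.15 K plus noise.
- **Carbon.** GPP = ε·Rg·G·f_T·f_W with a logistic temperature response
  (midpoint 10 °C) and an exponential VPD penalty. A single carbon pool
  C_t = (1−λ)C_{t−1} + γ·GPP_{t−1} (λ = 0.2, γ = 1, spun up at the mean
  influx) feeds respiration R_eco = r_b·e^{kT}·C (r_b = 0.07, k = 0.07 °C⁻¹,
  a Q10 near 2). NEE = R_eco − GPP + Gaussian noise (sd 0.3 gC m⁻² d⁻¹);
  negative NEE is net uptake. One pool, not several: a single decay rate
  gives one interpretable half-life (ln 2/−ln(1−λ) ≈ 3.1 months), which the
  altered-forcings plateau test needs.
- **Observation.** NEE exists only inside a site's measurement window
  (uniform 3–12-year spans within 2000–2015, so the ≥3-complete-year anomaly
  filter has bite), with per-month quality drawn from Beta(20, 1) (≈ 99 % of
  months clear the strict > 0.8 filter). Reflectance is masked at random
  (default 10 %/month, ×2.5 at tropical sites to mimic cloud climate); a
  MODIS-like auxiliary product (all seven channels, small noise, coverage
  from 2000) exists for gap-fill training, and withheld values are kept as
  ground truth. Random streams are split hierarchically
  (master → site → variable), so adding sites never perturbs existing ones.

What the generator does *not* emulate: sub-monthly dynamics, spatial
footprints, realistic EC error structure (heteroscedastic, gap-filling
artifacts), multi-pool soil carbon, species composition, or trends. Passing
tests therefore demonstrate that the pipeline detects and localizes memory
*when it is present in this form*, not that real forests behave this way.

## The sequence model

A single-layer LSTM (gates i, f, g, o; zero initial state) maps the
standardized predictor sequence to monthly NEE through a linear output
layer. Forward and backward passes are written directly in numpy — exact
analytic BPTT, verified against central finite differences to < 1e-5
relative error — and vectorized over ensemble members and sites via stacked
3-D matmuls, so an ensemble trains in one pass. Choices:

- **Masked loss.** MSE over observed months only; unobserved targets are
  zeroed before entering the residual, so they cannot influence loss or
  gradients even as NaN/garbage (asserted bit-for-bit in tests).
- **Standardization.** Predictors and target are z-scaled with statistics
  from the gradient-training sites only (target statistics from observed
  months only); learning rate 0.1 on raw flux scales diverges, and fitting
  the scaler on test folds would leak.
- **Optimization.** Full-batch Adam; an "iteration" is one pass over the
  training sites. 20 % of training sites (site-wise, whole sites) form the
  evaluation split; training stops after `patience` iterations without
  evaluation-loss improvement (default 500, so short-budget runs are bounded
  by `max_iterations`) and the best-iteration weights are returned.
- **Dropout** (0 or 0.5) acts on the hidden→output connection during
  training only, one mask per member per iteration.
- **Grid search** (lr ∈ {0.1, 0.01} × hidden ∈ {10, 20, 30} × dropout
  ∈ {0, 0.5}) selects by final evaluation loss, ties broken toward the
  smaller network; it runs per CV fold (nested) so the test fold stays
  untouched. In practice larger hidden sizes often edge out smaller ones
  even on purely instantaneous tasks, so no "parsimony wins" behavior should
  be assumed.
- **Ensembles** differ only in weight-initialization seed (default 50
  members; the test/benchmark profile uses 5). Metrics are reported as the
  mean ± sd of per-member metrics; metrics of the ensemble-mean prediction
  are emitted alongside.

The static baseline is a scikit-learn random forest on the identical
(predictor, target) rows from observed months, with rows canonically sorted
before fitting so predictions are invariant to collection order.

## Experiments

- **Entire-site cross-validation** (default K = 10; benchmark runs use
  K = 3): whole sites per fold, balanced to ±1; per fold the standardizer,
  hyperparameters and ensemble are fit on K−1 folds and predictions made for
  the held-out fold. Provenance logs record the exact train/test site sets.
- **Factorial set-ups.** MSC and annual-mean transforms touch only the seven
  band columns (climate stays byte-identical); the permutation shuffles
  (X row, y, mask) jointly within each site, preserving every instantaneous
  pair; the permutation is within-site because sequences are per-site
  constructs. The MSC of a series is its per-calendar-month mean over all
  panel years.
- **Altered forcings.** For target year i and horizon n, predictors in years
  i−1…i−n are replaced by their MSC (bands, climate, or both); years before
  i−n and year i keep actual values; the site's own test-fold ensemble
  predicts, and only year i is read off. Target years whose altered span
  precedes the panel are skipped. Calendar years are replaced whole;
  deviations are aggregated per month (southern-hemisphere months shifted by
  6) and per forest group.

## Evaluation

Four scales from one prediction table: raw monthly pairs ("seasonal cycle"
— the monthly series itself, not the 12-point climatology); seasonal
anomalies (value minus the site's calendar-month mean, observations and
predictions each centered on their own means, mirroring the residual-curve
formula); across-site (one mean pair per site over common observed months);
interannual anomalies (site-year mean minus the site's mean of annual means,
complete — all-12-months-observed — years only, sites with ≥ 3 such years).
Strata (PFT, climate class, age class) with no eligible site report NA, never
zero. NSE is undefined for zero-variance observations and errors out rather
than returning a sentinel.

## Numerical and degenerate-input policy

Seeded determinism end to end: every stage's randomness derives from one
master seed through `numpy` SeedSequences; identical configs reproduce
metric JSON to 1e-10 across runs. Family selection in climate down-scaling
breaks ties by fixed family order, so listing order is irrelevant; a
down-scaled series whose best NSE is below 0.1 is flagged low-skill (NSE
near zero is indistinguishable from predicting the mean). Gap-filling never
overwrites observed values and provenance flags partition every cell into
observed/stage-1/stage-2. Degenerate requests fail loudly: zero sites,
periods under 5 years, λ = 0 without explicitly requesting an
infinite-memory pool, all-false loss masks, zero-variance NSE denominators,
more folds than sites, bands with no observed months at stage 2.

## Benchmark problem sizes

The heavy properties (memory detection, MSC ablation, altered-forcings
plateau) run on a 40-site, 1996–2015 benchmark with 3-fold entire-site CV,
ensembles of 5, fixed hyperparameters (hidden 10, lr 0.01, dropout 0) and
150 Adam iterations — the point where held-out skill has stabilized on this
fixture — repeated over 5 master seeds for the ordering claims. The
`ci`/`desk`/`full` profiles in `fluxmem.interface` scale sites, folds,
ensemble size and grid breadth up to the full 185-site / 50-member / K = 10
configuration (hours of compute).

## The vegetation-variability control

The MSC-ablation control ("no interannual vegetation variability") zeroes
disturbances, greenness noise, band sensor noise *and* air-temperature
noise. The last is deliberate: the thermal band is temperature-coupled, so
with T_air noise on, MSC-replacing the bands removes genuine *climate*
information through the thermal channel and the control no longer isolates
vegetation memory. With all four off, the bands are exactly periodic, the
MSC transform is an exact no-op, and the two variants must agree to within
ensemble spread — while radiation, VPD and precipitation noise keep the
interannual prediction task itself nontrivial.

## Known limitations

- Memory in the generator lives in one respiration pool; models are not
  tested against multi-timescale or threshold legacies.
- The LSTM is single-layer, CPU, full-batch; no attention/bidirectional
  variants, by design.
- The permutation ablation is the simplest order-destroying null (order destroyed,
  instantaneous pairs kept); block-bootstrap or phase-randomized nulls are
  out of scope.
- Anomaly-scale NSEs on 40-site fixtures carry substantial seed-to-seed
  variance; ordering claims are therefore made over repeated master seeds,
  not single runs.
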