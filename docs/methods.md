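# Methods

This note records the modelling assumptions, parameter choices and numerical
conventions behind `plumbsdm`, and what the synthetic-data tests do and do
not establish.

## Temporal Fourier components

Per-pixel series are summarised by the harmonic model
`y(t) = A0 + Σ_{k=1..3} A_k cos(2πk t/L − 2πk P_k/L)` with `L` samples per
year. Choices that matter:

- **Least squares, not FFT.** Coefficients come from an ordinary
  least-squares fit on the available samples. On complete, regularly
  sampled whole-period series this equals the DFT result; unlike an FFT it
  remains exact when composites are missing or sampling is irregular.
  Pixels missing some composites are refit individually on their available
  samples; a pixel needs at least 7 non-missing samples (the model has 7
  free parameters) or it propagates nodata.
- **Phase convention.** `P_k` is the time of the cycle-k peak in timestep
  units, reduced to one period of that cycle (`[0, L/k)`). Phases are
  circular: a value of `L − ε` is the same phase as 0, and tests compare
  them on the circle. Radians are available via `phase_units="radians"`.
  The phase of a cycle with (numerically) zero amplitude is undefined.
- **Variance convention.** `VR` is the population (divide-by-n) variance of
  the *observed* series. This makes `D1 = A1²/(2·VR) = 1` exact for a pure
  annual cosine sampled over whole periods. `D_k` are defined as 0 when
  `VR = 0` (a constant series), so a constant pixel yields a valid
  component set rather than NaNs.
- **MN/MX** are the observed series extremes, not the fitted curve's.

## Synthetic landscape and survey (the stated world)

The generator emulates a 1-km gridded landscape observed monthly for two
years, and a cross-sectional survey in which each trap runs exactly once
for one week.

- **Seasonal signals** (NDVI, EVI, day/night LST, MIR, precipitation) are
  per-pixel smooth mean fields plus annual (optionally bi-annual) harmonics
  with smoothly varying amplitude and phase, plus iid Gaussian noise
  (default sd 0.05 in each signal's units). Parameter ranges are set to
  plausible NW-European values (e.g. NDVI mean 0.3–0.7 with annual
  amplitude up to 0.25 peaking in mid-summer; precipitation peaking in
  winter). Static layers are a smoothed-random-field DEM (0–300 m), a
  log-scaled population density, and a three-stratum land cover (15% urban,
  50% rural-agricultural, 35% natural — a lowland agricultural mix).
- **Truth surfaces.** Suitability is the inverse logit of a linear
  combination of grid-standardised covariate layers; the default
  coefficients put positive weight on vegetation seasonality (NDVI_A1) and
  mean precipitation and negative weight on elevation and day temperature,
  mirroring the predictor families a tree-hole-breeding mosquito's survey
  would flag. Expected abundance is `m ×` suitability with `m = 15` by
  default (catches rarely exceed ~10 per trap-week; the non-outlier maximum
  sits in the tens).
- **Survey.** Traps are allocated 40/40/20 across urban/rural/natural
  strata by largest-remainder rounding (deterministic, sums exactly),
  sampled without replacement within strata, and given one uniform ISO week
  in April–October (weeks 14–44). Counts are negative binomial with mean
  `expected_abundance × seasonal weight` and dispersion 0.8 — heavy-tailed
  enough that isolated extreme catches (the reason for the outlier rule)
  actually occur; `dispersion=inf` gives the Poisson limit. The seasonal
  weight is a Gaussian bump over week peaking in mid-July (week 29, sd 5
  weeks), so expected counts peak inside June–September. One global seed
  expands into per-stage substreams (locations / weeks / counts), so each
  stage is separately reproducible.
- **Not emulated:** spatial autocorrelation of counts beyond what the
  smooth suitability surface induces, trap failure or loss (every trap
  returns a record), observer or identification error, multi-species
  interference, real geography or CRS handling. A green recovery test
  therefore establishes that the pipeline recovers a known smooth
  suitability field from a stratified one-visit survey — not that it would
  do as well against ecological confounding absent from this world.

## Occurrence model

- **Balancing** keeps every minority-class record and subsamples the
  majority class without replacement; only records with complete covariates
  participate. Records with incomplete (nodata) covariates are excluded
  from modelling with a logged count.
- **Forest.** 500 trees by default, `mtry = ⌊√p⌋` for classification and
  `p/3` for regression, grown on bootstrap resamples of the balanced set.
  The tree inducer is scikit-learn CART; the bootstrap, out-of-bag
  book-keeping and vote aggregation are implemented here so the evaluation
  is explicit. Suitability is the exact fraction of trees voting presence.
- **Out-of-bag metrics.** Sensitivity and specificity are computed for each
  tree on its out-of-bag records and then averaged across trees (the
  default); a pooled mode thresholds the per-record OOB vote fraction at
  the vote threshold (default 0.5) instead. The per-tree average is
  systematically more pessimistic than the pooled vote because single trees
  are weak; both are exposed. OOB AUC is always rank-based on the pooled
  vote fractions. Under label permutation the OOB AUC is approximately
  centred on 0.5 with a mild downward bias typical of OOB estimates, which
  is why the chance-band check uses the median over a seed family.
- **Importance** is the unnormalised Gini impurity decrease per covariate
  averaged over trees (per-sample scale; the ranking is what is
  interpreted).
- **GLM comparator.** A binomial GLM on the same covariates; its
  sensitivity/specificity/AUC come from out-of-fold (5-fold) predicted
  probabilities so forest (OOB) and GLM (CV) are both scored on data unseen
  by the fit. Quasi-perfect separation is detected from saturated fitted
  probabilities and flagged; coefficients are still reported.

## Abundance model

- Records are filtered to the peak months, June–September by default. The
  month of a trap-week is the month of the ISO week's Thursday (the ISO
  anchor day), which resolves weeks straddling a month boundary
  deterministically.
- **Outlier rule.** The field practice of discarding a single absurd catch
  by judgment is formalised as a relative gap: counts greater than
  `k ×` the second-largest count (default `k = 10`) are excluded, listed
  and logged — never silently dropped. With counts {…, 62, 1701}, 1701 is
  excluded and 62 retained.
- The response is `log10(count + 1)`; MSE is reported on this transformed
  scale (in-sample and out-of-bag separately), and back-transformed
  predictions `10^ŷ − 1` are floored at zero. Both scales are returned
  because the "expected maximum per trap" reading lives on the count scale.
- The predicted suitability of the occurrence model enters as an additional
  covariate (the chained design). On worlds where abundance is proportional
  to suitability, the chained model's OOB MSE is lower than the unchained
  model's and suitability ranks first in node-purity importance — both are
  regression-tested.

## Validation and maps

- **Presence-only error** is the fraction of independent presence points
  whose pixel suitability falls below a threshold (default 0.5 — recorded
  in the report, since the choice is not canonical). Points sharing a pixel
  count individually by default; a unique-pixel mode exists. The error rate
  is monotone non-decreasing in the threshold.
- **Confusion metrics** report undefined denominators as not-available
  rather than 0.
- **Maps** are produced by applying the fitted model to every complete
  pixel of the covariate stack; suitability is clamped to [0, 1], nodata
  propagates, and map pixels equal the tabular prediction on the same
  covariate vector exactly (no resampling). Output rasters are ESRI ASCII
  grids — plain text, readable by any GIS; GeoTIFF is not produced because
  no GeoTIFF library is part of the supported environment.

## Benchmarks behind the acceptance suite

The pipeline-recovery suite runs 10 simulated surveys (seeds 0–9, 300
traps, 40×40 grid — reduced from the 60×60 default to keep runtime in
seconds) with generating coefficients scaled ×3 ("strong signal") and
abundance scale 50. It checks medians over the seed family: held-out
Spearman correlation between predicted and true suitability ≥ 0.6
(measured ≈ 0.86), OOB AUC > 0.9 on a separable benchmark where presence is
a deterministic function of true suitability (measured ≈ 0.97), OOB AUC in
[0.4, 0.6] under permuted labels (measured ≈ 0.46), and chained OOB MSE no
greater than unchained (holds at every seed). Medians are used because
single-seed OOB statistics have sampling noise comparable to the band
widths.

## Known limitations

- No spatial autocorrelation correction and no collinearity pruning of the
  (deliberately redundant) 87-layer covariate set.
- The negative-binomial count model is stationary within a week; no
  zero-inflation or temporal forecasting.
- Categorical land cover enters the forests as a numeric code; with three
  ordered-by-construction strata this is harmless here, but a richer
  legend would warrant one-hot encoding.
- Model files are joblib pickles with a versioned envelope; they are
  runtime artifacts, not an archival format.
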