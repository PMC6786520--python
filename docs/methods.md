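# Methods

## The estimation problem

Large-scale mosquito surveillance yields presence records but almost
never proof of absence: failing to find a species says little where no
one looked. Habitat-suitability models for *Aedes aegypti* and
*Ae. albopictus* therefore disagree substantially at range margins, and
their published accuracy is hard to compare. This package implements a
procedure that (1) constructs defensible pseudo-absence labels from
detection-effort side information, (2) scores each candidate model's
binary county calls on those labels, (3) fuses the calls into a single
probability using each model's predictive values as weights, and (4)
calibrates and stress-tests that probability.

## Pseudo-absence labeling

A county is labeled pseudo-absent for species A iff (i) A was never
reported there, (ii) the county conducts mosquito surveillance or has
reported the co-surveyed species B (so detection of A was plausible),
and (iii) its centroid is at least `buffer_km` from the nearest centroid
of a county with an A report. The buffer (default 100 km, the typical
centroid-to-neighbor spacing of U.S. counties) removes counties likely
to share habitat with a presence county; counties strictly inside it
stay unlabeled rather than becoming absences. Distances are
centroid-to-centroid great-circle (haversine, Earth radius 6371 km);
county polygons are deliberately not used. "At least" is taken
literally: a candidate exactly on the radius qualifies. `buffer_km=0`
gives the unbuffered variant for sensitivity analysis.

Labeled counties are split 80/20 train/test, stratified by class, with
round-half-up of `fraction·n` per class (291 presences → 233 train / 58
test). Splitting uses its own RNG seeded from the pipeline seed.

## Dichotomization of continuous models

For a continuous model, every cutoff c on a 0.01-step grid over [0, 1]
is evaluated on the training labels with calls `score ≥ c`; the smallest
c on the plateau maximizing sensitivity + specificity is kept (a 1e-12
slack absorbs float non-associativity; true objective gaps are at least
1/(P·N)). Maximizing the sum is equivalent to maximizing the average of
the two. Tie-breaking toward the smallest cutoff favors sensitivity at
range margins and makes the search deterministic. Binary input models
pass through untouched. Scores outside [0, 1] are clamped with a
warning. Raster inputs are reduced to counties by taking the grid cell
whose center is nearest each county centroid (ties to the lower cell
index; centroids outside the grid extent become missing values and are
excluded from metrics, with a warning).

## Accuracy-weighted ensemble

Let model m have in-sample (training) predictive values PPVₘ and NPVₘ.
Each county contributes PPVₘ for a presence call and 1 − NPVₘ for an
absence call — in both cases an estimate of P(county truly present |
model's call) — and the raw ensemble score is the unweighted mean over
models with non-missing calls. Models with an undefined PPV or NPV
(zero positive or negative calls on the training set) are excluded with
a warning. The raw score is therefore bounded by
[minₘ(1 − NPVₘ), maxₘ PPVₘ] and invariant to model order.

## Calibration

The raw score is mapped to a probability by a binomial GAM: logit link,
penalized cubic B-spline basis of dimension 10 on the raw score. The
penalty weight is selected from a log-spaced grid (10⁻⁴…10⁴) by AIC,
with effective degrees of freedom computed from the converged
penalized-IRLS normal equations, edf = tr[(XᵀWX + S)⁺ XᵀWX]; the
implementation does not rely on the fitting library's hat-matrix trace,
which proved numerically unstable when the raw score takes few distinct
values (K binary models yield at most 2ᴷ distinct scores). AIC is
−2ℓ + 2·edf with the unpenalized binomial log-likelihood ℓ.

Degenerate cases: a constant raw score falls back to the empirical class
rate; if every spline fit is rejected (non-finite coefficients, e.g.
perfect separation), a plain logistic regression on the raw score is
used instead, with a warning either way. Predictions are clamped to
[0, 1], and raw scores outside the training range are predicted at the
boundary value of the fitted map (constant extension) to avoid spline
extrapolation. Fitted ensembles serialize to JSON as the weight table
plus a dense 2001-point lookup of the calibration curve, which reloads
to within 1e-6 of the original predictions.

On simulated data the procedure lands at roughly 4–5.5 edf, and when the
raw score is fed the true generating probability, the fitted map is
within 0.05 of the identity on [0.05, 0.95] at n = 3000 (tested, with an
independent mgcv cross-check of the calibration curve).

## Evaluation

- **Reliability**: predictions binned into deciles [0, 0.1), …,
  [0.9, 1.0] (left-closed, right-open, last bin closed, so p = 1 falls
  in the top bin); per non-empty bin, the observed presence fraction
  with an exact two-sided 95% Clopper–Pearson interval. Empty bins are
  reported with n = 0 and undefined intervals.
- **Uncertainty**: H = −p log₂p − (1 − p) log₂(1 − p) per county, with
  0·log 0 := 0; H = 1 marks maximal disagreement among
  similarly-accurate models, H = 0 a confident consensus.
- **Residuals**: E = x − p on labeled counties only (x = 1 presence,
  x = 0 pseudo-absence); |E| near 1 flags systematic bias.
- **Model comparison**: the ensemble dichotomized at p ≥ 0.5 against
  every base model on the test set; confusion metrics are computed over
  labeled counties only, denominator-zero metrics reported as undefined
  (never silent zeros), rows sorted by accuracy with alphabetical
  tie-break.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
not mosquito biology. Per species, a latent field is kernel-smoothed
white noise on the county lattice (Gaussian filter with σ =
`smoothness` cells, an inexpensive surrogate for a Gaussian process with
comparable correlation length), standardized and pushed through
expit(b + 2z); the intercept b is root-found (Brent, tolerance 1e-6) so
the mean presence probability matches `mean_prevalence`. Occupancy is
Bernoulli per county; the two species' fields are independent unless
`species_correlation` is set (the labeling rule exploits
co-surveillance, not co-occurrence, so independence is the neutral
default). A county's *observed* presence requires occupancy,
surveillance (Bernoulli at `surveillance_fraction`), and detection
(Bernoulli at `detection_prob`). Base models call each county from its
*true* occupancy with designed sensitivity/specificity.

Default study conditions: a 50×60 lattice (3,000 counties, ~1° cells),
smoothness 3 cells, prevalence 0.3, surveillance fraction 0.6,
detection probability 0.9, and five base models with
(sens, spec) ∈ {(.85,.80), (.75,.90), (.90,.70), (.65,.95), (.80,.85)} —
ranges comparable to published suitability models for these species.
These sizes keep the full validation suite and the acceptance script in
the seconds-to-minutes range while leaving binomial sampling error well
below the tolerances being checked.

All randomness flows from one master seed; each component draws from a
stream spawned as `SeedSequence((seed, offset))` with fixed offsets
(fields 0–1, occupancy 2, surveillance 3, detection 4, model j for
species s at 100 + 2j + s), so reruns are byte-identical and adding a
component does not perturb the others.

What passing synthetic tests does **not** show: real occurrence records
have temporally heterogeneous effort, spatially clustered surveillance,
misidentification, and base models whose errors correlate through shared
climate inputs — none of which the generator reproduces. Results on
synthetic data validate the machinery and its statistical contracts, not
the ecological accuracy of any real-world map.

## Known limitations

- Grid ingestion accepts in-memory lon/lat arrays (or CSV county
  tables); there is no GeoTIFF reader.
- Base-model errors are simulated independently across models; the
  ensemble's measured advantage will shrink when real models share
  inputs.
- The calibration smooth is not constrained to be monotone; with
  well-separated training data the fitted map is monotone in practice
  (tested), but small non-monotonicities can occur and are reported
  rather than corrected.
- Counties with partial model coverage are averaged over available
  models rather than dropped; with very few covering models the raw
  score is noisy.
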