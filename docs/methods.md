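# Methods

This note documents the statistical models, the synthetic data-generating
process, the numerical choices, and the limitations of `trawlkit`.

## The hurdle (delta-GLM) index

Trawl CPUE for epipelagic forage taxa is zero-inflated and lognormal-tailed,
and survey effort is not balanced across space or years. The index model is
the standard two-part decomposition used for fishery-independent survey
standardization:

- occurrence: `present ~ C(year) + spatial terms`, binomial GLM with logit
  link, fitted to all hauls;
- magnitude: `log(cpue) ~ C(year) + spatial terms`, normal linear model
  fitted only to hauls with positive catch.

Year is always a fixed effect in both submodels. Candidate spatial terms
(none; depth stratum; region; region + depth; region × depth; optionally
Julian-day bins of 10 days for strongly seasonal taxa such as young-of-year
rockfish) are scored by AIC independently per submodel; the minimum-AIC set
is selected, ties broken toward the smaller set. The per-submodel AIC table
is retained so selection can be audited against brute-force enumeration.

**Back-transform and standardization.** The annual index multiplies the
back-transformed year terms, `x_y = p̂_y · m̂_y`. Because year never
interacts with other covariates, each submodel's prediction for year y is
the year coefficient added to a year-free linear predictor; both are
averaged over the pooled haul-level covariate distribution (effort
weighting). This makes the series invariant to covariate coding and
reduces, for a year-only model, to the closed form (proportion positive) ×
exp(mean log positive catch). No lognormal mean correction exp(σ²/2) is
applied by default: under homoscedastic σ it is a constant multiplier that
cancels in a relative index (available via `bias_correct=True`).

**Reporting scales.** `point_index` (arithmetic), `log_index = log(x+1)`,
`se_log` (SD of log-scale resampling draws, excluding zero draws and not
adding 1), 95% intervals from draw percentiles on the arithmetic scale, and
z-scores of the log index over a configurable baseline (default: all years).
Years with no positive catches are pinned at 0 and flagged `low_info`;
they are excluded from se_log summaries.

**Uncertainty.** Two interchangeable engines:

- *bootstrap* (default): year-stratified nonparametric resampling of hauls
  with refitting of the selected submodels; resamples that lose all
  positives of a year are dropped and counted, with an error above 20%.
- *posterior*: a normal (Laplace) approximation to a Bayesian fit with
  weakly informative priors. The binomial submodel uses a MAP estimate
  under normal(0, 2.5²) coefficient priors (10² on the intercept) with the
  Laplace covariance; the positive submodel uses the asymptotic MVN of its
  OLS coefficients. The prior matters: under quasi-separation (e.g. a year
  with all 15 hauls positive) the plain MLE covariance diverges and
  coefficient draws send p̂ → 0, producing absurd log-scale SEs; the prior
  keeps the posterior proper, which is exactly why regularizing priors are
  the default in applied Bayesian GLM software. Point estimates remain pure
  MLE. Residual-variance uncertainty of the positive model is ignored in
  the draws (second-order at the sample sizes involved).

Empirically (see `tests/test_acceptance.py` and `scripts/acceptance.py`)
the posterior intervals attain ~93–95% coverage of true year effects over
200 simulated datasets at 40 hauls/year.

## Effort-reduction machinery

`subset_focal_year` reduces one year to at most one haul per subset station
— the temporally last haul, resolved by (julian_day, haul_id) order since
"last" needs a tie rule. The operation is deterministic and idempotent, and
all other years are untouched. Relative bias is `(x_sub − x_all)/x_all` on
arithmetic-scale point estimates for the model-based index and on the
mean-log(CPUE+1) scale for the naive estimator (whose point estimate *is*
that mean); a `log_scale` flag switches both to log(x+1). Cells with
`x_all = 0` are undefined and dropped from summaries with a logged count.
Boxplot summaries report median, quartiles, and 1.5×IQR whiskers per
taxon × estimator.

Precision extrapolation uses SE(n) = (se_obs·√n_obs)/√n, exactly
interpolating the observed SE and halving when n quadruples. The
random-exclusion experiment validates it: keep n focal-year hauls (purely
at random, or whole randomly-ordered nights trimmed to n — the survey works
station-by-station through nights of ~3 trawls), refit, and record the
focal-year se_log from the posterior engine. On the default scenario the
log–log slope of mean SE versus n is −0.5 within ±0.05 and the two
exclusion modes agree within Monte-Carlo error.

## Diet-index calibration

Ordinary least squares with the log abundance index as response and the
mean chick-diet proportion as predictor. This direction makes prediction of
an index from a new diet observation direct rather than inverse-regression;
under joint normality of (proportion, log index) the OLS prediction
interval is calibrated for a new pair regardless of which variable is
causally upstream. Proportions enter untransformed (a logit option exists
but linear fits are the default). Requirements: ≥10 paired years,
non-constant proportions; the pairing window is configurable (e.g. a later
start for prey whose early counts were not standardized). Reported:
slope, intercept, residual SE, r², two-sided slope p, plus a
permutation p-value (|r| under year reshuffling) as a distribution-free
check. Prediction returns a 95% prediction interval by default (residual +
coefficient uncertainty) and flags extrapolation outside the training range
of proportions. Agreement between a diet-based prediction and a trawl-based
interval estimate is reported as signed discrepancy, interval overlap, and
mutual containment of each point in the other's interval.

## Krill SDM

Gradient-boosted regression trees on ln(CPUE+1) with conventional
settings — learning rate 0.01, interaction depth 3, bag fraction 0.5 — and
the tree count selected by 5-fold cross-validation *blocked by year*: whole
years are held out, because the model's use case is predicting years
outside the training set, and row-wise folds would leak interannual signal
through the dynamic covariates. The staged held-out MSE curve is retained;
the CV score is its minimum. Permutation importances are computed on the
training data. Predictions are floored at 0 on the ln(CPUE+1) scale
(negative values are uninterpretable; flooring is logged). The climatology
is the per-cell mean of floored predictions over the baseline years, so
anomalies sum exactly to zero over the baseline by construction. Maps are
masked to 150 km from shore (config constant). The station-mean series
averages predictions over the training-station cells per year; its
comparison with the delta-GLM index standardizes both series over the
overlapping years and reports Pearson r, p, and years where the two
standardized series disagree in sign. Patchiness diagnostics compare
per-year CVs across stations (arithmetic CPUE scale) and residuals
(ln-scale): a smooth covariate-driven surface cannot reproduce swarm-scale
patchiness, so its CV is systematically lower than the observed CV.

## Synthetic data generator

The generator's defaults are the study conditions, not tuning knobs:

- **Design**: 35 core stations (the true core-area station count is not a
  published value; ~35 is a realistic core-grid size) allocated
  50/30/20% to shelf/slope/deep strata with stratum-typical bottom depths
  and shore distances, spread over three alongshore regions. The 15
  shallowest stations form the reduced-year subset, so the degraded year is
  inshore-biased by construction.
- **Effort**: 31 years (1990–2020 analogue), 62 hauls/year within a May–June
  season window (days 121–180), grouped ~3 hauls per night; the final year
  has exactly one haul at each flagged station, later in the season
  (days 160–177), mirroring a delayed, curtailed survey.
- **Catches**: per taxon and haul, Bernoulli(occurrence) ×
  LogNormal(λ_y + covariate effects, σ_log), rounded to integer counts;
  a haul rounded to zero is a zero in the hurdle sense, keeping the
  generative model essentially the estimator's model while producing
  integer CPUE. Depth association shifts both the occurrence logit and the
  positive log mean by ±1 unit between shelf and deep. Default taxa span
  the association spectrum: nearshore (+1.2, anchovy-like), offshore
  (−1.2, hake-like), neutral (sanddab-like), and a mildly nearshore
  seasonal taxon (rockfish-like, −0.02/day). σ_log = 0.7 and occurrence
  intercept ≈ 1.4 (≈80% positive) are typical of well-sampled forage taxa;
  year effects are iid normal(3.0, 0.7) on the log scale. An optional
  station-level lognormal "swarm" factor (`patchiness_cv`) adds
  krill-style patchiness.
- **Diet**: proportion_y = clamp₀₁(a + b·log index_y + noise). With the
  default slope 0.12 and noise SD 0.05, calibration fits on 30-year series
  give r² ≈ 0.6–0.8, the regime reported for real murre-diet calibrations.
- **Krill world**: a 16×8 coastal grid (cross-shore spacing 11 km, to
  170 km), depth a smooth function of distance; two dynamic covariates
  (winter preconditioning, spring ocean state) varying by year (iid N(0,1),
  pinnable per year for scenario construction) with a mild alongshore
  gradient. Species truth is a Gaussian dome over distance to shore
  (neritic: peak 15 km; offshore: peak 75 km) plus linear covariate
  responses, floored at 0; station samples multiply the truth CPUE by
  mean-1 lognormal patchiness noise (SD 0.6). Interannual variability
  enters *through the covariates*, so a covariate-driven model can track
  it — which is the property the consensus check exercises.

**What the generator does not emulate**: real oceanography (heatwaves,
ENSO), multi-species interactions, within-season movement, vessel or gear
effects, observation error in diet identification, and spatial
autocorrelation beyond the stratum/dome structure. Passing tests therefore
demonstrate that the estimators recover the structure they assume, with
correctly calibrated uncertainty, at realistic effort and noise levels —
not that any particular real-world index is correct.

## Numerical choices and degenerate inputs

- AIC ties break toward the smaller covariate set; candidate sets that fail
  to fit score +∞.
- All-positive data degenerate the binomial submodel to p̂ ≡ 1; all-zero
  years pin the index at 0 (`low_info`); fewer than 2 years or 2 positive
  hauls is an error.
- Submodels are fit on design matrices built from the *full* haul table, so
  factor levels are shared; a level absent from the positive subset yields
  an all-zero column handled by pinv/least-squares.
- MVN coefficient draws use SVD factorization (covariances can be
  numerically semidefinite).
- Boosted-tree determinism: fixed `random_state`; predictions are invariant
  to strictly monotone rescaling of a covariate (tree-split property),
  which the suite checks.
- Experiment problem sizes (30 focal years × 4 taxa for the bias study;
  25 reps × 5 sample sizes × 2 modes for the exclusion study; 200–300
  replicates for coverage/recovery studies) were chosen to keep Monte-Carlo
  error comfortably below the effect sizes being measured while running in
  minutes on a single CPU.

## Known limitations

- The posterior engine is a Laplace approximation, not MCMC; for very small
  positive-catch counts its intervals can deviate from exact posterior
  quantiles (the bootstrap engine is the cross-check).
- Effort standardization assumes year does not interact with spatial
  covariates; candidate sets with year interactions are deliberately not
  offered.
- The SDM cannot attribute effects between strongly collinear covariates
  (depth and distance to shore are nearly aliased on a coastal grid);
  partial-dependence profiles should be read accordingly.
- The naive index and the hurdle index answer slightly different questions
  (mean log(x+1) vs p·geometric-mean); their relative biases are compared
  each on its own scale.
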