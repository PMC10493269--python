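# Methods

## Model and procedure

The outcome is the WEMWBS total score `y` (14 items scored 1–5, summed;
range 14–70, higher = better well-being; `score_wemwbs` validates and sums
item vectors). Predictors enter a single linear model with main terms and
first-order time interactions:

    y_i = a + b_t t_i + Σ_j b_j x_ij + Σ_j g_j x_ij t_i + e_i

where `t` is days since survey launch (day 0 = 25 March 2020; lockdown week
w spans days 7(w−2) … 7(w−2)+6, weeks 2–8). `b_j` is predictor j's overall
association over the study period, in score units per predictor unit; `g_j`
is the change in that association per additional day of lockdown. Binary
predictors are 0/1 (1 = non-reference), categoricals are reference-coded
into L−1 dummies, Likert responses are treated as numeric scores, age in
years. For presentation, time-related coefficients are rescaled ×10 (per 10
days of lockdown) and age ×10 (per 10 years).

Estimation is ridge regression: minimize `‖Xβ − y‖² + λ‖β‖²`. The solver
computes one thin SVD of the standardized design and evaluates the whole
penalty path through `β(λ) = V diag(d/(d²+λ)) Uᵀy`; at λ = 0 singular
values below a 1e-12 relative cutoff are truncated (pseudo-inverse limit).
The intercept is handled by centering `y` and every column and is never
penalized.

### Pipeline stages

1. **Encode** the table into the design matrix (time column first, then
   mains in schema order — column order is deterministic).
2. **Near-zero-variance filter** on the encoded *main* columns:
   drop a column when (most frequent count / second most frequent count)
   ≥ 19 and the percentage of distinct values ≤ 10% (constant columns
   always). These are the conventional screen defaults; both cuts are
   configurable. The screen runs before interaction construction because a
   binary×t product is mostly zeros by construction under skewed arrivals —
   that says nothing about the predictor itself.
3. **Interactions**: one `x:days` column per surviving main, the raw
   elementwise product. Products are built from raw (uncentered) values;
   as a consequence, a predictor with a large mean relative to its spread
   can produce an interaction column nearly collinear with `t` itself, and
   the correlation filter may then remove that interaction. This is a
   documented property of the raw-product convention, not an error; with
   the default battery exactly one interaction column is affected.
4. **Correlation filter** over the full column set: repeatedly find the
   most correlated pair; if |r| > 0.9 drop the member with the larger mean
   absolute correlation to all remaining columns (lexicographically later
   name on ties). The time column is structural (interactions derive from
   it; the per-day trend is a headline estimate) and is exempt from both
   filters — when it is part of an offending pair, the partner is dropped.
5. **Standardize**: center all columns; scale all non-time columns to unit
   SD (the time column keeps per-day units, so its coefficient needs no
   back-scaling). `y` is centered. The penalty therefore acts on the
   standardized scale and coefficients are back-transformed for reporting —
   whether the original analysis standardized is unknowable from its
   description, so this choice is explicit and can be bypassed by supplying
   pre-scaled data (the penalty is *not* scale-equivariant; a test
   documents this).
6. **Penalty selection**: 100-value log-spaced grid from
   `λ_max = max_j |x_jᵀy| / (n·0.001)` down four decades; k = 20 folds
   (each fold a 5% test set); standardization constants recomputed on each
   training split (no leakage); out-of-fold predictions pooled into one R²
   per λ (lower-variance than averaging 5%-fold R²s; per-fold averaging is
   available); argmax wins, ties toward the larger λ (more shrinkage).
   The winner is refit on all rows.
7. **Balanced bootstrap**: B replicates; each resamples every week with
   replacement down to the minority-week size m (the minority week too is
   resampled at size m), giving m × n_weeks rows — 952 at the published
   weekly counts. The full CV + refit runs inside every replicate, with
   per-replicate standardization. Child seeds are spawned from the master
   seed by `numpy.random.SeedSequence`, so serial and parallel execution
   agree and runs are bit-reproducible. If a replicate's resample makes a
   column constant, the column is dropped from that fit, its draw recorded
   as zero and the event logged — B stays fixed rather than biasing toward
   more-varied replicates. Per-replicate λ re-selection is used throughout
   (each replicate is an independent training set).
8. **Inference**: per coefficient, the estimate is the median of the B
   draws (mean of central order statistics for even B), the 95% CI the
   empirical 2.5/97.5 percentiles with numpy's linear interpolation
   (convention recorded in the output metadata), significance = CI excludes
   zero. No p-values and no multiplicity correction — zero-exclusion only,
   reproducing the procedure as specified. Boxplot summaries for plotting
   use hinges at the 25th/75th percentiles and whiskers at the most extreme
   point within 1.5 × IQR of the hinge.

## Synthetic data generator

`SimulationConfig` defaults encode the study conditions: n = 18,957
respondents; weekly arrival proportions equal to the published counts
(11,194 / 5,008 / 629 / 1,259 / 394 / 337 / 136); response day uniform
within each week (the within-week arrival distribution was not published —
an explicit assumption); a ~20-variable battery whose categorical marginals
match the published overall percentages where available, with plausible
Likert/coping marginals elsewhere; noise SD 7 and intercept 43, which put
the mean outcome near 49 with SD ≈ 7.4 — close to the published 49.2 (8.2)
— and keep clipping to the 14–70 scale below 1% of rows. Default injected
effects mirror the magnitudes reported for this design (e.g. −2.26 for
current psychiatric problems, +0.071/year of age, −0.03/day of lockdown;
interactions of ±0.01–0.04 per day). Predictors are drawn independently —
the generator reproduces marginals and arrival imbalance, not the real
joint distribution, no missingness (the study analysed complete
questionnaires), and no non-linear time structure. Passing recovery tests
therefore demonstrates the *procedure* is sound under its own assumptions,
not that the substantive published estimates are correct.

Outcomes are rounded to integers and clipped after noise; the recorded
truth refers to the pre-clipping linear model, so validation configurations
keep effects/noise in ranges where clipping is rare.

## Validation scales and choices

The acceptance-style checks run the full pipeline at n = 20,000 with
B = 200 replicates (the full-scale default is B = 1,000; 200 keeps a
complete run under a minute while leaving percentile estimates stable to
the tolerances tested). Injected-effect recovery places the small
interaction (0.02/day) on a Likert predictor and 0.04/day on a
mid-prevalence binary, and mains of 0.75 / 1.5 / 3 score units on Likert /
binary / categorical-dummy predictors respectively — the variable types for
which effects of those magnitudes are realistically detectable at 952 rows
per replicate. Rank-correlation of |effect| recovery is computed over the
injected (nonzero-truth) coefficients: with ~90% of true effects exactly
zero, a rank correlation over *all* columns is mathematically capped near
0.5 by ties regardless of estimator quality.

## Numerical notes and edge cases

- Grid selection is invariant to grid order (sorted internally,
  descending); `n_lambda = 1` degenerates to a forced choice.
- A fold whose training split contains a constant column uses lenient
  standardization (scale 1 on a zero column → zero coefficient) so CV stays
  defined; the strict standardizer raises instead, since constant columns
  should have been filtered.
- `r_squared` is 1 − SS_res/SS_tot around the evaluated sample's own mean
  and may be negative out of sample; zero outcome variance raises.
- Week labels are sorted before resampling and iteration everywhere, so
  results do not depend on row order within weeks.

## Known limitations

- Linear-in-time interactions only; no non-linear temporal effects or
  higher-order interactions.
- No survey weighting or propensity adjustment (deliberately, matching the
  procedure modelled).
- The λ values selected here are on this implementation's standardized
  scale and are not comparable to penalty values reported by other
  implementations with different internal scalings.
- Percentile CIs from a down-sampling bootstrap quantify resampling
  variability at the balanced-replicate size, not full sampling uncertainty
  of the original survey; under-coverage for weakly identified interaction
  terms is visible in the null-calibration test (safely under the tested
  15% bound, but not exactly 5%).
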