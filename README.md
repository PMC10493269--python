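# lockwell

Bootstrap-ridge inference for predictors of mental well-being in repeated
cross-sectional lockdown surveys.

## The problem

During the spring-2020 COVID-19 lockdown in France, a large online survey
measured mental well-being with the Warwick-Edinburgh Mental Well-Being
Scale (WEMWBS: 14 items scored 1–5, summed to a 14–70 total) together with a
large battery of socio-demographic, health, COVID-related and coping
predictors. Two features of such data make naive regression unreliable:

1. **Many, partly collinear predictors.** Dozens of main effects plus their
   interactions with time inflate OLS coefficient variance.
2. **Severe temporal imbalance.** Respondents arrived mostly in the first
   surveyed weeks (11,194 in week 2 of lockdown down to 136 in week 8), so
   later weeks would barely influence an unweighted fit.

`lockwell` implements the inference procedure built for this setting, as a
reusable, fully seeded pipeline for epidemiologists and survey
methodologists:

- **Design**: main effects for every predictor (reference-coded
  categoricals, numeric Likert scales) plus first-order interactions with
  *t*, the days since survey launch — so each predictor gets an *overall*
  effect and a *temporal* effect (change in association per additional day
  of lockdown). Near-zero-variance predictors and one member of any pair
  with |r| > 0.9 are removed before modelling.
- **Estimation**: ridge regression, minimizing `‖Xβ − y‖² + λ‖β‖²`
  (from-scratch SVD solver with a shared-SVD penalty path), with λ selected
  by k = 20-fold cross-validation maximizing held-out R² over a 100-value
  grid.
- **Inference**: a balanced down-sampling bootstrap — each of B replicates
  resamples every lockdown week with replacement down to the minority-week
  size (7 × 136 = 952 rows at the published counts), refits the whole
  CV + ridge procedure, and the per-coefficient distribution of B draws
  yields the estimate **B** (median), 95% CI (2.5/97.5 percentiles) and a
  significance flag (CI excludes zero).
- **Validation**: a synthetic survey generator with the same arrival
  imbalance and predictor marginals and *known* injected effects, so sign
  recovery, significance calibration and rank-ordering of effect sizes can
  be verified end to end.

## Worked example

```python
import lockwell as lw

# a synthetic survey at the study's scale, with known injected effects
cfg = lw.SimulationConfig(n_total=18_957, seed=1)
table = lw.generate_survey(cfg)

ens = lw.run_bootstrap(table, cfg.schema(), B=200, master_seed=2)
summary = lw.summarize_coefficients(ens)
print(summary.loc[["days", "psych_history[current]", "cope_resilience"],
                  ["estimate", "ci_low", "ci_high", "significant"]].round(3))
```

prints (seeds as above):

```
                        estimate  ci_low  ci_high  significant
column
days                      -0.059  -0.146   -0.001         True
psych_history[current]    -1.412  -2.409   -0.184         True
cope_resilience            0.901   0.287    1.713         True
```

Read: across 200 balanced bootstrap replicates of 952 respondents each, a
current psychiatric problem is associated with a 1.4-point lower WEMWBS
score (95% CI −2.4 to −0.2, significant), resilience-based coping with a
0.9-point higher score, and each additional day of lockdown with a
0.06-point decline (truth −0.03/day here; the ridge-shrunken bootstrap
median is noisier than the main-effect estimates).
Interaction columns (`<predictor>:days`) are reported per day and scaled
×10 in `estimate_scaled` — i.e. per 10 days of lockdown.

The same pipeline is scriptable from the shell:

```bash
lockwell simulate --n 18957 --seed 1 --out runs/sim
lockwell fit --input runs/sim/survey.csv --schema runs/sim/schema.yaml \
             -B 200 --seed 2 --out runs/fit
lockwell report --ensemble runs/fit/ensemble.csv \
                --manifest runs/fit/manifest.json --out runs/report
```

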