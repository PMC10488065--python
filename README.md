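# twamatch

Propensity-score-matched analysis of intraoperative hypotension burden.

Observational comparisons of hemodynamic monitoring strategies — e.g.
predictive alarm-index ("HPI") monitoring versus standard invasive
arterial pressure monitoring — are confounded: sicker, longer, epidural
and emergency cases are not assigned to monitoring modes at random.
`twamatch` implements the full analysis chain such studies use, plus a
synthetic cohort generator with the same confounding structure so every
stage is testable without access to a clinical registry:

- **Hypotension endpoints** from fixed-interval mean-arterial-pressure
  (MAP) series. The primary metric is the *time-weighted average* (TWA)
  of hypotension below a threshold *thr*:

  TWA(thr) = Σᵢ max(0, thr − MAPᵢ)·Δt / (N·Δt)   [mmHg]

  i.e. the area of the MAP deficit below the threshold divided by the
  total monitoring time. Also: episode counts (run-length segmentation
  with minimum-duration and gap-merge rules), cumulative minutes below
  threshold, alarm counts (runs of an index ≥ 85), and prevented-event
  arithmetic max(0, alarms − events).
- **Propensity-score matching**: maximum-likelihood logistic regression
  (Newton/IRLS, with explicit perfect-separation and collinearity
  errors), greedy 1:1 nearest-neighbor matching without replacement on
  the logit score with a caliper of 0.1 × SD(logit score), and
  standardized-mean-difference (SMD) balance tables before/after
  matching, with |SMD| < 0.2 as the adequacy bar. For a binary
  covariate, SMD = (p₁ − p₂) / √((p₁(1−p₁) + p₂(1−p₂))/2).
- **Comparison tables**: Shapiro–Wilk-gated choice between Student's
  t-test (mean ± SD) and the Mann–Whitney U-test (median, IQR),
  Fisher's exact test for categorical variables, and a creatinine-based
  acute-kidney-injury classifier (rise > 0.3 mg/dL within 48 h, or
  ≥ 1.5 × baseline within 7 days).
- **Synthetic cohorts**: covariates with registry-like marginals,
  logistic confounded group assignment, Poisson hypotensive-episode
  processes with a mechanistic treatment effect (reduced episode rate
  and duration plus alarm-based episode aversion), alarm-index
  channels, and postoperative creatinine trajectories whose AKI risk
  increases with the realized TWA.

## Worked example

```
twamatch run-all --seed 1 --out-dir demo
```

simulates the default confounded cohort (n = 800), computes per-patient
endpoints, fits the propensity model on all 23 baseline covariates,
matches 1:1 at caliper 0.1 and writes the comparison tables plus a
manifest. With seed 1 the manifest reports:

| quantity | value |
|---|---|
| patients (treated / total) | 247 / 800 |
| matched pairs | 201 |
| max abs SMD after matching | 0.095 |
| matched TWA < 65 mmHg, non-HPI | 0.239 mmHg (IQR 0.061, 0.573) |
| matched TWA < 65 mmHg, HPI | 0.090 mmHg (IQR 0.014, 0.290) |
| matched events / cum. duration, non-HPI | 2.0 / 5.0 min |
| matched events / cum. duration, HPI | 1.0 / 2.5 min |

Reading: before matching the arms are grossly imbalanced (emergency and
case-duration SMDs well above 0.2, written to `demo/balance.csv`);
after caliper matching every covariate is below the 0.2 bar, and the
remaining group contrast in TWA — roughly a factor 2–3 lower burden
under predictive monitoring — reflects the simulated treatment effect
rather than selection.

The same stages are available individually (`twamatch simulate`,
`metrics`, `match`, `compare`) and as library functions
(`twamatch.generate_cohort`, `twamatch.summarize_patient`,
`twamatch.fit_propensity`, `twamatch.match_caliper`,
`twamatch.build_comparison_table`, ...).

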