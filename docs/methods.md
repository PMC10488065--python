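# Methods

## Hypotension endpoints

All endpoints are computed on uniformly sampled MAP series (default
Δt = 30 s, the export interval of the anesthesia record systems this
data shape comes from).

**TWA.** The time-weighted average of hypotension below threshold
*thr* is the per-sample rectangle rule: Σ max(0, thr − MAPᵢ)·Δt divided
by N·Δt, which reduces to the mean per-sample deficit (mmHg). No
interpolation is attempted at threshold crossings — at 30-s sampling,
sub-interval interpolation would be spurious precision. TWA is computed
at 65, 60 and 55 mmHg; monotonicity TWA(65) ≥ TWA(60) ≥ TWA(55) holds
by construction.

**Episodes.** An episode is a maximal run of consecutive samples with
MAP strictly below threshold (a sample at time t covers [t, t + Δt)).
Runs separated by at most `merge_gap_s` (default 0) are merged; merged
runs shorter than `min_duration_s` (default 60 s, the common convention
of the intraoperative-hypotension literature; the source registries do
not define an event) are discarded. Cumulative duration below
threshold counts *all* below-threshold samples regardless of episode
filtering, so with `min_duration_s = 0` and `merge_gap_s = 0` episode
lengths sum exactly to the cumulative duration; with the default
one-minute floor a brief isolated dip contributes duration but no
event, which is why the "no events ⇔ zero duration" equivalence is
only guaranteed in the unfiltered regime.

**Alarms.** One alarm is one maximal run of alarm-index samples at or
above the threshold (default 85, following the "equal or greater"
convention of the index literature; configurable). An absent index
channel raises an error — it is not the same as an index that never
alarms. Prevented events are max(0, alarms − events) per patient,
summed for group aggregates.

**Monitoring time** is the full trace span, first to last sample plus
one interval.

## Propensity model and matching

The propensity score is fitted by maximum-likelihood logistic
regression written as explicit Newton/IRLS iterations with
step-halving, so the log-likelihood is non-decreasing and convergence
means a gradient max-norm ≤ 1e−8. Two pathologies are first-class
errors rather than silent divergence: rank deficiency (the collinear
columns are listed) and complete separation (detected when the
likelihood approaches its supremum of zero; the individually separating
covariates are named). Quasi-separation on a rare level — e.g. a
binary covariate with zero cases in one arm — is fit through, as
standard GLM software does, leaving a large but finite coefficient.

Matching is greedy 1:1 nearest-neighbor without replacement on the
logit of the score. Treated units are processed in descending
propensity with ascending-id tie-break; nearest-control ties also break
by ascending id, making the result deterministic and invariant to input
row order. The caliper is 0.1 × SD of the logit scores by default —
the dominant convention of the matching literature and of the software
ecosystem this design mirrors; a raw-probability caliper is available
via `scale="probability"`. Pair counts are non-decreasing in the
caliper, which the tests exercise over 0.1–0.5.

Balance uses standardized mean differences: continuous
(mean difference over the pooled-variance SD, n−1 variances), binary
(proportion difference over pooled binomial SD, unrounded proportions).
Multi-level categoricals are expanded to per-level indicators, each
reported, with the level-maximum reported under the variable name;
there is no canonical single-number SMD for a multi-level factor, so
the per-level convention is documented rather than asserted equivalent
to any other. Degenerate zero-variance contrasts with unequal means
are flagged as signed infinity.

## Comparison tables and AKI

Quantitative variables are gated by Shapiro–Wilk in *both* groups
(α = 0.05): t-test with mean (SD) if both pass, otherwise Mann–Whitney
U with median (IQR). Groups smaller than three force the rank-sum path
with a warning. The U-test uses exact enumeration when the smaller
group has ≤ 8 values and no ties, else the normal approximation with
continuity and tie correction; identical pooled samples give p = 1.
Fisher's exact test sums hypergeometric probabilities ≤ that of the
observed table; an empty margin gives p = 1. Quartiles are linear
interpolation (type 7) everywhere. Percentages are computed on
unrounded counts and printed to one decimal. No multiple-testing
adjustment is applied, and all tests are two-sided.

AKI: creatinine rise strictly greater than 0.3 mg/dL above the
preoperative baseline within 48 h of surgery end (checked first), or a
value at or above 1.5 × baseline within 7 days or until laboratory
controls end. Both cutoffs and both window lengths are parameters; a
1 ns-scale numeric tolerance keeps decimal boundary values (1.30 on
baseline 1.00) on the side their printed arithmetic implies. The rule
is monotone: raising any postoperative value can never clear an AKI
classification.

## Synthetic cohort generator

The generator emulates a single-center perioperative registry of major
non-cardiac surgery (duration > 30 min, ASA II–IV, invasive arterial
monitoring) in which the treated arm receives predictive alarm-index
monitoring.

**Covariates** are drawn from simple parametric marginals loosely
matching such registries (normal age ~69 ± 10, lognormal duration with
median 180 min, ASA II/III/IV ≈ 28/63/9%, emergency ≈ 17%, epidural
probability 0.75 for open-abdomen approaches and 0.25 otherwise, etc.).
Only the epidural–approach link is modelled as a covariate
correlation; the joint distribution is otherwise independent, which is
a deliberate simplification.

**Assignment** is Bernoulli(expit(β·x)) with default log-odds weights
intercept −1.1, emergency −3.0, epidural +1.3, +0.45 per hour of
surgery, −0.6 per ASA grade, yielding ≈ 30% treated and pre-matching
|SMD| well above 0.2 for emergency, epidural and duration — the
selection pattern the matching stage must remove. A configuration
whose assignment empties one arm raises a degenerate-cohort error.

**Episodes** arrive as a homogeneous Poisson process over the case
(default 1.5 per hour) with exponential durations (mean 2.5 min,
floored at 60 s) and gamma depths (mean 25 mmHg). MAP is baseline
(≈ 85 ± 7 mmHg) plus two slow sinusoidal drifts and Gaussian noise
(3 mmHg), minus a flat-topped deficit with 30-s raised-cosine ramps per
episode; overlapping episodes take the deepest per-sample deficit;
everything is clipped to [20, 200] mmHg. In the treated arm the
episode rate and duration are scaled by the treatment-effect multiplier
(default 0.9) and each incipient episode is independently *averted*
with the alarm-aversion probability (default 0.3): averted episodes
leave an alarm-index excursion (planted 300 s ahead, the index's
advertised warning horizon) but no MAP dip. The episode process is
deliberately independent of the covariates, so that with the effect
switched off (multiplier 1, aversion 0) the TWA distribution is
identical in law between arms — the null-calibration property the test
suite checks; confounding in the simulator is purely assignment-side.
The effect defaults were calibrated once against the matched-cohort
endpoint medians typical of the study design this emulates
(TWA(65) ≈ 0.18 vs 0.07 mmHg between arms); the realized medians vary
by seed — the README's worked example shows one actual run.

**Creatinine.** One value per 24 h for 7 days. AKI is drawn with
probability expit(logit(p₀) + s·TWA(65)) (defaults p₀ = 0.08,
s = 1.5 /mmHg); an AKI draw emits a > 0.3 mg/dL rise within 48 h with
exponential recovery, a non-AKI draw fluctuates strictly inside both
criteria.

**Determinism.** A single root seed feeds a `SeedSequence`; covariates
and assignment use the root stream and each patient's trace/outcome
processes use a spawned child stream, so identical configurations
reproduce bit-identical cohorts.

**What passing tests do and do not show.** The simulator reproduces
the *structure* of the analysis problem (confounded assignment, fixed
grid, episode-shaped hypotension, a mechanistic protective effect), not
real arterial physiology: no artifacts, no treatment-response dynamics,
no covariate-dependent episode risk, no correlation between comorbidity
and outcome except through assignment. Passing the end-to-end suite
demonstrates the pipeline recovers known simulated effects and removes
simulated selection bias; it says nothing about transportability to any
particular clinical registry.

## Problem sizes and numerical choices

The default pipeline cohort is n = 800 (≈ 250 treated, ≈ 200 matched
pairs), which keeps a full simulate→match→compare run under a few
seconds; statistical property checks use 100–5000 Monte-Carlo
replicates at n = 120–600. Newton iterations cap at 100; the caliper
degenerates to +∞ when all scores are identical (any pairing is then
within any caliper). CSV is the only interchange format — the data
shapes here have no community binary standard.
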