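# Methods

This note documents the models and procedures implemented in `smoldercmp`,
the assumptions behind them, the free parameters and their defaults, what
the synthetic cohort generator does and does not emulate, and the numerical
and design choices made where more than one reasonable option existed.

## 1. Confirmed worsening, PIRA, PIRMA

### Detection algorithm

Visits are `(day, EDSS)` pairs per patient, day 0 = treatment start, EDSS
restricted to the valid ordinal scale {0} ∪ {1.0, 1.5, …, 10.0}. The
detector maintains a *roving reference* initialized at the first visit and
scans chronologically:

- A visit is a **worsening candidate** when its EDSS exceeds the reference
  by the baseline-dependent minimum increase: 1.5 points from reference 0,
  1.0 from 1.0–5.5, 0.5 above 5.5.
- The candidate is **confirmed** at the first visit ≥ `confirmation_window`
  days later (default 180 = the 6-month convention) provided every visit
  from onset through confirmation still meets the threshold versus the same
  reference (`sustained=True`; a switch relaxes this to the confirmation
  visit only). A failed candidate leaves the reference unchanged.
- After a confirmed worsening the reference moves to the confirmation
  visit. A **confirmed improvement** (EDSS ≥ 0.5 below the reference,
  sustained over the same window) also moves the reference to its
  confirmation visit, so later worsening is judged from the improved level.

Events are therefore non-overlapping and chronologically ordered, and every
emitted event satisfies `onset_edss − reference_edss ≥ threshold` and
`confirmation_day − onset_day ≥ 180` by construction. The test suite checks
the sequential detector against an independent exhaustive-search oracle on
10,000 random trajectories.

Duplicate same-day EDSS entries are rejected rather than averaged: EDSS is
ordinal and a same-day pair is a data error upstream.

### PIRA

An event is PIRA iff no relapse falls in the **closed** interval from the
anchor visit to the confirmation visit, where the anchor is the latest
visit at least `pre_window` (default 90) days before onset. When no visit
that old exists (onset early in follow-up), the earliest visit serves as
anchor and the event carries a QC flag (`anchor_fallback`) instead of being
discarded — the alternative (dropping such events) would bias early
follow-up toward fewer events.

### PIRMA

For a PIRA event, MRI scans in the **half-open** window
`(reference_day, confirmation_day]` decide: any new/enlarged-T2 flag →
not PIRMA; at least one clean scan and none flagged → PIRMA; no scan in the
window → *indeterminate*. The interval conventions (closed relapse window,
half-open MRI window excluding the reference-day scan, which by definition
predates the interval of change) are stated because nothing forces them;
both are configurable only in code, not silently. Indeterminate events are
excluded from the PIRMA event count by default (`indeterminate_as_event`
flips this), since an event without interval imaging is unverifiable.

### Survival records

Event time is the **onset** day (converted to years at 365.25 d/y), not the
confirmation day: the onset visit dates the clinical worsening, the
confirmation only validates it. Patients without a qualifying event are
censored at `min(last_visit_day, discontinuation_day)`. Events whose onset
precedes day 0 (possible when pre-treatment visits are supplied) are
clamped to time 0 in the main analysis and dropped by the onset-filter
sensitivity scheme.

## 2. Propensity matching

Treatment (teriflunomide = 1) is modelled by maximum-likelihood logistic
regression on the ten baseline covariates listed in the README.
Missing-covariate rows are excluded listwise with a reported count;
constant covariates are dropped so a degenerate design reduces to an
intercept-only model. Perfect or quasi-separation raises an explicit error
recommending penalized estimation rather than returning divergent scores.

Matching is greedy 1:1 nearest neighbour **without replacement** on
logit-propensity distance, caliper = 0.2 × SD of the pooled logit scores (a
conventional default), treated patients processed in seeded random order,
distance ties broken toward the smaller control id. Separate matched sets
are built per endpoint cohort (clinical / atrophy / DTI / PRL) using
data-availability masks, maximizing each analysis's sample size. Balance is
reported as median [IQR] per arm, standardized mean difference
(`(m_a − m_b)/√((v_a+v_b)/2)`, proportion variance for binaries), and
two-sided Mann–Whitney U p-values.

Out of scope by design: inverse-probability weighting, optimal/full
matching, doubly-robust estimation.

## 3. Time-to-event models

The Cox model uses the group indicator as its only covariate — the design
is matched, and a single hazard ratio is the estimand — with the Efron
approximation for ties and Wald confidence intervals. Zero events, or all
events in one arm (monotone partial likelihood), raise informative errors
instead of returning boundary estimates. Robust (pair-clustered) variance
is available but off by default. Kaplan–Meier curves use the product-limit
estimator with numbers at risk.

Sensitivity schemes, each a labelled fit in `run_endpoint_suite`:
1. **pairwise censoring** — both members of a pair are censored at the
   shorter of the two follow-ups, removing differential-follow-up bias;
   events after the truncation become censorings;
2. **onset filtering** — only events with onset after treatment start;
3. **PIRMA endpoint** — PIRMA events as the outcome.

Per-analysis failures are reported as strings, not raised, so a sparse
endpoint cannot abort the suite.

## 4. Annualized percentage change

The default APC model is a random-intercept linear mixed model on the log
outcome with linear time (years), group, group × time, plus scanner field
strength and standardized TIV for volumetric outcomes. REML estimation;
Wald inference. `APC_group = 100·(exp(β_time [+ β_interaction]) − 1)`, CI
transformed from the log scale with the delta covariance
`Var(β_t + β_gt) = V_tt + V_gg + 2V_tg`.

"Log-transforming time to derive the APC" admits a second reading, so an
alternative `log_time` specification (log outcome on `log(1+t)`, APC
reported as the modelled change over the first year) is implemented and
selectable; the default is the canonical log-outcome/linear-time
construction, under which a constant-rate exponential decline is exactly
linear.

Numerical details: when the variance components are degenerate (residual
variance below 1e−6 of the outcome variance — e.g. noiseless synthetic
data), the fit falls back to exact OLS with subject fixed intercepts; a
zero-SE interaction with a zero point estimate reports p = 1. Zero-variance
extra covariates are dropped, which makes sensitivity variants collapse
exactly onto the primary fit when their covariate is degenerate (e.g. ARR
in a relapse-free cohort). Non-positive outcome values under the log
transform are an error listing the offending rows.

Sensitivity variants (volumetric outcomes): demographics (+ age, sex,
disease duration, each × time), ARR (+ annualized relapse rate over the MRI
follow-up window, × time), ≥ 2-scan subjects, scans ≥ 183 days after
treatment start. DTI: one model per (FA/MD/RD/AD) × (WML/NAWM/cortex)
without scanner covariates and **without multiplicity adjustment** — the
analysis is exploratory and adjusted inference would be misleadingly
conservative across 12 correlated outcomes. PRL: counts of subjects with
any increase (new) or decrease (resolving), and a random-intercept model on
the raw counts for the group × time p-value (counts may be zero, so no log
transform; a constant count path short-circuits to p = 1).

Random slopes are deliberately not offered: with a median of 2–3 scans per
subject they are weakly identified, and the estimand is the marginal group
trajectory.

## 5. Synthetic cohort generator

The generator emulates an observational two-arm RRMS cohort with known
ground truth, emitting the same CSV schemas the analysis stages read.

Covariate marginals (defaults): age ~ Normal(43.1, 12.5) truncated to
[18, 80] with the parent location shifted so the truncated mean stays 43.1;
65.5% female; log-normal disease duration (median 9.2 y), sNfL (10.2
pg/ml), T2 volume (7.4 ml), T2 count (32); geometric prior-DMT count
(median 1); discrete EDSS (median 2.5, 8% at 0); zero-inflated exponential
time under treatment (median 2.2 y). Treatment is assigned by a logistic
model on a fixed standardized covariate score scaled by
`confounding_strength` (default 0.5, log-odds units; teriflunomide patients
older, longer-treated, with less active disease), drawing candidates until
both group quotas fill; the true propensity is stored per patient.

Clinical streams: visit days on a jittered annual grid (365 ± U(−60, 60)
days); relapses as a Poisson process (default 0.15/person-year, a typical
on-treatment rate); EDSS = baseline + permanent progression steps +
transient relapse bumps (0.5–1.5 points decaying linearly over 90 days,
residual 0.5 step with probability 0.3) snapped to valid EDSS steps and
capped at 10. Progression onsets are exponential with ocrelizumab-arm rate
`baseline_pira_rate` (default 0.10/person-year) and teriflunomide rate
multiplied by `true_pira_hazard_ratio` (default 0.80). The 0.10 default is
the *underlying onset* rate: with annual visits only about half of onsets
can be confirmed in-window, so the detected event burden at study scale
(~30–35 events in 256 patients over median 1.9–3.1 y of group-specific
follow-up) matches the cohort being emulated. Follow-up is exponential with
group-specific medians (3.1 / 1.9 years), truncated at 6 years, mirroring
the asymmetric observation periods of the two arms; dropout is exponential
at 0.05/person-year and the discontinuation day is recorded at the final
attended visit.

MRI streams: jittered annual grids (365 ± U(−90, 90) days); per-patient
constant TIV ~ N(1500, 120) ml and field strength (80% 3T); volumes decay
exponentially at the configured group APC (defaults: brain −1.06 / −0.80,
cortex −1.24 / −0.97, thalamus −0.97 / −1.04, gray matter −1.20 / −0.92
%/year for ocrelizumab / teriflunomide) with multiplicative log-normal
noise (SD 0.004, i.e. ~0.4% scan–rescan, a realistic volumetry figure);
DTI region means start at typical values (e.g. FA 0.30/0.38/0.17 in
WML/NAWM/cortex) and drift linearly at `dti_drift` (default 0 — group
differences in DTI drift are a null by default, configurable per outcome);
PRL counts are non-decreasing with Poisson increments at 0.025/person-year
from a Poisson(1.2) baseline; the new-T2 flag is drawn per scan interval
(5% baseline, 60% when a relapse occurred in the interval). MRI modality
availability follows configurable per-group sub-cohort sizes (defaults
72/33/31 for atrophy/DTI/PRL, first-k-per-group masks).

All randomness flows from the config seed through independent per-stage
generator streams; a fixed config reproduces every table byte-identically.

**What the generator does not emulate** — and hence what passing tests do
not establish about real cohorts: EDSS measurement error and inter-rater
variability (default EDSS noise is 0; worsening enters only through
explicit steps); treatment switching mid-follow-up; pseudoatrophy (early
inflammation-driven volume change that is not neurodegeneration);
informative dropout or visit timing correlated with disease activity;
spatial or lesion-level structure behind the region-mean DTI and PRL
summaries; center effects. Parameter-recovery results therefore validate
the estimators under the stated generative model, not robustness to these
real-data features.

## 6. Problem sizes and statistical checks

The statistical acceptance checks run at the study's operating scales,
chosen as the package's own verification design: detector/oracle
equivalence on 10,000 random trajectories; Cox CI coverage over 200
replicates at 500/group (true HR 0.8, baseline 0.08/y, 3-year
administrative censoring) and type-I calibration over 2,000 null
replicates; APC recovery over 100 replicates at 72/group against the
configured truths of −1.06 and −0.80 %/year with CI coverage pooled over
both group intervals; matching balance improvement over 100 seeded
replicates at 500/group; full-pipeline byte-level determinism at
128/group. Monte-Carlo bands are interpreted against binomial noise at
these replicate counts.

## 7. Known limitations

- The PIRA endpoint is EDSS-only; composite endpoints (timed walk,
  9-hole peg) are out of scope.
- The Cox layer offers only the Efron tie approximation; exact partial
  likelihood for heavily tied data is not implemented (an informative
  error points there when the likelihood is monotone).
- The propensity model is strictly logistic; separation must be resolved
  by the caller (covariate reduction or penalization) rather than silently.
- Greedy matching is order-dependent by construction; the seeded order
  makes this reproducible but not optimal in the optimal-matching sense.
- `balance.csv` reports both pre-match (`smd_prematch`) and post-match
  (`smd`) standardized mean differences, but the Mann–Whitney p-values are
  post-match only.
- The mixed models assume a shared residual variance across groups and
  scans; heteroscedastic extensions are not provided.
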