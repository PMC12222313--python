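# smoldercmp

A tested, reusable pipeline for comparative-effectiveness analysis of
*smoldering* disease activity in relapsing–remitting multiple sclerosis
(RRMS): disability worsening that accrues independently of relapses, and its
MRI correlates. It is aimed at biostatisticians and MS researchers working
with observational cohort data — long-format tables of dated EDSS visits,
relapses, and MRI-derived metrics for two treatment groups (here
teriflunomide vs ocrelizumab).

## What it computes

**PIRA / PIRMA event detection.** Confirmed EDSS worsening is detected with
a *roving baseline*: a visit is a candidate onset when its EDSS exceeds the
current reference by ≥ 1.5, ≥ 1.0, or ≥ 0.5 points (reference EDSS 0,
1.0–5.5, or > 5.5 respectively), confirmed at the first visit ≥ 180 days
later with the increase sustained at every intervening visit; the reference
then moves to the confirmation visit (likewise after a confirmed ≥ 0.5-step
improvement). An event is **PIRA** (progression independent of relapse
activity) if no relapse falls between the pre-onset anchor visit (latest
visit ≥ 90 days before onset) and the confirmation; it is **PIRMA** if
interval MRI additionally shows no new/enlarged T2 lesions
(indeterminate when no interval MRI exists).

**Propensity-matched comparison.** Logistic propensity scores on ten
baseline covariates (age, sex, disease duration, prior DMTs, T2-lesion
count and volume, sNfL and its Z-score, EDSS, time under treatment), greedy
1:1 nearest-neighbour matching on the logit score with a 0.2-SD caliper,
and balance diagnostics (standardized mean differences, Mann–Whitney U).

**Survival analysis.** Cox proportional hazards (group indicator, Efron
ties) and Kaplan–Meier curves for time to PIRA, with sensitivity schemes:
pairwise censoring within matched pairs, restriction to post-baseline
onsets, and the PIRMA endpoint.

**Annualized percentage change (APC).** For brain volumes, regional DTI
metrics, and PRL counts, a linear mixed model with random intercepts per
participant:

    log y_ij = β0 + β_g·teri_i + β_t·t_ij + β_gt·teri_i·t_ij (+ scanner, TIV) + u_i + ε_ij

so `APC = 100·(exp(β_t [+ β_gt]) − 1)` %/year per group, with the group
difference tested by the Wald p-value of the interaction. Four sensitivity
variants (demographics × time, relapse rate × time, ≥ 2-scan subset,
scans ≥ 183 days).

**Synthetic cohort generator.** Because patient-level data from the
originating registry setting are not openly distributable, the package
ships a seeded simulator with known ground truth (true hazard ratio, true
APC per group, true propensity scores) that emulates the cohort structure:
confounded treatment assignment, annual clinical visits, sparse MRI,
Poisson relapses with transient EDSS bumps, exponential progression onset
times, group-specific atrophy, and rare PRL accrual.

## Worked example

```bash
smoldercmp all --seed 1 --out demo_run
```

simulates 128 patients per group (MRI sub-cohorts 72/33/31 per group),
detects events, matches, and fits every model. Inspecting the outputs:

```python
>>> import json, pandas as pd
>>> cox = json.load(open("demo_run/cox_results.json"))
>>> cox["primary"]["hazard_ratio"], cox["primary"]["n_events"]
(0.9977778293425837, 10)
>>> apc = pd.read_csv("demo_run/apc_results.csv")
>>> apc.query("outcome == 'brain_ml' and variant == 'primary'")[["group", "apc"]]
           group       apc
0    ocrelizumab -1.066573
1  teriflunomide -0.757539
```

The hazard ratio near 1 reflects the small matched event count at this
cohort size (10 events among 174 matched patients; the generator's true
hazard ratio is 0.80, recoverable only across replicates). The brain-volume
APCs land near the generator's truths of −1.06 and −0.80 %/year: the
ocrelizumab arm loses ~1% of brain volume per year in this simulated
cohort, the teriflunomide arm ~0.8%, and the interaction p-value in the
same table tests that difference. `demo_run/reports/` contains the
baseline-characteristics table, the matched-balance table, the
longitudinal-results table, and the Kaplan–Meier figure.

The same stages run on user-supplied data with
`smoldercmp all --input my_cohort_dir --out my_results` where the input
directory holds `patients.csv`, `visits.csv`, `relapses.csv`, `mri.csv` in
the documented schemas (see `docs/methods.md`).

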