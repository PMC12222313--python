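"""Seeded synthetic cohort generator with known ground truth.

Emulates an observational two-arm MS cohort: covariates drawn to match the
marginal distributions of a real-world relapsing-remitting MS population,
treatment (teriflunomide vs ocrelizumab) assigned by a logistic model on the
covariates (confounded assignment), annual clinical visits with EDSS, a
Poisson relapse process with transient EDSS bumps, permanent progression
steps at exponential ground-truth onset times with a group hazard ratio,
and sparse MRI visits carrying volumetric, DTI and PRL outcomes with
group-specific annualized percentage change (APC).

All randomness flows from ``SimulationConfig.seed`` through per-stage
``numpy.random.Generator`` streams, so a fixed config reproduces the cohort
byte-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from .config import (
    DTI_OUTCOMES,
    GROUPS,
    SimulationConfig,
    VOLUMETRIC_OUTCOMES,
)
from .events import DAYS_PER_YEAR, min_increase_for, snap_edss

PATIENT_COLUMNS = [
    "patient_id",
    "group",
    "age",
    "sex",
    "disease_duration_years",
    "n_prior_dmts",
    "t2_count",
    "t2_volume_ml",
    "snfl_pg_ml",
    "snfl_z",
    "edss_baseline",
    "discontinuation_day",
    "last_visit_day",
    "time_under_treatment_years",
]
VISIT_COLUMNS = ["patient_id", "day", "edss"]
RELAPSE_COLUMNS = ["patient_id", "day"]
MRI_COLUMNS = [
    "patient_id",
    "day",
    "field_strength",
    "tiv_ml",
    "brain_ml",
    "cortex_ml",
    "thalamus_ml",
    "gm_ml",
    "fa_wml",
    "fa_nawm",
    "fa_cortex",
    "md_wml",
    "md_nawm",
    "md_cortex",
    "rd_wml",
    "rd_nawm",
    "rd_cortex",
    "ad_wml",
    "ad_nawm",
    "ad_cortex",
    "prl_count",
    "new_t2_flag",
]

# --- covariate marginal targets -------------------------------------------
# age: Normal(43.1, 12.5) truncated to [18, 80]; the location is shifted
# down so the *truncated* mean stays at 43.1.
_AGE_MEAN, _AGE_SD, _AGE_LO, _AGE_HI = 43.1, 12.5, 18.0, 80.0
_FEMALE_FRAC = 0.655
_EDSS_ZERO_FRAC = 0.08

# logistic assignment weights (direction: teriflunomide patients tend to be
# older, longer disease duration, longer on drug, with less active disease).
_ASSIGN_WEIGHTS = {
    "age": 0.40,
    "sex_f": -0.10,
    "disease_duration_years": 0.30,
    "n_prior_dmts": -0.30,
    "t2_count": -0.20,
    "t2_volume_ml": -0.20,
    "snfl_pg_ml": -0.30,
    "snfl_z": -0.20,
    "edss_baseline": 0.20,
    "time_under_treatment_years": 0.40,
}
# reference scales for standardization of the linear predictor
_ASSIGN_SCALE = {
    "age": (43.1, 12.3),
    "sex_f": (0.655, 0.475),
    "disease_duration_years": (15.2, 17.0),
    "n_prior_dmts": (1.8, 2.2),
    "t2_count": (35.2, 15.5),
    "t2_volume_ml": (12.2, 14.0),
    "snfl_pg_ml": (11.9, 7.0),
    "snfl_z": (0.8, 1.34),
    "edss_baseline": (2.5, 1.4),
    "time_under_treatment_years": (4.1, 5.4),
}


def _age_trunc_loc() -> float:
    """Location of the parent normal whose [18, 80]-truncation has mean 43.1."""
    from scipy.optimize import brentq

    def f(loc):
        a, b = (_AGE_LO - loc) / _AGE_SD, (_AGE_HI - loc) / _AGE_SD
        return truncnorm.mean(a, b, loc=loc, scale=_AGE_SD) - _AGE_MEAN

    return brentq(f, 35.0, 50.0, xtol=1e-10)


_AGE_LOC = None  # computed lazily once


@dataclass
class Cohort:
    """In-memory bundle of the generator's canonical tables."""

    patients: pd.DataFrame
    visits: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=VISIT_COLUMNS)
    )
    relapses: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=RELAPSE_COLUMNS)
    )
    mri: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=MRI_COLUMNS)
    )
    ground_truth: dict = field(default_factory=dict)


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage]))


def _draw_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    global _AGE_LOC
    if _AGE_LOC is None:
        _AGE_LOC = _age_trunc_loc()
    a = (_AGE_LO - _AGE_LOC) / _AGE_SD
    b = (_AGE_HI - _AGE_LOC) / _AGE_SD
    age = truncnorm.rvs(a, b, loc=_AGE_LOC, scale=_AGE_SD, size=n, random_state=rng)
    sex_f = rng.random(n) < _FEMALE_FRAC
    dd = rng.lognormal(np.log(9.2), 1.0, n)
    dmts = rng.geometric(0.36, n) - 1  # support {0,1,...}, median 1, q75 3
    t2_count = np.rint(rng.lognormal(np.log(32.0), 0.45, n)).astype(int)
    t2lv = rng.lognormal(np.log(7.4), 1.0, n)
    snfl = rng.lognormal(np.log(10.2), 0.55, n)
    snfl_z = rng.normal(0.8, 1.335, n)
    edss = np.array([snap_edss(x) for x in rng.lognormal(np.log(2.5), 0.55, n)])
    edss = np.minimum(edss, 7.0)
    edss[rng.random(n) < _EDSS_ZERO_FRAC] = 0.0
    tut = np.where(rng.random(n) < 0.25, 0.0, rng.exponential(5.4, n))
    return pd.DataFrame(
        {
            "age": age,
            "sex_f": sex_f.astype(int),
            "disease_duration_years": dd,
            "n_prior_dmts": dmts,
            "t2_count": t2_count,
            "t2_volume_ml": t2lv,
            "snfl_pg_ml": snfl,
            "snfl_z": snfl_z,
            "edss_baseline": edss,
            "time_under_treatment_years": tut,
        }
    )


def _linear_predictor(cov: pd.DataFrame) -> np.ndarray:
    norm = np.sqrt(sum(w * w for w in _ASSIGN_WEIGHTS.values()))
    eta = np.zeros(len(cov))
    for name, w in _ASSIGN_WEIGHTS.items():
        m, s = _ASSIGN_SCALE[name]
        eta += (w / norm) * (cov[name].to_numpy(dtype=float) - m) / s
    return eta


def simulate_baseline(config: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """Draw baseline covariates and confounded treatment assignment.

    Draws candidate patients, assigns treatment with probability
    ``expit(confounding_strength * score)`` where the score is a fixed
    standardized combination of the ten matching covariates, and keeps
    candidates until both group quotas (``n_per_group``) are filled.
    Returns the patients table plus a ground-truth dict holding each kept
    patient's true propensity and assignment.
    """
    config.validate()
    rng = _stage_rng(config.seed, 0)
    kept: list[dict] = []
    counts = {g: 0 for g in GROUPS}
    while min(counts.values()) < config.n_per_group:
        block = _draw_covariates(rng, 256)
        eta = config.confounding_strength * _linear_predictor(block)
        p_teri = expit(eta)
        u = rng.random(len(block))
        for i in range(len(block)):
            g = "teriflunomide" if u[i] < p_teri[i] else "ocrelizumab"
            if counts[g] >= config.n_per_group:
                continue
            row = block.iloc[i].to_dict()
            row["group"] = g
            row["true_propensity"] = float(p_teri[i])
            counts[g] += 1
            kept.append(row)
            if min(counts.values()) >= config.n_per_group:
                break

    pts = pd.DataFrame(kept)
    pts["patient_id"] = [f"P{i:05d}" for i in range(len(pts))]
    pts["sex"] = np.where(pts.pop("sex_f") == 1, "F", "M")

    # follow-up span and treatment discontinuation (independent draws so the
    # order of earlier draws cannot shift them between patients)
    rng2 = _stage_rng(config.seed, 10)
    med = pts["group"].map(config.followup_median_years).to_numpy(dtype=float)
    fu_years = np.minimum(
        rng2.exponential(med / np.log(2.0)), config.followup_max_years
    )
    fu_years = np.maximum(fu_years, 0.25)
    disc_years = (
        rng2.exponential(1.0 / config.dropout_rate, len(pts))
        if config.dropout_rate > 0
        else np.full(len(pts), np.inf)
    )
    pts["last_visit_day"] = np.rint(fu_years * DAYS_PER_YEAR).astype(int)
    pts["discontinuation_day"] = np.where(
        disc_years < fu_years, np.rint(disc_years * DAYS_PER_YEAR), np.nan
    )

    truth = {
        "config": config.to_dict(),
        "patients": {
            pid: {"group": g, "true_propensity": p, "pira_onset_days": []}
            for pid, g, p in zip(
                pts["patient_id"], pts["group"], pts["true_propensity"]
            )
        },
    }
    pts = pts[PATIENT_COLUMNS]
    return pts.reset_index(drop=True), truth


def _visit_grid(
    rng: np.random.Generator, end_day: float, interval: float, jitter: float
) -> list[int]:
    days = [0]
    t = 0.0
    while True:
        t += interval + rng.uniform(-jitter, jitter)
        if t > end_day:
            break
        d = int(round(t))
        if d <= days[-1]:
            d = days[-1] + 1
        if d > end_day:
            break
        days.append(d)
    return days


def _observation_end(patient: pd.Series) -> int:
    end = patient["last_visit_day"]
    disc = patient["discontinuation_day"]
    if pd.notna(disc):
        end = min(end, disc)
    return int(end)


def simulate_clinical_stream(
    patients: pd.DataFrame, config: SimulationConfig, ground_truth: Optional[dict] = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate per-patient EDSS visit and relapse tables.

    The EDSS trajectory is baseline + permanent progression steps at
    ground-truth onset times (exponential, group hazard =
    ``baseline_pira_rate`` times the hazard ratio for teriflunomide) +
    transient relapse bumps decaying over ``relapse_bump_decay_days`` with a
    residual 0.5 step with probability ``relapse_residual_prob``; values are
    snapped to valid EDSS steps and capped at 10. Records never extend past
    min(last_visit_day, discontinuation_day). The patients table's
    ``last_visit_day`` is updated in place to the realized last visit.
    """
    config.validate()
    rng = _stage_rng(config.seed, 1)
    visit_rows, relapse_rows = [], []
    last_days = {}
    for _, p in patients.iterrows():
        pid = p["patient_id"]
        end = _observation_end(p)
        days = _visit_grid(
            rng, end, config.visit_interval_days, config.visit_jitter_days
        )
        end_years = end / DAYS_PER_YEAR

        n_rel = rng.poisson(config.relapse_rate * end_years)
        rel_days = np.sort(rng.uniform(1, max(end, 2), n_rel)).astype(int)
        rel_days = np.unique(rel_days)

        hr = config.true_pira_hazard_ratio if p["group"] == "teriflunomide" else 1.0
        rate = config.baseline_pira_rate * hr
        onsets = []
        if rate > 0:
            t = rng.exponential(1.0 / rate)
            while t < end_years:
                onsets.append(int(round(t * DAYS_PER_YEAR)))
                t += rng.exponential(1.0 / rate)
        if ground_truth is not None:
            ground_truth["patients"][pid]["pira_onset_days"] = list(map(int, onsets))

        # permanent EDSS path: breakpoints at progression onsets and relapse
        # residual steps, evaluated left-to-right so each step size depends
        # on the level reached so far
        steps = [(d, "pira") for d in onsets]
        bumps = []
        for rd in rel_days:
            amp = rng.choice([0.5, 1.0, 1.5], p=[0.5, 0.35, 0.15])
            bumps.append((int(rd), float(amp)))
            if rng.random() < config.relapse_residual_prob:
                steps.append((int(rd), "residual"))
        steps.sort()

        sd_edss = float(config.measurement_sd.get("edss", 0.0))
        for d in days:
            level = float(p["edss_baseline"])
            for sd_day, kind in steps:
                if sd_day <= d:
                    if kind == "pira":
                        level = min(10.0, level + min_increase_for(snap_edss(level)))
                    else:
                        level = min(10.0, level + 0.5)
            transient = sum(
                amp * max(0.0, 1.0 - (d - bd) / config.relapse_bump_decay_days)
                for bd, amp in bumps
                if bd <= d
            )
            noise = rng.normal(0.0, sd_edss) if sd_edss > 0 else 0.0
            visit_rows.append((pid, d, snap_edss(level + transient + noise)))
        for rd in rel_days:
            relapse_rows.append((pid, int(rd)))
        last_days[pid] = days[-1]

    patients["last_visit_day"] = patients["patient_id"].map(last_days).astype(int)
    # a discontinuing patient is last observed at their final attended visit
    disc = patients["discontinuation_day"]
    patients["discontinuation_day"] = np.where(
        disc.notna(), patients["last_visit_day"], np.nan
    )
    visits = pd.DataFrame(visit_rows, columns=VISIT_COLUMNS)
    relapses = pd.DataFrame(relapse_rows, columns=RELAPSE_COLUMNS)
    return visits, relapses


# baseline medians of the DTI region means (FA unitless, diffusivities mm^2/s)
_DTI_BASE = {
    "fa_wml": 0.30,
    "fa_nawm": 0.38,
    "fa_cortex": 0.17,
    "md_wml": 1.11e-3,
    "md_nawm": 0.74e-3,
    "md_cortex": 0.91e-3,
    "rd_wml": 0.93e-3,
    "rd_nawm": 0.58e-3,
    "rd_cortex": 0.83e-3,
    "ad_wml": 1.47e-3,
    "ad_nawm": 1.06e-3,
    "ad_cortex": 1.06e-3,
}
# TIV fractions for the volumetric outcomes (brain parenchymal fraction etc.)
_VOL_FRACTION = {"brain_ml": 0.69, "cortex_ml": 0.31, "thalamus_ml": 0.0145,
                 "gm_ml": 0.40}


def _modality_mask(patients: pd.DataFrame, n_per_group: Optional[int]) -> pd.Series:
    """First-k-per-group data-availability mask (k=None -> everyone)."""
    if n_per_group is None:
        return pd.Series(True, index=patients.index)
    mask = pd.Series(False, index=patients.index)
    for g in GROUPS:
        idx = patients.index[patients["group"] == g][:n_per_group]
        mask.loc[idx] = True
    return mask


def simulate_mri_stream(
    patients: pd.DataFrame,
    config: SimulationConfig,
    relapses: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Generate the MRI observation table.

    Volumes decay exponentially at the group's configured APC with
    multiplicative log-normal noise; TIV and field strength are fixed per
    patient; DTI region means drift linearly at ``dti_drift`` %/year; the
    PRL count is a non-decreasing integer path; the new/enlarged-T2 flag is
    drawn per scan interval with elevated probability when a relapse
    occurred in the interval. Modality availability follows the configured
    per-group sub-cohort sizes (volumetric / DTI / PRL columns are missing
    outside their sub-cohort).
    """
    config.validate()
    rng = _stage_rng(config.seed, 2)
    if relapses is None:
        relapses = pd.DataFrame(columns=RELAPSE_COLUMNS)
    vol_mask = _modality_mask(patients, config.n_atrophy_per_group)
    dti_mask = _modality_mask(patients, config.n_dti_per_group)
    prl_mask = _modality_mask(patients, config.n_prl_per_group)
    any_mask = vol_mask | dti_mask | prl_mask

    sd_vol = float(config.measurement_sd.get("volume", 0.0))
    sd_dti = float(config.measurement_sd.get("dti", 0.0))
    rows = []
    for idx, p in patients.iterrows():
        if not any_mask.loc[idx]:
            continue
        pid = p["patient_id"]
        end = _observation_end(p)
        days = _visit_grid(rng, end, config.mri_interval_days, config.mri_jitter_days)
        t_years = np.asarray(days) / DAYS_PER_YEAR
        field_strength = 3.0 if rng.random() < 0.8 else 1.5
        tiv = rng.normal(1500.0, 120.0)
        rel_days = relapses.loc[relapses["patient_id"] == pid, "day"].to_numpy()

        rec = {d: {"patient_id": pid, "day": d, "field_strength": field_strength,
                   "tiv_ml": tiv} for d in days}

        if vol_mask.loc[idx]:
            for out in VOLUMETRIC_OUTCOMES:
                apc = float(config.true_apc[out][p["group"]])
                v0 = _VOL_FRACTION[out] * tiv * rng.lognormal(0.0, 0.05)
                noise = (
                    rng.normal(0.0, sd_vol, len(days)) if sd_vol > 0
                    else np.zeros(len(days))
                )
                vals = v0 * (1.0 + apc / 100.0) ** t_years * np.exp(noise)
                for d, v in zip(days, vals):
                    rec[d][out] = v
        if dti_mask.loc[idx]:
            for out in DTI_OUTCOMES:
                drift = float(config.dti_drift.get(out, {}).get(p["group"], 0.0))
                base = _DTI_BASE[out] * rng.lognormal(0.0, 0.04)
                noise = (
                    rng.normal(0.0, sd_dti, len(days)) if sd_dti > 0
                    else np.zeros(len(days))
                )
                vals = base * (1.0 + drift / 100.0 * t_years) * (1.0 + noise)
                vals = np.maximum(vals, 1e-9)
                if out.startswith("fa_"):
                    vals = np.minimum(vals, 1.0)
                for d, v in zip(days, vals):
                    rec[d][out] = v
        if prl_mask.loc[idx]:
            count = int(rng.poisson(1.2))
            prev_t = None
            for d, t in zip(days, t_years):
                if prev_t is not None:
                    count += int(rng.poisson(config.prl_new_prob * (t - prev_t)))
                rec[d]["prl_count"] = count
                prev_t = t

        prev_d = None
        for d in days:
            if prev_d is None:
                flag = 0
            else:
                rel_in = np.any((rel_days > prev_d) & (rel_days <= d))
                pr = (
                    config.new_t2_relapse_prob if rel_in else config.new_t2_base_prob
                )
                flag = int(rng.random() < pr)
            rec[d]["new_t2_flag"] = flag
            prev_d = d
        rows.extend(rec[d] for d in days)

    mri = pd.DataFrame(rows)
    for c in MRI_COLUMNS:
        if c not in mri.columns:
            mri[c] = np.nan
    return mri[MRI_COLUMNS]


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Run the three generator stages and bundle the result."""
    patients, truth = simulate_baseline(config)
    visits, relapses = simulate_clinical_stream(patients, config, truth)
    mri = simulate_mri_stream(patients, config, relapses)
    truth["true_pira_hazard_ratio"] = config.true_pira_hazard_ratio
    truth["true_apc"] = config.true_apc
    return Cohort(patients, visits, relapses, mri, truth)


# ---------------------------------------------------------------------------
# I/O


def _to_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def write_cohort(cohort: Cohort, out_dir: str | Path) -> list[Path]:
    """Write patients/visits/relapses/mri CSVs + ground_truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df, cols in (
        ("patients.csv", cohort.patients, PATIENT_COLUMNS),
        ("visits.csv", cohort.visits, VISIT_COLUMNS),
        ("relapses.csv", cohort.relapses, RELAPSE_COLUMNS),
        ("mri.csv", cohort.mri, MRI_COLUMNS),
    ):
        path = out / name
        _to_csv(df.reindex(columns=cols), path)
        written.append(path)
    gt_path = out / "ground_truth.json"
    gt_path.write_text(json.dumps(cohort.ground_truth, indent=2, sort_keys=True))
    written.append(gt_path)
    return written


def read_cohort(in_dir: str | Path) -> Cohort:
    """Read a cohort directory written by :func:`write_cohort`."""
    d = Path(in_dir)
    patients = pd.read_csv(d / "patients.csv")
    visits = pd.read_csv(d / "visits.csv")
    relapses = pd.read_csv(d / "relapses.csv")
    mri = pd.read_csv(d / "mri.csv")
    gt_path = d / "ground_truth.json"
    truth = json.loads(gt_path.read_text()) if gt_path.exists() else {}
    return Cohort(patients, visits, relapses, mri, truth)
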