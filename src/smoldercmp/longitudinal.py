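"""Annualized percentage change (APC) from linear mixed-effects models.

Default model for an outcome y observed at time t years:

    log(y_ij) = b0 + b_g * teri_i + b_t * t_ij + b_gt * teri_i * t_ij
                [+ scanner field strength + standardized TIV, volumetric only]
                [+ sensitivity covariates and their time interactions]
                + u_i + e_ij,    u_i ~ N(0, s_u^2)  (random intercept)

so each group's fitted trajectory is exponential in time and

    APC_ocrelizumab  = 100 * (exp(b_t) - 1)           [%/year]
    APC_teriflunomide = 100 * (exp(b_t + b_gt) - 1)

with Wald confidence intervals on the log scale and the group difference
tested by the Wald p-value of the interaction coefficient. Estimation is
REML. An alternative ``log_time`` specification regresses log(y) on
log(1 + t) instead, reporting the modelled change over the first year.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .config import DTI_OUTCOMES, GROUPS, VOLUMETRIC_OUTCOMES
from .events import DAYS_PER_YEAR

TREATED_GROUP = "teriflunomide"
_Z = norm.ppf(0.975)


class ModelError(ValueError):
    pass


@dataclass
class ApcResult:
    """Per-group annualized percentage change for one outcome/variant."""

    outcome: str
    variant: str
    apc: dict  # group -> {"apc", "ci_low", "ci_high"}
    interaction_p: float
    n_subjects: int
    n_observations: int
    note: str = ""

    @property
    def estimable(self) -> bool:
        return self.note != "unestimable"


@dataclass
class PrlChangeResult:
    n_new: dict  # group -> count of subjects whose PRL count ever increases
    n_resolving: dict  # group -> count with any decrease
    group_sizes: dict
    interaction_p: float
    note: str = ""


def _wald_p(beta: float, se: float) -> float:
    if not np.isfinite(se) or se <= 1e-12:
        # exact-fit degenerate case: no evidence of a difference unless the
        # point estimate itself is non-zero
        return 1.0 if abs(beta) < 1e-8 else 0.0
    return float(2 * norm.sf(abs(beta) / se))


def _apc_from(beta: float, var: float, spec: str) -> dict:
    scale = np.log(2.0) if spec == "log_time" else 1.0
    se = np.sqrt(max(var, 0.0))
    return {
        "apc": 100.0 * (np.exp(beta * scale) - 1.0),
        "ci_low": 100.0 * (np.exp((beta - _Z * se) * scale) - 1.0),
        "ci_high": 100.0 * (np.exp((beta + _Z * se) * scale) - 1.0),
    }


def _prepare(obs: pd.DataFrame, outcome: str, log_outcome: bool) -> pd.DataFrame:
    need = {"patient_id", "group", "day", outcome}
    missing = need - set(obs.columns)
    if missing:
        raise ModelError(f"missing columns: {sorted(missing)}")
    df = obs.dropna(subset=[outcome]).copy()
    if df.empty:
        raise ModelError(f"no observations for outcome {outcome}")
    if log_outcome:
        bad = df[df[outcome] <= 0]
        if len(bad):
            raise ModelError(
                f"non-positive {outcome} under log transform in rows: "
                f"{bad.index.tolist()[:10]}"
            )
    df["t_years"] = df["day"].astype(float) / DAYS_PER_YEAR
    df["teri"] = (df["group"] == TREATED_GROUP).astype(float)
    per_subj = df.groupby("patient_id")["day"].nunique()
    if (per_subj >= 2).sum() == 0:
        raise ModelError("all subjects have a single timepoint; slope unidentifiable")
    return df


def _fit_mixed(endog: np.ndarray, exog: pd.DataFrame, groups: np.ndarray):
    """REML random-intercept fit with a fixed-effects OLS fallback.

    The fallback absorbs subjects as fixed intercepts and is used only when
    the variance components are degenerate (e.g. noiseless data).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.MixedLM(endog, exog, groups=groups)
            res = model.fit(reml=True, method=["lbfgs"])
            params = res.fe_params
            cov = res.cov_params().loc[params.index, params.index]
            degenerate = res.scale < 1e-6 * max(np.var(endog), 1e-30)
            if np.all(np.isfinite(cov.to_numpy())) and not degenerate:
                return params, cov
        except (np.linalg.LinAlgError, ValueError):
            pass
        # within-subject OLS fallback
        dummies = pd.get_dummies(pd.Series(groups, name="pid"), dtype=float)
        X = pd.concat(
            [exog.drop(columns=["const"], errors="ignore").reset_index(drop=True),
             dummies.reset_index(drop=True)],
            axis=1,
        )
        # drop columns constant within all subjects (absorbed by dummies)
        keep = [c for c in X.columns if X[c].nunique() > 1 or c in dummies.columns]
        X = X[keep]
        res = sm.OLS(endog, X).fit()
        names = [c for c in exog.columns if c in X.columns]
        params = res.params.reindex(exog.columns).fillna(0.0)
        cov_full = pd.DataFrame(0.0, index=exog.columns, columns=exog.columns)
        cov = res.cov_params()
        for a in names:
            for b in names:
                cov_full.loc[a, b] = cov.loc[a, b]
        return params, cov_full


def fit_apc_model(
    obs: pd.DataFrame,
    outcome: str,
    variant: str = "primary",
    spec: str = "log_outcome",
    scanner_covariates: Optional[bool] = None,
    extra_covariates: Sequence[str] = (),
    extra_time_interactions: Sequence[str] = (),
) -> ApcResult:
    """Fit the APC mixed model for one outcome.

    Parameters
    ----------
    obs
        Long-format observations: patient_id, group, day, the outcome
        column, plus field_strength/tiv_ml for volumetric outcomes and any
        sensitivity covariate columns.
    outcome
        Column to model (must be positive under the log transform).
    spec
        ``log_outcome`` (default; linear time on the log scale) or
        ``log_time`` (log(1+t) regressor; APC reported as the modelled
        change over the first year).
    scanner_covariates
        Include field strength + standardized TIV fixed effects; default:
        automatically for volumetric outcomes.
    extra_covariates / extra_time_interactions
        Column names added as fixed effects / as interactions with time.
        Zero-variance columns are silently dropped.
    """
    if spec not in ("log_outcome", "log_time"):
        raise ModelError(f"unknown spec {spec!r}")
    df = _prepare(obs, outcome, log_outcome=True)
    if scanner_covariates is None:
        scanner_covariates = outcome in VOLUMETRIC_OUTCOMES

    tcol = np.log1p(df["t_years"]) if spec == "log_time" else df["t_years"]
    exog = pd.DataFrame(
        {
            "const": 1.0,
            "teri": df["teri"].to_numpy(),
            "time": tcol.to_numpy(),
        }
    )
    exog["teri_time"] = exog["teri"] * exog["time"]
    if scanner_covariates:
        exog["field_3t"] = (df["field_strength"].astype(float) >= 3.0).astype(float).to_numpy()
        tiv = df["tiv_ml"].astype(float)
        exog["tiv_std"] = ((tiv - tiv.mean()) / (tiv.std(ddof=0) or 1.0)).to_numpy()
    for c in extra_covariates:
        exog[c] = df[c].astype(float).to_numpy()
    for c in extra_time_interactions:
        exog[f"{c}_x_time"] = df[c].astype(float).to_numpy() * exog["time"]
    # drop degenerate columns (constant 0-variance covariates)
    for c in list(exog.columns):
        if c != "const" and exog[c].nunique() <= 1:
            exog = exog.drop(columns=[c])

    endog = np.log(df[outcome].to_numpy(dtype=float))
    params, cov = _fit_mixed(endog, exog, df["patient_id"].to_numpy())

    b_t = float(params["time"])
    has_int = "teri_time" in params.index
    b_it = float(params["teri_time"]) if has_int else 0.0
    v_t = float(cov.loc["time", "time"])
    if has_int:
        v_it = float(cov.loc["teri_time", "teri_time"])
        v_sum = v_t + v_it + 2.0 * float(cov.loc["time", "teri_time"])
        p_int = _wald_p(b_it, np.sqrt(max(v_it, 0.0)))
    else:
        v_sum, p_int = v_t, 1.0
    apc = {
        "ocrelizumab": _apc_from(b_t, v_t, spec),
        "teriflunomide": _apc_from(b_t + b_it, v_sum, spec),
    }
    return ApcResult(
        outcome=outcome,
        variant=variant,
        apc=apc,
        interaction_p=p_int,
        n_subjects=int(df["patient_id"].nunique()),
        n_observations=int(len(df)),
    )


def _unestimable(outcome: str, variant: str, reason: str) -> ApcResult:
    nanblock = {"apc": np.nan, "ci_low": np.nan, "ci_high": np.nan}
    return ApcResult(
        outcome=outcome,
        variant=variant,
        apc={g: dict(nanblock) for g in GROUPS},
        interaction_p=np.nan,
        n_subjects=0,
        n_observations=0,
        note="unestimable",
    )


def compute_arr(mri: pd.DataFrame, relapses: pd.DataFrame) -> pd.Series:
    """Annualized relapse rate during each patient's MRI follow-up window."""
    out = {}
    for pid, scans in mri.groupby("patient_id"):
        d0, d1 = scans["day"].min(), scans["day"].max()
        span = (d1 - d0) / DAYS_PER_YEAR
        if span <= 0:
            out[pid] = 0.0
            continue
        r = relapses[relapses["patient_id"] == pid]
        n = int(((r["day"] >= d0) & (r["day"] <= d1)).sum()) if len(r) else 0
        out[pid] = n / span
    return pd.Series(out, name="arr")


def run_bvl_sensitivity_suite(
    mri: pd.DataFrame,
    patients: pd.DataFrame,
    relapses: pd.DataFrame,
    outcomes: Sequence[str] = VOLUMETRIC_OUTCOMES,
    spec: str = "log_outcome",
) -> list[ApcResult]:
    """The four brain-volume-loss sensitivity variants per volumetric outcome.

    demographics: + baseline age, sex, disease duration and their time
    interactions; arr: + annualized relapse rate over the MRI follow-up and
    its time interaction; min2scans: only subjects with >= 2 scans;
    post183: only scans acquired >= 183 days after treatment start.
    """
    base = mri.merge(
        patients[
            ["patient_id", "group", "age", "sex", "disease_duration_years"]
        ],
        on="patient_id",
        how="left",
    )
    base["sex_f"] = (base["sex"] == "F").astype(float)
    arr = compute_arr(mri, relapses)
    base["arr"] = base["patient_id"].map(arr).fillna(0.0)

    results: list[ApcResult] = []
    for outcome in outcomes:
        specs = {
            "demographics": dict(
                extra_covariates=["age", "sex_f", "disease_duration_years"],
                extra_time_interactions=["age", "sex_f", "disease_duration_years"],
            ),
            "arr": dict(extra_covariates=["arr"], extra_time_interactions=["arr"]),
        }
        for variant, kwargs in specs.items():
            try:
                results.append(
                    fit_apc_model(base, outcome, variant=variant, spec=spec, **kwargs)
                )
            except ModelError as e:
                results.append(_unestimable(outcome, variant, str(e)))
        counts = base.dropna(subset=[outcome]).groupby("patient_id")["day"].nunique()
        keep = counts.index[counts >= 2]
        sub = base[base["patient_id"].isin(keep)]
        try:
            results.append(fit_apc_model(sub, outcome, variant="min2scans", spec=spec))
        except ModelError as e:
            results.append(_unestimable(outcome, "min2scans", str(e)))
        sub2 = base[base["day"] >= 183]
        try:
            results.append(fit_apc_model(sub2, outcome, variant="post183", spec=spec))
        except ModelError as e:
            results.append(_unestimable(outcome, "post183", str(e)))
    return results


def fit_dti_suite(
    obs: pd.DataFrame, spec: str = "log_outcome"
) -> list[ApcResult]:
    """One APC model per (DTI metric, region); no scanner covariates, no
    multiplicity adjustment (exploratory convention)."""
    results = []
    for outcome in DTI_OUTCOMES:
        try:
            results.append(
                fit_apc_model(obs, outcome, spec=spec, scanner_covariates=False)
            )
        except ModelError as e:
            results.append(_unestimable(outcome, "primary", str(e)))
    return results


def analyze_prl(obs: pd.DataFrame) -> PrlChangeResult:
    """Count subjects with new / resolving PRLs and test the group x time
    interaction with a random-intercept model on the raw counts."""
    df = obs.dropna(subset=["prl_count"]).copy()
    if df.empty:
        return PrlChangeResult({}, {}, {}, np.nan, note="no PRL data")
    df["t_years"] = df["day"].astype(float) / DAYS_PER_YEAR
    df["teri"] = (df["group"] == TREATED_GROUP).astype(float)

    n_new = {g: 0 for g in GROUPS}
    n_res = {g: 0 for g in GROUPS}
    sizes = {g: 0 for g in GROUPS}
    for (pid, g), sub in df.sort_values("day").groupby(["patient_id", "group"]):
        counts = sub["prl_count"].to_numpy(dtype=float)
        sizes[g] = sizes.get(g, 0) + 1
        if np.any(np.diff(counts) > 0):
            n_new[g] = n_new.get(g, 0) + 1
        if np.any(np.diff(counts) < 0):
            n_res[g] = n_res.get(g, 0) + 1

    if df["prl_count"].nunique() <= 1 or df["t_years"].nunique() <= 1:
        return PrlChangeResult(n_new, n_res, sizes, 1.0, note="degenerate outcome")
    exog = pd.DataFrame(
        {
            "const": 1.0,
            "teri": df["teri"].to_numpy(),
            "time": df["t_years"].to_numpy(),
        }
    )
    exog["teri_time"] = exog["teri"] * exog["time"]
    params, cov = _fit_mixed(
        df["prl_count"].to_numpy(dtype=float), exog, df["patient_id"].to_numpy()
    )
    p = _wald_p(
        float(params["teri_time"]),
        float(np.sqrt(max(cov.loc["teri_time", "teri_time"], 0.0))),
    )
    return PrlChangeResult(n_new, n_res, sizes, p)


def apc_frame(results: list[ApcResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for g in GROUPS:
            block = r.apc.get(g, {})
            rows.append(
                {
                    "outcome": r.outcome,
                    "variant": r.variant,
                    "group": g,
                    "apc": block.get("apc", np.nan),
                    "ci_low": block.get("ci_low", np.nan),
                    "ci_high": block.get("ci_high", np.nan),
                    "interaction_p": r.interaction_p,
                    "n_subj": r.n_subjects,
                    "n_obs": r.n_observations,
                    "note": r.note,
                }
            )
    return pd.DataFrame(rows)
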