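"""Propensity-score estimation, 1:1 greedy matching, and balance diagnostics.

The propensity model is a logistic regression of treatment (teriflunomide =
1) on the ten baseline matching covariates. Matching is greedy nearest
neighbour without replacement on the logit of the propensity score with a
caliper expressed in SDs of the logit score; separate matched sets can be
built per endpoint by passing eligibility masks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import mannwhitneyu

DEFAULT_COVARIATES = [
    "age",
    "sex",
    "disease_duration_years",
    "n_prior_dmts",
    "t2_count",
    "t2_volume_ml",
    "snfl_pg_ml",
    "snfl_z",
    "edss_baseline",
    "time_under_treatment_years",
]

TREATED_GROUP = "teriflunomide"
CONTROL_GROUP = "ocrelizumab"


class MatchingError(ValueError):
    pass


class SeparationError(MatchingError):
    """Perfect separation in the propensity fit; advise penalized estimation."""


@dataclass
class PropensityModel:
    coefficients: pd.Series  # includes 'const'; dropped covariates absent
    scores: pd.Series  # fitted P(teriflunomide), indexed by patient_id
    standard_errors: pd.Series
    n_dropped_missing: int = 0
    dropped_constant: list = field(default_factory=list)


@dataclass(frozen=True)
class MatchedPair:
    teri_id: str
    ocre_id: str
    logit_distance: float


def _design(patients: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    X = patients[covariates].copy()
    if "sex" in X.columns:
        X["sex"] = (X["sex"] == "F").astype(float)
    return X.astype(float)


def fit_propensity(
    patients: pd.DataFrame, covariates: list[str] | None = None
) -> PropensityModel:
    """Fit the logistic propensity model.

    Rows with missing covariate values are dropped (complete-case; count
    reported on the result). Constant covariates are removed before the fit
    so a fully degenerate design reduces to an intercept-only model whose
    score is the treated prevalence.
    """
    covariates = list(covariates or DEFAULT_COVARIATES)
    for g, n in patients["group"].value_counts().items():
        if n < 10:
            raise MatchingError(f"need >= 10 patients per group; {g} has {n}")
    X = _design(patients, covariates)
    y = (patients["group"] == TREATED_GROUP).astype(float)
    ok = X.notna().all(axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        warnings.warn(f"dropping {n_dropped} patient(s) with missing covariates")
    X, y = X[ok], y[ok]
    ids = patients.loc[ok, "patient_id"]

    dropped_const = [c for c in X.columns if X[c].nunique() <= 1]
    Xf = X.drop(columns=dropped_const)
    design = sm.add_constant(Xf, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
    except (sm.tools.sm_exceptions.PerfectSeparationError,
            sm.tools.sm_exceptions.PerfectSeparationWarning,
            np.linalg.LinAlgError) as e:
        raise SeparationError(
            "perfect separation in propensity model; refit with penalization "
            "(e.g. L2) or drop the offending covariate"
        ) from e
    if not res.mle_retvals.get("converged", True) or np.abs(res.params).max() > 50:
        raise SeparationError(
            "propensity fit did not converge (quasi-separation); consider "
            "penalized estimation"
        )
    scores = pd.Series(np.asarray(res.predict(design)), index=ids.to_numpy())
    return PropensityModel(
        coefficients=res.params,
        scores=scores,
        standard_errors=res.bse,
        n_dropped_missing=n_dropped,
        dropped_constant=dropped_const,
    )


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return np.log(p / (1 - p))


def match_1to1(
    patients: pd.DataFrame,
    scores: pd.Series,
    caliper_sd: float = 0.2,
    seed: int = 0,
) -> list[MatchedPair]:
    """Greedy 1:1 nearest-neighbour matching without replacement.

    Operates on logit propensity scores; treated (teriflunomide) patients
    are processed in seeded random order, each taking the closest unused
    control within ``caliper_sd`` SDs of the pooled logit score (ties broken
    by smaller control patient_id).
    """
    grp = patients.set_index("patient_id")["group"]
    grp = grp[grp.index.isin(scores.index)]
    teri = sorted(grp.index[grp == TREATED_GROUP])
    ocre = sorted(grp.index[grp == CONTROL_GROUP])
    if not teri or not ocre:
        raise MatchingError("both treatment groups must be non-empty")
    lg = pd.Series(_logit(scores.loc[grp.index].to_numpy()), index=grp.index)
    sd = float(lg.std(ddof=1))
    caliper = caliper_sd * sd if sd > 0 else np.inf

    order = np.array(teri, dtype=object)
    np.random.default_rng(seed).shuffle(order)
    ocre_arr = np.array(ocre, dtype=object)  # sorted, so argmin tie -> smaller id
    lg_o = lg.loc[ocre_arr].to_numpy()
    avail = np.ones(len(ocre_arr), dtype=bool)
    pairs: list[MatchedPair] = []
    for tid in order:
        d = np.abs(lg_o - lg[tid])
        d[~avail] = np.inf
        k = int(np.argmin(d))
        if d[k] <= caliper + 1e-12:
            avail[k] = False
            pairs.append(MatchedPair(str(tid), str(ocre_arr[k]), float(d[k])))
    return sorted(pairs, key=lambda p: p.teri_id)


def pairs_frame(pairs: list[MatchedPair], endpoint: str = "clinical") -> pd.DataFrame:
    return pd.DataFrame(
        [(endpoint, p.teri_id, p.ocre_id, p.logit_distance) for p in pairs],
        columns=["endpoint", "teri_id", "ocre_id", "logit_distance"],
    )


def standardized_mean_difference(x_a, x_b) -> float:
    """SMD = (mean_a - mean_b) / sqrt((var_a + var_b)/2).

    Binary (0/1) variables use the proportion variance p(1-p). Zero pooled
    SD returns 0 for equal means and signed infinity otherwise.
    """
    a = np.asarray(x_a, dtype=float)
    b = np.asarray(x_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per arm")
    binary = set(np.unique(np.concatenate([a, b]))) <= {0.0, 1.0}
    if binary:
        va, vb = a.mean() * (1 - a.mean()), b.mean() * (1 - b.mean())
    else:
        va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = np.sqrt((va + vb) / 2.0)
    diff = a.mean() - b.mean()
    if pooled == 0:
        return 0.0 if diff == 0 else float(np.sign(diff) * np.inf)
    return float(diff / pooled)


def _median_iqr(x: np.ndarray) -> str:
    q1, q2, q3 = np.percentile(x, [25, 50, 75])
    return f"{q2:.2f} [{q1:.2f}; {q3:.2f}]"


def balance_table(
    patients: pd.DataFrame,
    pairs: list[MatchedPair],
    variables: list[str] | None = None,
    endpoint: str = "clinical",
) -> pd.DataFrame:
    """Post-match balance report: median [IQR], SMD, Mann-Whitney U p-value.

    Constant variables get p = 1 with a note; variables appear in the
    requested order.
    """
    variables = list(variables or DEFAULT_COVARIATES)
    if not pairs:
        raise MatchingError("no matched pairs")
    idx = patients.set_index("patient_id")
    teri = idx.loc[[p.teri_id for p in pairs]]
    ocre = idx.loc[[p.ocre_id for p in pairs]]
    rows = []
    for var in variables:
        a = teri[var]
        b = ocre[var]
        if var == "sex":
            a = (a == "F").astype(float)
            b = (b == "F").astype(float)
        a = a.to_numpy(dtype=float)
        b = b.to_numpy(dtype=float)
        smd = standardized_mean_difference(a, b)
        if np.unique(np.concatenate([a, b])).size <= 1:
            p, note = 1.0, "constant variable"
        else:
            p = float(mannwhitneyu(a, b, alternative="two-sided").pvalue)
            note = ""
        rows.append(
            {
                "endpoint": endpoint,
                "variable": var,
                "median_iqr_teri": _median_iqr(a),
                "median_iqr_ocre": _median_iqr(b),
                "smd": smd,
                "mwu_p": p,
                "note": note,
            }
        )
    return pd.DataFrame(rows)


def smd_series(
    patients: pd.DataFrame,
    teri_ids: list[str],
    ocre_ids: list[str],
    variables: list[str] | None = None,
) -> pd.Series:
    """Per-variable SMD between two patient id sets."""
    variables = list(variables or DEFAULT_COVARIATES)
    idx = patients.set_index("patient_id")
    a_df, b_df = idx.loc[teri_ids], idx.loc[ocre_ids]
    out = {}
    for var in variables:
        a, b = a_df[var], b_df[var]
        if var == "sex":
            a = (a == "F").astype(float)
            b = (b == "F").astype(float)
        out[var] = standardized_mean_difference(a, b)
    return pd.Series(out)


def mean_abs_smd(
    patients: pd.DataFrame,
    teri_ids: list[str],
    ocre_ids: list[str],
    variables: list[str] | None = None,
) -> float:
    """Mean |SMD| across covariates between two id sets (balance summary)."""
    return float(smd_series(patients, teri_ids, ocre_ids, variables).abs().mean())
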