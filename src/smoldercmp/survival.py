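"""Time-to-event comparison between matched treatment groups.

Cox proportional hazards (group indicator only, Efron ties) and
Kaplan-Meier estimation over the survival records produced by the event
module, plus the sensitivity schemes: pairwise censoring within matched
pairs, onset filtering, and the PIRMA endpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter

from .matching import MatchedPair

TREATED_GROUP = "teriflunomide"


class SurvivalError(ValueError):
    pass


@dataclass
class CoxResult:
    """Hazard ratio for teriflunomide vs ocrelizumab with Wald 95% CI."""

    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n_events: int
    n_subjects: int
    label: str = "primary"

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class KMCurve:
    group: str
    times: np.ndarray
    survival: np.ndarray
    n_at_risk: np.ndarray


def fit_cox(
    records: pd.DataFrame,
    tie_method: str = "efron",
    robust: bool = False,
    label: str = "primary",
) -> CoxResult:
    """Fit the two-group Cox model on survival records.

    The sole covariate is the treated-group indicator, so exp(beta) is the
    teriflunomide-vs-ocrelizumab hazard ratio. Raises with an explicit
    message when there are no events, or when all events fall in one arm
    (monotone partial likelihood; an exact or penalized method would be
    needed).
    """
    if tie_method != "efron":
        raise NotImplementedError(
            f"tie_method {tie_method!r}: only the Efron approximation is provided"
        )
    if records.empty:
        raise SurvivalError("no survival records")
    n_events = int(records["event"].sum())
    if n_events == 0:
        raise SurvivalError("zero events: Cox model is not estimable")
    ev_groups = set(records.loc[records["event"] == 1, "group"])
    if len(ev_groups) < 2:
        raise SurvivalError(
            "all events in one arm (monotone likelihood); use an exact or "
            "penalized fallback"
        )
    df = pd.DataFrame(
        {
            "time": records["time_years"].astype(float).clip(lower=1e-9),
            "event": records["event"].astype(int),
            "teri": (records["group"] == TREATED_GROUP).astype(int),
        }
    )
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event", robust=robust)
    beta = float(cph.params_["teri"])
    se = float(cph.standard_errors_["teri"])
    p = float(cph.summary.loc["teri", "p"])
    z = 1.959963984540054
    return CoxResult(
        hazard_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - z * se)),
        ci_high=float(np.exp(beta + z * se)),
        p_value=p,
        n_events=n_events,
        n_subjects=len(records),
        label=label,
    )


def km_estimate(records: pd.DataFrame) -> dict[str, KMCurve]:
    """Kaplan-Meier product-limit curve per treatment group."""
    curves = {}
    for g, sub in records.groupby("group"):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time_years"], sub["event"])
        tbl = kmf.event_table
        times = tbl.index.to_numpy(dtype=float)
        surv = kmf.survival_function_at_times(times).to_numpy(dtype=float)
        curves[str(g)] = KMCurve(
            group=str(g),
            times=times,
            survival=surv,
            n_at_risk=tbl["at_risk"].to_numpy(dtype=int),
        )
    return curves


def km_frame(curves: dict[str, KMCurve]) -> pd.DataFrame:
    rows = []
    for g in sorted(curves):
        c = curves[g]
        for t, s, n in zip(c.times, c.survival, c.n_at_risk):
            rows.append((g, float(t), float(s), int(n)))
    return pd.DataFrame(rows, columns=["group", "time_years", "survival", "n_at_risk"])


def pairwise_censor(records: pd.DataFrame, pairs: list[MatchedPair]) -> pd.DataFrame:
    """Censor each patient at the shorter follow-up time of their pair.

    Events occurring after the truncation time become censorings with
    reason ``pairwise``. Every record must belong to exactly one pair.
    """
    partner = {}
    for p in pairs:
        partner[p.teri_id] = p.ocre_id
        partner[p.ocre_id] = p.teri_id
    missing = set(records["patient_id"].astype(str)) - set(partner)
    if missing:
        raise SurvivalError(f"unpaired patient(s) in records: {sorted(missing)[:5]}")
    time = records.set_index("patient_id")["time_years"]
    out = records.copy().reset_index(drop=True)
    for i, row in out.iterrows():
        own = row["time_years"]
        other = time.loc[partner[str(row["patient_id"])]]
        t = min(own, other)
        if own > t:
            out.loc[i, "time_years"] = t
            if row["event"] == 1:
                out.loc[i, "event"] = 0
            out.loc[i, "censor_reason"] = "pairwise"
        elif row["event"] == 0 and other < own:
            out.loc[i, "censor_reason"] = "pairwise"
    return out


def run_endpoint_suite(
    patients: pd.DataFrame,
    events: pd.DataFrame,
    pairs: list[MatchedPair],
    tie_method: str = "efron",
    indeterminate_as_event: bool = False,
) -> dict[str, CoxResult | str]:
    """Run the four labelled time-to-event analyses on the matched cohort.

    primary (PIRA), pairwise_censored, onset_filtered (only events with
    onset after treatment start), and pirma. Per-analysis errors are
    captured as strings so one failing fit does not abort the suite.
    """
    from .events import build_survival_records

    matched_ids = {p.teri_id for p in pairs} | {p.ocre_id for p in pairs}
    pts = patients[patients["patient_id"].astype(str).isin(matched_ids)]
    results: dict[str, CoxResult | str] = {}

    def attempt(label, fn):
        try:
            results[label] = fn()
        except (SurvivalError, ValueError) as e:
            results[label] = f"error: {e}"

    rec_primary = build_survival_records(pts, events, endpoint="pira")
    attempt("primary", lambda: fit_cox(rec_primary, tie_method, label="primary"))
    attempt(
        "pairwise_censored",
        lambda: fit_cox(
            pairwise_censor(rec_primary, pairs), tie_method, label="pairwise_censored"
        ),
    )
    attempt(
        "onset_filtered",
        lambda: fit_cox(
            build_survival_records(pts, events, endpoint="pira", onset_filter=True),
            tie_method,
            label="onset_filtered",
        ),
    )
    attempt(
        "pirma",
        lambda: fit_cox(
            build_survival_records(
                pts,
                events,
                endpoint="pirma",
                indeterminate_as_event=indeterminate_as_event,
            ),
            tie_method,
            label="pirma",
        ),
    )
    return results
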