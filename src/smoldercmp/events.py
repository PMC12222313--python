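"""Confirmed disability worsening detection and PIRA / PIRMA classification.

Implements the roving-baseline algorithm for confirmed EDSS worsening:
a visit qualifies as an onset when its EDSS exceeds the current reference
by a baseline-dependent threshold, the worsening must be confirmed at the
first visit at least ``confirmation_window`` days later (sustained at every
intervening visit), and the reference moves to the confirmation visit after
each confirmed change (worsening or improvement).

PIRA (progression independent of relapse activity) additionally requires no
relapse between a pre-onset anchor visit and the confirmation visit; PIRMA
(progression independent of relapse and MRI activity) additionally requires
interval MRI free of new/enlarged T2 lesions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

import numpy as np
import pandas as pd

#: Valid EDSS steps: 0, then half-point steps from 1.0 to 10.0.
VALID_EDSS = frozenset([0.0] + [x / 2 for x in range(2, 21)])

CONFIRMATION_WINDOW_DAYS = 180  # "confirmed at least after 6 months"
PRE_ONSET_WINDOW_DAYS = 90
IMPROVEMENT_STEP = 0.5


class EventDetectionError(ValueError):
    """Raised on invalid visit/relapse input to the event detector."""


def is_valid_edss(edss: float) -> bool:
    return float(edss) in VALID_EDSS


def snap_edss(value: float) -> float:
    """Snap a real value to the nearest valid EDSS step (ties round up).

    0.5 is not a valid step; values nearest to it resolve upward to 1.0.
    Output is clipped to [0, 10].
    """
    v = min(max(float(value), 0.0), 10.0)
    if v < 0.5:
        return 0.0
    if v < 1.0:
        return 1.0  # 0 and 1.0 are equidistant at 0.5; ties resolve upward
    snapped = np.floor(2.0 * v + 0.5) / 2.0  # half-up to nearest 0.5
    return float(min(snapped, 10.0))


def min_increase_for(reference_edss: float) -> float:
    """Minimum EDSS increase that counts as worsening for a given reference.

    1.5 points from reference 0, 1.0 from 1.0-5.5, 0.5 above 5.5.
    """
    r = float(reference_edss)
    if not is_valid_edss(r):
        raise ValueError(f"{reference_edss!r} is not a valid EDSS step")
    if r == 0.0:
        return 1.5
    if r <= 5.5:
        return 1.0
    return 0.5


@dataclass
class ProgressionEvent:
    """A confirmed EDSS worsening for one patient.

    ``is_pirma`` is ternary: True / False / None (indeterminate, no interval
    MRI available). ``anchor_fallback`` flags events where no visit existed
    at least ``PRE_ONSET_WINDOW_DAYS`` before onset, so the relapse window
    was anchored at the earliest visit instead (QC condition).
    """

    patient_id: str
    onset_day: int
    confirmation_day: int
    reference_edss: float
    reference_day: int
    onset_edss: float
    is_pira: Optional[bool] = None
    is_pirma: Optional[bool] = None
    anchor_fallback: bool = False


def _validate_visits(days: np.ndarray, patient_id: str = "?") -> None:
    if len(days) != len(np.unique(days)):
        raise EventDetectionError(
            f"duplicate same-day EDSS entries for patient {patient_id}"
        )
    if np.any(np.diff(days) < 0):
        raise EventDetectionError(f"visits not sorted by day for patient {patient_id}")


def detect_confirmed_worsening(
    visits: pd.DataFrame,
    confirmation_window: int = CONFIRMATION_WINDOW_DAYS,
    sustained: bool = True,
) -> list[ProgressionEvent]:
    """Detect confirmed EDSS worsenings for a single patient's visit stream.

    Parameters
    ----------
    visits
        DataFrame with columns ``patient_id``, ``day``, ``edss`` for one
        patient; must be sortable with unique days.
    confirmation_window
        Minimum days between onset and the confirming visit.
    sustained
        If True (default), every visit between onset and confirmation must
        also satisfy the worsening threshold versus the same reference; if
        False only the confirmation visit is checked.

    Returns
    -------
    list of ProgressionEvent with PIRA/PIRMA flags unset.

    Notes
    -----
    The reference ("roving baseline") starts at the first visit and moves to
    the confirmation visit after each confirmed worsening, and likewise after
    a confirmed improvement (a >= 0.5-step decrease sustained for the same
    window). A failed candidate does not move the reference.
    """
    if len(visits) < 2:
        return []
    visits = visits.sort_values("day")
    days = visits["day"].to_numpy(dtype=np.int64)
    edss = visits["edss"].to_numpy(dtype=float)
    pid = str(visits["patient_id"].iloc[0])
    _validate_visits(days, pid)
    for e in edss:
        if not is_valid_edss(e):
            raise EventDetectionError(f"invalid EDSS value {e} for patient {pid}")

    n = len(days)
    events: list[ProgressionEvent] = []
    ref = 0  # index of current reference visit
    i = 1
    while i < n:
        delta = edss[i] - edss[ref]
        thr = min_increase_for(edss[ref])
        moved = False
        if delta >= thr:
            j = _first_confirmation(days, i, confirmation_window)
            if j is not None and _sustained_worsening(
                edss, ref, i, j, thr, sustained
            ):
                events.append(
                    ProgressionEvent(
                        patient_id=pid,
                        onset_day=int(days[i]),
                        confirmation_day=int(days[j]),
                        reference_edss=float(edss[ref]),
                        reference_day=int(days[ref]),
                        onset_edss=float(edss[i]),
                    )
                )
                ref = j
                i = j + 1
                moved = True
        elif delta <= -IMPROVEMENT_STEP:
            j = _first_confirmation(days, i, confirmation_window)
            if j is not None and _sustained_improvement(edss, ref, i, j, sustained):
                ref = j
                i = j + 1
                moved = True
        if not moved:
            i += 1
    return events


def _first_confirmation(days: np.ndarray, onset: int, window: int) -> Optional[int]:
    for j in range(onset + 1, len(days)):
        if days[j] - days[onset] >= window:
            return j
    return None


def _sustained_worsening(edss, ref, onset, conf, thr, sustained) -> bool:
    ks = range(onset + 1, conf + 1) if sustained else [conf]
    return all(edss[k] - edss[ref] >= thr for k in ks)


def _sustained_improvement(edss, ref, onset, conf, sustained) -> bool:
    ks = range(onset + 1, conf + 1) if sustained else [conf]
    return all(edss[ref] - edss[k] >= IMPROVEMENT_STEP for k in ks)


def classify_pira(
    event: ProgressionEvent,
    visits: pd.DataFrame,
    relapses: pd.DataFrame,
    pre_window: int = PRE_ONSET_WINDOW_DAYS,
) -> bool:
    """Set and return the PIRA flag for a confirmed worsening.

    The event is PIRA iff no relapse falls in the closed interval from the
    anchor visit to the confirmation visit, where the anchor is the latest
    visit on or before ``onset_day - pre_window``. If no such visit exists
    the earliest visit is used and ``anchor_fallback`` is set.
    """
    if not relapses.empty:
        other = set(relapses["patient_id"].astype(str)) - {event.patient_id}
        if other:
            raise EventDetectionError(
                f"relapses for foreign patient(s) {sorted(other)} passed with "
                f"event of patient {event.patient_id}"
            )
    days = np.sort(visits["day"].to_numpy(dtype=np.int64))
    eligible = days[days <= event.onset_day - pre_window]
    if len(eligible):
        anchor_day = int(eligible[-1])
    else:
        anchor_day = int(days[0])
        event.anchor_fallback = True
    if relapses.empty:
        hit = False
    else:
        r = relapses["day"].to_numpy(dtype=np.int64)
        hit = bool(np.any((r >= anchor_day) & (r <= event.confirmation_day)))
    event.is_pira = not hit
    return event.is_pira


def classify_pirma(event: ProgressionEvent, mri: pd.DataFrame) -> Optional[bool]:
    """Set and return the ternary PIRMA flag for a PIRA event.

    Scans MRI observations in the half-open window
    (reference_day, confirmation_day]: any new/enlarged-T2 flag -> False;
    at least one clean MRI and none flagged -> True; no MRI -> None
    (indeterminate).
    """
    if event.is_pira is not True:
        raise EventDetectionError("classify_pirma requires a PIRA event")
    if mri.empty:
        event.is_pirma = None
        return None
    m = mri[
        (mri["day"] > event.reference_day) & (mri["day"] <= event.confirmation_day)
    ]
    if m.empty:
        event.is_pirma = None
    elif m["new_t2_flag"].astype(int).any():
        event.is_pirma = False
    else:
        event.is_pirma = True
    return event.is_pirma


def detect_events(
    visits: pd.DataFrame,
    relapses: pd.DataFrame,
    mri: Optional[pd.DataFrame] = None,
    confirmation_window: int = CONFIRMATION_WINDOW_DAYS,
    sustained: bool = True,
    pre_window: int = PRE_ONSET_WINDOW_DAYS,
) -> pd.DataFrame:
    """Run detection + PIRA/PIRMA classification for every patient.

    Returns the events table (one row per confirmed worsening) with columns
    patient_id, onset_day, confirmation_day, reference_edss, reference_day,
    onset_edss, is_pira, is_pirma, anchor_fallback. ``is_pirma`` holds
    "true"/"false"/"indeterminate" strings for CSV friendliness ("" for
    non-PIRA events).
    """
    if mri is None:
        mri = pd.DataFrame(columns=["patient_id", "day", "new_t2_flag"])
    rows = []
    for pid, v in visits.sort_values(["patient_id", "day"]).groupby(
        "patient_id", sort=True
    ):
        r = relapses[relapses["patient_id"] == pid]
        m = mri[mri["patient_id"] == pid]
        for ev in detect_confirmed_worsening(v, confirmation_window, sustained):
            classify_pira(ev, v, r, pre_window)
            if ev.is_pira:
                classify_pirma(ev, m)
            rows.append(
                {
                    "patient_id": ev.patient_id,
                    "onset_day": ev.onset_day,
                    "confirmation_day": ev.confirmation_day,
                    "reference_edss": ev.reference_edss,
                    "reference_day": ev.reference_day,
                    "onset_edss": ev.onset_edss,
                    "is_pira": bool(ev.is_pira),
                    "is_pirma": (
                        ""
                        if not ev.is_pira
                        else {True: "true", False: "false", None: "indeterminate"}[
                            ev.is_pirma
                        ]
                    ),
                    "anchor_fallback": ev.anchor_fallback,
                }
            )
    cols = [
        "patient_id",
        "onset_day",
        "confirmation_day",
        "reference_edss",
        "reference_day",
        "onset_edss",
        "is_pira",
        "is_pirma",
        "anchor_fallback",
    ]
    return pd.DataFrame(rows, columns=cols)


DAYS_PER_YEAR = 365.25


def build_survival_records(
    patients: pd.DataFrame,
    events: pd.DataFrame,
    endpoint: Literal["pira", "pirma"] = "pira",
    onset_filter: bool = False,
    indeterminate_as_event: bool = False,
    visits: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Build one survival record per patient for the chosen endpoint.

    Event time is the first qualifying event's onset day in years; patients
    without a qualifying event are censored at min(last_visit_day,
    discontinuation_day). With ``onset_filter`` events whose initial EDSS
    increase predates treatment start (onset_day < 0) are dropped; without
    it such times are clamped to 0.

    For the PIRMA endpoint, indeterminate events count as events only when
    ``indeterminate_as_event`` is set; otherwise those patients are censored.

    Patients with zero visits (when ``visits`` is supplied) are excluded
    with a warning.
    """
    if endpoint not in ("pira", "pirma"):
        raise ValueError(f"unknown endpoint {endpoint!r}")
    pts = patients.copy()
    if visits is not None:
        with_visits = set(visits["patient_id"])
        n_drop = (~pts["patient_id"].isin(with_visits)).sum()
        if n_drop:
            warnings.warn(
                f"excluding {n_drop} patient(s) with zero visits from survival set"
            )
            pts = pts[pts["patient_id"].isin(with_visits)]

    ev = events.copy()
    if endpoint == "pira":
        ev = ev[ev["is_pira"].astype(bool)]
    else:
        ok = {"true"} | ({"indeterminate"} if indeterminate_as_event else set())
        ev = ev[ev["is_pirma"].isin(ok)]
    if onset_filter:
        ev = ev[ev["onset_day"] >= 0]
    if len(ev):
        first = ev.sort_values("onset_day").groupby("patient_id")["onset_day"].first()
    else:
        first = pd.Series(dtype=float)

    rows = []
    for _, p in pts.iterrows():
        pid = p["patient_id"]
        disc = p.get("discontinuation_day")
        cens_day = p["last_visit_day"]
        reason = "last_visit"
        if pd.notna(disc) and disc <= cens_day:
            cens_day = disc
            reason = "discontinuation"
        if pid in first.index:
            t = max(first.loc[pid], 0) / DAYS_PER_YEAR
            rows.append((pid, p["group"], t, 1, reason))
        else:
            rows.append((pid, p["group"], cens_day / DAYS_PER_YEAR, 0, reason))
    return pd.DataFrame(
        rows, columns=["patient_id", "group", "time_years", "event", "censor_reason"]
    )
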