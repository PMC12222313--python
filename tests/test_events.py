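"""Event detection: thresholds, roving baseline, PIRA/PIRMA classification."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from smoldercmp.events import (
    EventDetectionError,
    build_survival_records,
    classify_pira,
    classify_pirma,
    detect_confirmed_worsening,
    detect_events,
    min_increase_for,
    snap_edss,
)

from conftest import mri_df, relapses_df, visits_df
from oracles import oracle_detect, oracle_pira


@pytest.mark.parametrize(
    "ref,expected",
    [(0.0, 1.5), (1.0, 1.0), (2.5, 1.0), (5.5, 1.0), (6.0, 0.5), (10.0, 0.5)],
)
def test_min_increase_thresholds(ref, expected):
    assert min_increase_for(ref) == expected


@pytest.mark.parametrize("bad", [0.5, 0.7, 3.25, -1.0, 11.0])
def test_min_increase_rejects_invalid_steps(bad):
    with pytest.raises(ValueError):
        min_increase_for(bad)


def test_snap_edss_on_scale():
    assert snap_edss(0.4) == 0.0
    assert snap_edss(0.5) == 1.0  # 0.5 is not a valid step; ties resolve up
    assert snap_edss(2.74) == 2.5
    assert snap_edss(2.75) == 3.0
    assert snap_edss(12.0) == 10.0
    assert snap_edss(-0.3) == 0.0


class TestDetector:
    def test_simple_confirmed_worsening(self):
        ev = detect_confirmed_worsening(visits_df([(0, 2.0), (200, 3.0), (400, 3.0)]))
        assert len(ev) == 1
        e = ev[0]
        assert (e.onset_day, e.confirmation_day, e.reference_edss) == (200, 400, 2.0)

    def test_subthreshold_increase_is_not_an_event(self):
        ev = detect_confirmed_worsening(visits_df([(0, 2.0), (200, 2.5), (400, 2.5)]))
        assert ev == []

    def test_improvement_rebaselines_reference(self):
        ev = detect_confirmed_worsening(
            visits_df([(0, 3.0), (180, 2.0), (370, 2.0), (600, 3.0), (790, 3.0)])
        )
        assert len(ev) == 1
        e = ev[0]
        assert (e.reference_edss, e.reference_day) == (2.0, 370)
        assert (e.onset_day, e.confirmation_day) == (600, 790)

    def test_reference_zero_needs_1p5(self):
        assert detect_confirmed_worsening(
            visits_df([(0, 0.0), (200, 1.0), (400, 1.0)])
        ) == []
        ev = detect_confirmed_worsening(visits_df([(0, 0.0), (200, 1.5), (400, 1.5)]))
        assert len(ev) == 1

    def test_reference_above_5p5_needs_half_step(self):
        ev = detect_confirmed_worsening(visits_df([(0, 6.0), (200, 6.5), (400, 6.5)]))
        assert len(ev) == 1
        assert ev[0].reference_edss == 6.0

    def test_unsustained_worsening_not_confirmed(self):
        # dip below threshold between onset and confirmation
        ev = detect_confirmed_worsening(
            visits_df([(0, 2.0), (100, 3.0), (200, 2.0), (400, 3.0), (600, 3.0)])
        )
        assert all(e.onset_day != 100 for e in ev)

    def test_sustained_switch_relaxes_intervening_visits(self):
        v = visits_df([(0, 2.0), (100, 3.0), (200, 2.0), (300, 3.0)])
        assert detect_confirmed_worsening(v, sustained=True) == []
        relaxed = detect_confirmed_worsening(v, sustained=False)
        assert len(relaxed) == 1 and relaxed[0].onset_day == 100

    def test_reference_moves_to_confirmation_after_event(self):
        ev = detect_confirmed_worsening(
            visits_df([(0, 2.0), (200, 3.0), (400, 3.5), (600, 4.5), (800, 4.5)])
        )
        assert len(ev) == 2
        assert ev[1].reference_day == 400 and ev[1].reference_edss == 3.5

    def test_duplicate_day_rejected(self):
        with pytest.raises(EventDetectionError):
            detect_confirmed_worsening(visits_df([(0, 2.0), (0, 3.0), (200, 3.0)]))

    def test_row_order_invariance(self):
        v = visits_df([(0, 2.0), (200, 3.0), (400, 3.0), (700, 4.5), (900, 4.5)])
        shuffled = v.sample(frac=1.0, random_state=4)
        a = detect_confirmed_worsening(v)
        b = detect_confirmed_worsening(shuffled)
        assert [e.__dict__ for e in a] == [e.__dict__ for e in b]


class TestPiraClassification:
    def _event(self):
        v = visits_df([(0, 2.0), (200, 3.0), (400, 3.0)])
        return detect_confirmed_worsening(v)[0], v

    def test_relapse_before_onset_within_window_blocks(self):
        e, v = self._event()
        assert classify_pira(e, v, relapses_df([150])) is False

    def test_no_relapses_is_pira(self):
        e, v = self._event()
        assert classify_pira(e, v, relapses_df([])) is True

    def test_relapse_between_onset_and_confirmation_blocks(self):
        e, v = self._event()
        assert classify_pira(e, v, relapses_df([300])) is False

    def test_relapse_before_anchor_is_ignored(self):
        v = visits_df([(0, 2.0), (300, 2.0), (500, 3.0), (700, 3.0)])
        e = detect_confirmed_worsening(v)[0]
        # anchor = latest visit on/before day 410 -> day 300
        assert classify_pira(e, v, relapses_df([100])) is True
        assert classify_pira(e, v, relapses_df([300])) is False

    def test_anchor_fallback_flags_qc(self):
        v = visits_df([(0, 2.0), (60, 3.0), (400, 3.0)])
        e = detect_confirmed_worsening(v)[0]
        classify_pira(e, v, relapses_df([]))
        assert e.anchor_fallback is True

    def test_foreign_relapses_rejected(self):
        e, v = self._event()
        with pytest.raises(EventDetectionError):
            classify_pira(e, v, relapses_df([100], pid="OTHER"))

    def test_adding_relapse_never_creates_pira(self):
        # monotonicity: extra relapses can only remove PIRA status
        e, v = self._event()
        base = classify_pira(e, v, relapses_df([900]))
        more = classify_pira(e, v, relapses_df([900, 250]))
        assert (base, more) == (True, False)


class TestPirmaClassification:
    def _pira_event(self):
        v = visits_df([(0, 2.0), (200, 3.0), (400, 3.0)])
        e = detect_confirmed_worsening(v)[0]
        classify_pira(e, v, relapses_df([]))
        return e

    def test_flagged_mri_means_not_pirma(self):
        assert classify_pirma(self._pira_event(), mri_df([(300, 1)])) is False

    def test_clean_mri_means_pirma(self):
        assert classify_pirma(self._pira_event(), mri_df([(300, 0)])) is True

    def test_no_mri_in_window_indeterminate(self):
        assert classify_pirma(self._pira_event(), mri_df([(500, 0)])) is None

    def test_window_is_half_open(self):
        # MRI exactly at reference day excluded; at confirmation day included
        assert classify_pirma(self._pira_event(), mri_df([(0, 1)])) is None
        assert classify_pirma(self._pira_event(), mri_df([(400, 1)])) is False

    def test_requires_pira(self):
        v = visits_df([(0, 2.0), (200, 3.0), (400, 3.0)])
        e = detect_confirmed_worsening(v)[0]
        classify_pira(e, v, relapses_df([300]))
        with pytest.raises(EventDetectionError):
            classify_pirma(e, mri_df([(300, 0)]))

    def test_adding_flagged_mri_never_restores_pirma(self):
        e = self._pira_event()
        assert classify_pirma(e, mri_df([(300, 0), (350, 1)])) is False


def _events_frame(rows):
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


class TestSurvivalRecords:
    def _patients(self, disc=np.nan, last=1132):
        return pd.DataFrame(
            {
                "patient_id": ["P1"],
                "group": ["ocrelizumab"],
                "discontinuation_day": [disc],
                "last_visit_day": [last],
            }
        )

    def test_censored_at_last_visit(self):
        rec = build_survival_records(self._patients(), _events_frame([]))
        assert rec.iloc[0]["event"] == 0
        assert rec.iloc[0]["time_years"] == pytest.approx(1132 / 365.25, abs=1e-9)
        assert rec.iloc[0]["censor_reason"] == "last_visit"

    def test_event_time_is_onset_in_years(self):
        ev = _events_frame(
            [("P1", 365, 550, 2.0, 0, 3.0, True, "indeterminate", False)]
        )
        rec = build_survival_records(self._patients(), ev)
        assert rec.iloc[0]["event"] == 1
        assert rec.iloc[0]["time_years"] == pytest.approx(365 / 365.25)

    def test_discontinuation_censoring(self):
        rec = build_survival_records(
            self._patients(disc=700.0), _events_frame([])
        )
        assert rec.iloc[0]["censor_reason"] == "discontinuation"
        assert rec.iloc[0]["time_years"] == pytest.approx(700 / 365.25)

    def test_pre_treatment_onset_branches(self):
        ev = _events_frame([("P1", -30, 200, 2.0, -120, 3.0, True, "true", False)])
        off = build_survival_records(self._patients(), ev, onset_filter=False)
        assert off.iloc[0]["event"] == 1 and off.iloc[0]["time_years"] == 0.0
        on = build_survival_records(self._patients(), ev, onset_filter=True)
        assert on.iloc[0]["event"] == 0

    def test_pirma_indeterminate_default_censored(self):
        ev = _events_frame(
            [("P1", 365, 550, 2.0, 0, 3.0, True, "indeterminate", False)]
        )
        rec = build_survival_records(self._patients(), ev, endpoint="pirma")
        assert rec.iloc[0]["event"] == 0
        rec2 = build_survival_records(
            self._patients(), ev, endpoint="pirma", indeterminate_as_event=True
        )
        assert rec2.iloc[0]["event"] == 1

    def test_zero_visit_patient_excluded_with_warning(self):
        pts = pd.concat([self._patients(), self._patients()]).reset_index(drop=True)
        pts.loc[1, "patient_id"] = "P2"
        visits = visits_df([(0, 2.0), (400, 2.0)])
        with pytest.warns(UserWarning):
            rec = build_survival_records(
                pts, _events_frame([]), visits=visits
            )
        assert list(rec["patient_id"]) == ["P1"]


def _run_pair(points, window=180, sustained=True):
    got = detect_confirmed_worsening(visits_df(points), window, sustained)
    want = oracle_detect(points, window, sustained)
    assert len(got) == len(want)
    for g, w in zip(got, want):
        assert g.onset_day == w["onset_day"]
        assert g.confirmation_day == w["confirmation_day"]
        assert g.reference_day == w["reference_day"]
        assert g.reference_edss == w["reference_edss"]


@given(st.data())
@settings(max_examples=300, deadline=None, derandomize=True)
def test_detector_matches_oracle_property(data):
    """Sequential detector == exhaustive-search oracle on random walks."""
    seed = data.draw(st.integers(0, 2**31 - 1))
    from conftest import random_trajectory

    points, relapses = random_trajectory(np.random.default_rng(seed))
    _run_pair(points)
    # PIRA flags agree too
    v = visits_df(points)
    for e in detect_confirmed_worsening(v):
        got = classify_pira(e, v, relapses_df(relapses))
        want = oracle_pira(
            {"onset_day": e.onset_day, "confirmation_day": e.confirmation_day},
            [d for d, _ in points],
            relapses,
        )
        assert got == want


def test_threshold_soundness_on_simulated_cohort(small_cohort):
    """Every emitted event satisfies the threshold + window invariants."""
    ev = detect_events(small_cohort.visits, small_cohort.relapses, small_cohort.mri)
    assert len(ev) > 0
    for _, e in ev.iterrows():
        assert e["onset_edss"] - e["reference_edss"] >= min_increase_for(
            e["reference_edss"]
        )
        assert e["confirmation_day"] - e["onset_day"] >= 180
    # pirma set only for pira events
    assert (ev.loc[~ev["is_pira"], "is_pirma"] == "").all()
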