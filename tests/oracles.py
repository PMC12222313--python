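"""Independent brute-force oracles used to check the implementation.

Everything here is written from the rule definitions alone, in a different
style from the package (plain lists/tuples, exhaustive enumeration), and is
deliberately slow.
"""

from __future__ import annotations

import itertools
import math


def _threshold(ref_edss: float) -> float:
    if ref_edss == 0:
        return 1.5
    if ref_edss <= 5.5:
        return 1.0
    return 0.5


def oracle_detect(
    visits: list[tuple[int, float]],
    window: int = 180,
    sustained: bool = True,
) -> list[dict]:
    """Exhaustive-search confirmed-worsening detector.

    From the current reference visit, enumerate every (onset, confirmation)
    pair; a pair is a valid worsening if the onset exceeds the reference by
    the baseline-dependent threshold, the confirmation is the first visit at
    least ``window`` days after onset, and (if ``sustained``) every visit in
    between holds the threshold. Valid improvements (>= 0.5 below reference,
    sustained the same way) also move the reference. The chronologically
    first valid transition is applied and the search restarts from the new
    reference (the confirmation visit).
    """
    visits = sorted(visits)
    n = len(visits)
    events = []
    ref = 0
    while True:
        applied = None
        for onset in range(ref + 1, n):
            # enumerate all confirmation candidates; keep the earliest
            confs = [
                c
                for c in range(onset + 1, n)
                if visits[c][0] - visits[onset][0] >= window
            ]
            if not confs:
                continue
            conf = min(confs)
            between = range(onset + 1, conf + 1) if sustained else [conf]
            thr = _threshold(visits[ref][1])
            if visits[onset][1] - visits[ref][1] >= thr and all(
                visits[k][1] - visits[ref][1] >= thr for k in between
            ):
                applied = ("worsening", onset, conf)
                break
            if visits[ref][1] - visits[onset][1] >= 0.5 and all(
                visits[ref][1] - visits[k][1] >= 0.5 for k in between
            ):
                applied = ("improvement", onset, conf)
                break
        if applied is None:
            return events
        kind, onset, conf = applied
        if kind == "worsening":
            events.append(
                {
                    "onset_day": visits[onset][0],
                    "confirmation_day": visits[conf][0],
                    "reference_day": visits[ref][0],
                    "reference_edss": visits[ref][1],
                    "onset_edss": visits[onset][1],
                }
            )
        ref = conf


def oracle_pira(
    event: dict, visit_days: list[int], relapse_days: list[int], pre_window: int = 90
) -> bool:
    """Independent PIRA rule: no relapse in [anchor, confirmation]."""
    before = [d for d in sorted(visit_days) if d <= event["onset_day"] - pre_window]
    anchor = before[-1] if before else sorted(visit_days)[0]
    return not any(anchor <= r <= event["confirmation_day"] for r in relapse_days)


def cox_neg_log_partial_likelihood(
    beta: float, times: list[float], events: list[int], x: list[int]
) -> float:
    """Hand-written Cox partial likelihood (Efron ties) for one binary covariate."""
    nll = 0.0
    for t in sorted({t for t, e in zip(times, events) if e}):
        d_idx = [i for i in range(len(times)) if times[i] == t and events[i]]
        risk = [i for i in range(len(times)) if times[i] >= t]
        sum_risk = sum(math.exp(beta * x[i]) for i in risk)
        sum_tied = sum(math.exp(beta * x[i]) for i in d_idx)
        m = len(d_idx)
        nll -= sum(beta * x[i] for i in d_idx)
        for j in range(m):
            nll += math.log(sum_risk - (j / m) * sum_tied)
    return nll


def brute_force_cox_hr(times, events, x, lo=-5.0, hi=5.0, tol=1e-10) -> float:
    """Golden-section minimization of the hand-written partial likelihood."""
    gr = (math.sqrt(5) - 1) / 2
    a, b = lo, hi
    c, d = b - gr * (b - a), a + gr * (b - a)
    while b - a > tol:
        if cox_neg_log_partial_likelihood(c, times, events, x) < \
           cox_neg_log_partial_likelihood(d, times, events, x):
            b = d
        else:
            a = c
        c, d = b - gr * (b - a), a + gr * (b - a)
    return math.exp((a + b) / 2)


def km_hand(times: list[float], events: list[int]) -> list[tuple[float, float]]:
    """Product-limit estimator computed longhand: (time, S(time)) at each
    distinct observed time."""
    order = sorted(set(times))
    s = 1.0
    out = []
    for t in order:
        at_risk = sum(1 for ti in times if ti >= t)
        deaths = sum(1 for ti, ei in zip(times, events) if ti == t and ei)
        if at_risk > 0:
            s *= 1.0 - deaths / at_risk
        out.append((t, s))
    return out


def mwu_exhaustive(a: list[float], b: list[float]) -> tuple[float, float]:
    """Mann-Whitney U and exact two-sided p by enumerating all group labelings."""
    def u_stat(xs, ys):
        u = 0.0
        for x in xs:
            for y in ys:
                u += 1.0 if x > y else (0.5 if x == y else 0.0)
        return u

    u_obs = u_stat(a, b)
    pooled = list(a) + list(b)
    n_a = len(a)
    total = 0
    extreme = 0
    mu = len(a) * len(b) / 2.0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_stat(xs, ys) - mu) >= abs(u_obs - mu) - 1e-12:
            extreme += 1
    return u_obs, extreme / total


def smd_textbook(a: list[float], b: list[float]) -> float:
    ma = sum(a) / len(a)
    mb = sum(b) / len(b)
    va = sum((x - ma) ** 2 for x in a) / (len(a) - 1)
    vb = sum((x - mb) ** 2 for x in b) / (len(b) - 1)
    return (ma - mb) / math.sqrt((va + vb) / 2.0)
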