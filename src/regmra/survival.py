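"""Kaplan–Meier estimation, log-rank testing and regulon-activity stratification.

Samples are split at the median of each regulon's per-sample activity
(strictly above the median -> "high", at or below -> "low"), overall
survival of the two groups is compared with the standard unweighted
log-rank test, and the prognostic direction (good/bad when activated) is
read from the Kaplan–Meier median survival of the two groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, false_discovery_control

logger = logging.getLogger("regmra")

__all__ = [
    "SurvivalRecord",
    "KMCurve",
    "LogRankResult",
    "records_to_frame",
    "frame_to_records",
    "km_estimate",
    "km_median",
    "km_area",
    "logrank_test",
    "median_split",
    "survival_screen",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """One sample's follow-up: time > 0, event 1 = death observed, 0 = censored."""

    sample: str
    time: float
    event: int

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"non-positive follow-up time for {self.sample}")
        if self.event not in (0, 1):
            raise ValueError(f"event flag must be 0 or 1 for {self.sample}")


@dataclass
class KMCurve:
    """Kaplan–Meier curve: S(t) drops only at observed event times."""

    times: np.ndarray      # distinct event times, ascending
    n_risk: np.ndarray     # at-risk counts just before each event time
    d_events: np.ndarray   # events at each time
    survival: np.ndarray   # S(t_i)

    def survival_at(self, t: float) -> float:
        """Step-function evaluation; S = 1 before the first event."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogRankResult:
    observed: np.ndarray   # O per group
    expected: np.ndarray   # E per group
    variance: float
    chi2: float
    p: float


def records_to_frame(records: list[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.sample, r.time, r.event) for r in records],
        columns=["sample", "time", "event"],
    )


def frame_to_records(frame: pd.DataFrame) -> list[SurvivalRecord]:
    return [
        SurvivalRecord(sample=str(s), time=float(t), event=int(e))
        for s, t, e in frame[["sample", "time", "event"]].itertuples(index=False)
    ]


def _to_arrays(records) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(records, pd.DataFrame):
        records = frame_to_records(records)
    t = np.array([r.time for r in records], dtype=float)
    e = np.array([r.event for r in records], dtype=int)
    if len(t) == 0:
        raise ValueError("no survival records")
    return t, e


def km_estimate(records) -> KMCurve:
    """Product-limit estimator S(t) = prod_{t_i <= t} (1 - d_i / n_i).

    Censored observations reduce the risk set without producing a drop.
    """
    t, e = _to_arrays(records)
    event_times = np.unique(t[e == 1])
    n_risk = np.array([(t >= ti).sum() for ti in event_times], dtype=float)
    d = np.array([((t == ti) & (e == 1)).sum() for ti in event_times], dtype=float)
    surv = np.cumprod(1.0 - d / n_risk) if len(event_times) else np.array([])
    return KMCurve(times=event_times, n_risk=n_risk, d_events=d, survival=surv)


def km_median(curve: KMCurve) -> float:
    """Smallest t with S(t) <= 0.5; +inf if the curve never reaches 0.5."""
    below = np.nonzero(curve.survival <= 0.5)[0]
    return float(curve.times[below[0]]) if below.size else float("inf")


def km_area(curve: KMCurve, tau: float) -> float:
    """Restricted mean survival time: area under S(t) on [0, tau]."""
    area, prev_t, prev_s = 0.0, 0.0, 1.0
    for t, s in zip(curve.times, curve.survival):
        if t > tau:
            break
        area += prev_s * (t - prev_t)
        prev_t, prev_s = t, s
    area += prev_s * max(tau - prev_t, 0.0)
    return area


def logrank_test(group_a, group_b) -> LogRankResult:
    """Standard (unweighted) two-group log-rank test, 1 df.

    Accumulates observed minus expected events over the pooled distinct
    event times with the hypergeometric variance. Zero total variance (no
    information) yields NaN chi-square/p with a warning.
    """
    ta, ea = _to_arrays(group_a)
    tb, eb = _to_arrays(group_b)
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    g = np.concatenate([np.zeros(ta.size, dtype=int), np.ones(tb.size, dtype=int)])
    if e.sum() == 0:
        raise ValueError("log-rank test needs at least one event")

    event_times = np.unique(t[e == 1])
    o = np.zeros(2)
    exp = np.zeros(2)
    var = 0.0
    for ti in event_times:
        at_risk = t >= ti
        n_j = at_risk.sum()
        n1 = (at_risk & (g == 0)).sum()
        dead = (t == ti) & (e == 1)
        d_j = dead.sum()
        d1 = (dead & (g == 0)).sum()
        o[0] += d1
        o[1] += d_j - d1
        e1 = d_j * n1 / n_j
        exp[0] += e1
        exp[1] += d_j - e1
        if n_j > 1:
            var += d_j * (n1 / n_j) * (1 - n1 / n_j) * (n_j - d_j) / (n_j - 1)

    if var <= 0:
        logger.warning("log-rank variance is zero; test undefined")
        return LogRankResult(o, exp, 0.0, float("nan"), float("nan"))
    stat = (o[0] - exp[0]) ** 2 / var
    return LogRankResult(o, exp, float(var), float(stat), float(chi2.sf(stat, 1)))


def median_split(activity_row: pd.Series) -> pd.Series:
    """High/low labels at the median of a regulon's per-sample activity.

    Strictly above the median -> "high"; at or below -> "low" (ties at the
    median therefore fall in the low group). Requires >= 4 samples and a
    non-degenerate activity vector.
    """
    x = activity_row.astype(float)
    if x.size < 4:
        raise ValueError("median split needs at least 4 samples")
    if x.nunique() == 1:
        raise ValueError("all activities equal; no split possible")
    med = float(np.median(x.to_numpy()))
    return pd.Series(np.where(x > med, "high", "low"), index=x.index, name="group")


def survival_screen(
    activity,
    records,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Median-split + log-rank for every regulon in an activity matrix.

    ``activity`` is a regulon x sample DataFrame (or an object exposing
    ``.des`` with that shape). Direction compares Kaplan–Meier median
    survival of the high versus low groups ("good" = high-activity samples
    survive longer); when both medians are undefined or equal, the restricted
    mean survival time breaks the tie. Raw and BH-adjusted p-values are both
    reported; regulons with an undefined split are skipped with a warning.
    """
    des = getattr(activity, "des", activity)
    if isinstance(records, pd.DataFrame):
        records = frame_to_records(records)
    by_sample = {r.sample: r for r in records}
    shared = [s for s in des.columns if s in by_sample]
    if len(shared) < 4:
        raise ValueError("fewer than 4 samples shared between activity and records")

    rows = []
    for regulon, row in des[shared].iterrows():
        row = row.dropna()
        try:
            groups = median_split(row)
        except ValueError as err:
            logger.warning("regulon %s skipped in survival screen: %s", regulon, err)
            continue
        high = [by_sample[s] for s in groups.index[groups == "high"]]
        low = [by_sample[s] for s in groups.index[groups == "low"]]
        res = logrank_test(high, low)
        km_h, km_l = km_estimate(high), km_estimate(low)
        med_h, med_l = km_median(km_h), km_median(km_l)
        if med_h == med_l:
            tau = max(r.time for r in high + low)
            med_h, med_l = km_area(km_h, tau), km_area(km_l, tau)
        if med_h > med_l:
            direction = "good"
        elif med_h < med_l:
            direction = "bad"
        else:
            direction = "none"
        rows.append(
            (regulon, res.chi2, res.p, len(high), len(low), direction)
        )
    out = pd.DataFrame(
        rows, columns=["regulon", "chi2", "p", "n_high", "n_low", "direction"]
    )
    if not out.empty:
        finite = out["p"].notna()
        adj = np.full(len(out), np.nan)
        if finite.any():
            adj[finite.to_numpy()] = false_discovery_control(
                out.loc[finite, "p"].to_numpy(), method="bh"
            )
        out.insert(3, "p_adj", adj)
        out["significant"] = out["p"] < alpha
    return out
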