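"""Time-to-onset: days from therapy start to the adverse event.

Onset is computed per drug–event pair as

    time to onset = event date - therapy start date   (whole days)

and only when both dates are known to day precision and the event does not
precede the start.  Every excluded pair is tallied by reason (missing
event date, missing start date, partial precision, negative duration), so
the input always reconciles: included + excluded = total.

Summaries report the median and quartiles (linear interpolation) and the
cumulative proportion of events on or before fixed landmark days
(30, 60, 90, 180, 360), i.e. 1/2/3/6/12 months at 30-day months.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .faers_io import parse_partial_date

DEFAULT_LANDMARKS = (30, 60, 90, 180, 360)


@dataclass
class OnsetExclusions:
    missing_event: int = 0
    missing_start: int = 0
    partial_precision: int = 0
    negative: int = 0

    @property
    def total(self) -> int:
        return self.missing_event + self.missing_start + self.partial_precision + self.negative


@dataclass
class OnsetSummary:
    n: int
    median_days: float | None
    q1_days: float | None
    q3_days: float | None
    cumulative: dict[int, float] = field(default_factory=dict)


def compute_durations(
    pairs: pd.DataFrame,
    event_column: str = "event_dt",
    start_column: str = "therapy_start",
) -> tuple[np.ndarray, OnsetExclusions]:
    """Durations in days for pairs with fully-dated event and therapy start.

    Dates arrive as FAERS-style digit strings (yyyymmdd, possibly truncated
    to yyyymm / yyyy); anything short of day precision is excluded as
    "partial precision", and event-before-start pairs are excluded as
    negative rather than clipped.
    """
    excl = OnsetExclusions()
    durations: list[int] = []
    for ev_raw, st_raw in zip(pairs[event_column].fillna(""), pairs[start_column].fillna("")):
        ev = parse_partial_date(str(ev_raw))
        st = parse_partial_date(str(st_raw))
        if ev is None:
            excl.missing_event += 1
            continue
        if st is None:
            excl.missing_start += 1
            continue
        if ev.precision != "day" or st.precision != "day":
            excl.partial_precision += 1
            continue
        days = (ev.to_date() - st.to_date()).days
        if days < 0:
            excl.negative += 1
            continue
        durations.append(days)
    return np.asarray(durations, dtype=float), excl


def summarize_onset(durations: np.ndarray, landmarks=DEFAULT_LANDMARKS) -> OnsetSummary:
    """Median, quartiles (linear-interpolation / type-7) and landmark proportions."""
    durations = np.asarray(durations, dtype=float)
    n = durations.size
    if n == 0:
        return OnsetSummary(n=0, median_days=None, q1_days=None, q3_days=None,
                            cumulative={int(l): 0.0 for l in landmarks})
    q1, med, q3 = np.percentile(durations, [25, 50, 75])
    cumulative = {int(l): float(np.mean(durations <= l)) for l in landmarks}
    return OnsetSummary(n=int(n), median_days=float(med), q1_days=float(q1),
                        q3_days=float(q3), cumulative=cumulative)


def onset_by_class(
    pairs: pd.DataFrame,
    event_dict,
    landmarks=DEFAULT_LANDMARKS,
) -> pd.DataFrame:
    """Per-event-class onset summary table (plus an 'All respiratory' row)."""
    rows = []

    def _row(name: str, subset: pd.DataFrame) -> dict:
        durations, excl = compute_durations(subset)
        s = summarize_onset(durations, landmarks)
        rec = {
            "event_class": name, "n_pairs": len(subset), "n_dated": s.n,
            "n_excluded": excl.total,
            "median_days": s.median_days, "q1_days": s.q1_days, "q3_days": s.q3_days,
        }
        for l in landmarks:
            rec[f"cum_{int(l)}d"] = s.cumulative[int(l)]
        return rec

    rows.append(_row("All respiratory", pairs[pairs["pt"].isin(event_dict.all_pts)]))
    for cname in event_dict.class_names:
        rows.append(_row(cname, pairs[pairs["pt"].isin(event_dict.pts_in_class(cname))]))
    return pd.DataFrame(rows)
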