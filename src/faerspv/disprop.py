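"""Shrinkage disproportionality statistics: ROR, information component, intervals.

Signal detection in a spontaneous reporting system compares the observed
count of a drug–event combination with the count expected if drug and
event were reported independently across the whole database:

    N_expected = N_drug * N_event / N_total
    ROR        = (N_observed + 0.5) / (N_expected + 0.5)
    IC         = log2(ROR)

The +0.5 additive shrinkage (the WHO Uppsala Monitoring Centre convention)
pulls small-count estimates toward the null and keeps both statistics
defined at zero observed counts.  Note this "ROR" is a shrunk
observed-to-expected ratio, not the classic 2x2 reporting odds ratio; the
classic odds ratio is provided separately for subgroup contrasts.

95% credibility bounds for the IC use the UMC closed-form approximation

    IC025 = IC - 3.3 (N_obs+0.5)^(-1/2) - 2   (N_obs+0.5)^(-3/2)
    IC975 = IC + 2.4 (N_obs+0.5)^(-1/2) - 0.5 (N_obs+0.5)^(-3/2)

ROR bounds default to the IC-consistent transform (2**IC025, 2**IC975);
a Wald interval on the reconstructed 2x2 table is available for
comparability with classic ROR analyses.

A combination is a signal when the lower interval bound excludes the null
(ROR025 > 1, equivalently IC025 > 0; both strict).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ContingencyCounts",
    "SignalResult",
    "SubgroupResult",
    "build_contingency",
    "expected_count",
    "shrunk_ror",
    "information_component",
    "ic_credibility_interval",
    "ic_interval",
    "ror_interval",
    "signal_flags",
    "compute_signal",
    "signal_table",
    "subgroup_ror",
    "round_half_up",
]

IntervalMethod = Literal["umc", "wald"]

Z_95 = float(sps.norm.ppf(0.975))


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of printed report tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ContingencyCounts:
    """Pair-level counts for one drug-set x event-set combination."""

    n_observed: int  # target drug AND target event
    n_drug: int      # any pair of the target drug(s)
    n_event: int     # target event with any drug
    n_total: int     # all pairs in the universe

    def __post_init__(self) -> None:
        if not (0 <= self.n_observed <= min(self.n_drug, self.n_event) <= self.n_total):
            raise ValueError(f"inconsistent contingency counts: {self}")

    def cells_2x2(self) -> tuple[int, int, int, int]:
        """Reconstructed 2x2 cells (a, b, c, d) = (D&E, D&!E, !D&E, !D&!E)."""
        a = self.n_observed
        b = self.n_drug - a
        c = self.n_event - a
        d = self.n_total - self.n_drug - self.n_event + a
        return a, b, c, d


@dataclass(frozen=True)
class SignalResult:
    counts: ContingencyCounts
    n_expected: float
    ror: float
    ror_025: float
    ror_975: float
    ic: float
    ic_025: float
    ic_975: float
    signal_ror: bool
    signal_ic: bool

    @property
    def signal(self) -> bool:
        """The published criterion: either lower bound excludes the null."""
        return self.signal_ror or self.signal_ic


def expected_count(c: ContingencyCounts) -> float:
    """N_expected = N_drug * N_event / N_total under independence."""
    if c.n_total == 0:
        raise ValueError("empty universe: n_total = 0")
    return c.n_drug * c.n_event / c.n_total


def shrunk_ror(c: ContingencyCounts) -> float:
    """(N_observed + 0.5) / (N_expected + 0.5)."""
    return (c.n_observed + 0.5) / (expected_count(c) + 0.5)


def information_component(c: ContingencyCounts) -> float:
    """IC = log2 of the shrunk observed/expected ratio, in bits."""
    return math.log2(shrunk_ror(c))


def ic_credibility_interval(ic: float, n_observed: float) -> tuple[float, float]:
    """UMC closed-form 95% credibility bounds around a given IC.

    ``n_observed`` is the raw observed count; the formulas act on the
    shrunk count n_observed + 0.5.  Exposed separately from
    :func:`ic_interval` so the approximation can also be applied to an IC
    derived from a printed ROR.
    """
    n = n_observed + 0.5
    lo = ic - 3.3 * n ** -0.5 - 2.0 * n ** -1.5
    hi = ic + 2.4 * n ** -0.5 - 0.5 * n ** -1.5
    return lo, hi


def ic_interval(c: ContingencyCounts) -> tuple[float, float]:
    """95% credibility interval of the IC for one contingency."""
    return ic_credibility_interval(information_component(c), c.n_observed)


def ror_interval(c: ContingencyCounts, method: IntervalMethod = "umc") -> tuple[float, float]:
    """95% interval for the shrunk ROR.

    ``"umc"`` (default) transforms the IC bounds: (2**IC025, 2**IC975), the
    natural interval for a shrunk observed/expected ratio.  ``"wald"``
    computes exp(ln OR +- z sqrt(1/a+1/b+1/c+1/d)) on the reconstructed
    2x2 table; a non-positive cell makes the interval undefined, signalled
    by (nan, nan).
    """
    if method == "umc":
        lo, hi = ic_interval(c)
        return 2.0 ** lo, 2.0 ** hi
    if method == "wald":
        a, b, cc, d = c.cells_2x2()
        if min(a, b, cc, d) <= 0:
            return math.nan, math.nan
        or_ = (a * d) / (b * cc)
        se = math.sqrt(1 / a + 1 / b + 1 / cc + 1 / d)
        return or_ * math.exp(-Z_95 * se), or_ * math.exp(Z_95 * se)
    raise ValueError(f"unknown interval method {method!r}")


def signal_flags(ror_025: float, ic_025: float) -> tuple[bool, bool]:
    """Strict threshold flags: ROR025 > 1 and IC025 > 0."""
    return ror_025 > 1.0, ic_025 > 0.0


def compute_signal(c: ContingencyCounts, interval_method: IntervalMethod = "umc") -> SignalResult:
    """Assemble the full signal statistics for one contingency."""
    n_exp = expected_count(c)
    ror = shrunk_ror(c)
    ic = math.log2(ror)
    ic_lo, ic_hi = ic_credibility_interval(ic, c.n_observed)
    ror_lo, ror_hi = ror_interval(c, method=interval_method)
    flag_ror, flag_ic = signal_flags(ror_lo, ic_lo)
    return SignalResult(
        counts=c, n_expected=n_exp, ror=ror, ror_025=ror_lo, ror_975=ror_hi,
        ic=ic, ic_025=ic_lo, ic_975=ic_hi, signal_ror=flag_ror, signal_ic=flag_ic,
    )


def build_contingency(
    pairs: pd.DataFrame,
    target_drugs: Iterable[str],
    target_events: Iterable[str],
    drug_column: str = "drug",
    event_column: str = "pt",
) -> ContingencyCounts:
    """Count pairs for one drug-set x event-set combination.

    ``pairs`` is the full deduplicated pair universe (all drugs, all
    events); counting is at the pair level.
    """
    if len(pairs) == 0:
        raise ValueError("empty pair universe")
    target_drugs = set(target_drugs)
    target_events = set(target_events)
    if not target_drugs or not target_events:
        raise ValueError("target drug and event sets must be non-empty")
    in_drug = pairs[drug_column].isin(target_drugs)
    in_event = pairs[event_column].isin(target_events)
    return ContingencyCounts(
        n_observed=int((in_drug & in_event).sum()),
        n_drug=int(in_drug.sum()),
        n_event=int(in_event.sum()),
        n_total=int(len(pairs)),
    )


def signal_table(
    pairs: pd.DataFrame,
    drug_sets: dict[str, set[str]],
    event_sets: dict[str, set[str]],
    interval_method: IntervalMethod = "umc",
    drug_column: str = "drug",
    event_column: str = "pt",
) -> pd.DataFrame:
    """Tidy table of signal statistics for every drug-set x event-set combination.

    One row per (drug set, event set), with counts, expected count, shrunk
    ROR and IC with 95% bounds, and both signal flags.
    """
    records = []
    n_total = len(pairs)
    drug_masks = {name: pairs[drug_column].isin(ds).to_numpy() for name, ds in drug_sets.items()}
    event_masks = {name: pairs[event_column].isin(es).to_numpy() for name, es in event_sets.items()}
    for dname, dmask in drug_masks.items():
        n_drug = int(dmask.sum())
        for ename, emask in event_masks.items():
            c = ContingencyCounts(
                n_observed=int(np.sum(dmask & emask)),
                n_drug=n_drug,
                n_event=int(emask.sum()),
                n_total=n_total,
            )
            r = compute_signal(c, interval_method=interval_method)
            records.append({
                "drug_set": dname, "event_set": ename,
                "n_observed": c.n_observed, "n_drug": c.n_drug,
                "n_event": c.n_event, "n_total": c.n_total,
                "n_expected": r.n_expected,
                "ror": r.ror, "ror_025": r.ror_025, "ror_975": r.ror_975,
                "ic": r.ic, "ic_025": r.ic_025, "ic_975": r.ic_975,
                "signal_ror": r.signal_ror, "signal_ic": r.signal_ic,
                "signal": r.signal,
            })
    return pd.DataFrame.from_records(records)


@dataclass(frozen=True)
class SubgroupResult:
    """Classic 2x2 reporting odds ratio for a subgroup contrast.

    The table compares stratum level_a vs level_b (rows) across ICI vs
    other-drug pairs (columns), restricted to the event set:

        OR = (a/b) / (c/d),  a = ICI & level_a, b = ICI & level_b,
                             c = other & level_a, d = other & level_b

    with a Wald 95% CI on the log OR.  When any cell is zero the Haldane
    continuity correction (+0.5 to all cells) is applied and flagged.
    """

    odds_ratio: float
    ci_low: float
    ci_high: float
    a: int
    b: int
    c: int
    d: int
    continuity_corrected: bool
    formula: str = "OR = (a/b)/(c/d); Wald CI exp(ln OR +- 1.96 se), se = sqrt(1/a+1/b+1/c+1/d)"


def odds_ratio_2x2(a: int, b: int, c: int, d: int) -> SubgroupResult:
    """Wald odds ratio for an explicit 2x2 table (a/b vs c/d)."""
    corrected = min(a, b, c, d) == 0
    aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d)) if corrected else (a, b, c, d)
    or_ = (aa / bb) / (cc / dd)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    return SubgroupResult(
        odds_ratio=or_, ci_low=or_ * math.exp(-Z_95 * se), ci_high=or_ * math.exp(Z_95 * se),
        a=a, b=b, c=c, d=d, continuity_corrected=corrected,
    )


def subgroup_ror(
    pairs: pd.DataFrame,
    stratifier: str,
    level_a,
    level_b,
    event_set: Iterable[str],
    ici_mask_column: str = "ici_class",
) -> SubgroupResult:
    """Subgroup contrast (e.g. men vs women) for an event set, ICI vs other drugs.

    ``stratifier`` is a pair-table column (``sex``, ``age_group``,
    ``death`` ...); rows with values outside {level_a, level_b} are
    excluded.  ICI pairs are those with a non-empty ``ici_class``.
    """
    sub = pairs[pairs["pt"].isin(set(event_set))]
    strat = sub[stratifier]
    sub = sub[strat.isin([level_a, level_b])]
    is_ici = sub[ici_mask_column] != ""
    is_a = sub[stratifier] == level_a
    a = int((is_ici & is_a).sum())
    b = int((is_ici & ~is_a).sum())
    c = int((~is_ici & is_a).sum())
    d = int((~is_ici & ~is_a).sum())
    return odds_ratio_2x2(a, b, c, d)
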