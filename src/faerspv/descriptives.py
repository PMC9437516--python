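"""Baseline characteristics and outcome tables for the pair-level corpus.

Two group-comparison products mirror a standard pharmacovigilance report:

* a characteristics table (sex, age group, receipt year, outcome, country)
  for the ICI group against the other-drug control group, with counts and
  within-group percentages (computed over the full group including the
  explicit ``Missing`` level, so each dimension sums to 100%);
* per-event-class death / life-threatening proportions.

The outcome dimension of the characteristics table assigns each record a
single level by severity precedence DE > LT > DS > HO > CA > RI > OT, so
the column sums to the group total; the per-class death proportions
instead use marginal presence of the death code DE.
"""

from __future__ import annotations

import pandas as pd

OUTCOME_LABELS = {
    "DE": "Death",
    "LT": "Life-threatening",
    "DS": "Disability",
    "HO": "Hospitalization",
    "CA": "Congenital anomaly",
    "RI": "Required intervention",
    "OT": "Other serious",
    "Missing": "Missing",
}

#: the named reporting countries of the characteristics table (ISO-ish codes
#: as they appear in FAERS OCCR_COUNTRY), everything else -> Others
NAMED_COUNTRIES = {
    "US": "United States", "JP": "Japan", "FR": "France", "DE": "Germany",
    "IT": "Italy", "GB": "Great Britain", "CA": "Canada", "ES": "Spain",
    "AU": "Australia", "NL": "Netherlands",
}


def _country_level(code: str) -> str:
    if code in ("", "Missing"):
        return "Missing"
    return NAMED_COUNTRIES.get(code, "Others")


def _dimension_levels(pairs: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame(index=pairs.index)
    out["sex"] = pairs["sex"].map({"M": "Men", "F": "Women"}).fillna("Missing")
    out["age_group"] = pairs["age_group"].map(
        {">=70": ">=70 years", "<70": "<70 years"}).fillna("Missing")
    out["year"] = pairs["year"].map(lambda y: str(int(y)) if pd.notna(y) else "Missing")
    out["outcome"] = pairs["outcome_primary"].map(OUTCOME_LABELS).fillna("Missing")
    out["country"] = pairs["country"].map(_country_level)
    return out


def percentage(count: int, total: int, ndigits: int = 2) -> float:
    """count/total as a percentage; 0.0 for an empty group (no division error)."""
    if total == 0:
        return 0.0
    return round(100.0 * count / total, ndigits)


def characteristics(ici_pairs: pd.DataFrame, other_pairs: pd.DataFrame) -> pd.DataFrame:
    """Baseline characteristics of the ICI group vs the other-drug group.

    One row per (dimension, level) with counts and within-group
    percentages; every dimension includes an explicit Missing level and
    its counts sum to the group total.
    """
    n_ici, n_other = len(ici_pairs), len(other_pairs)
    lv_ici = _dimension_levels(ici_pairs) if n_ici else None
    lv_other = _dimension_levels(other_pairs) if n_other else None

    rows = []
    for dim in ("sex", "age_group", "year", "outcome", "country"):
        counts_ici = lv_ici[dim].value_counts() if lv_ici is not None else pd.Series(dtype=int)
        counts_other = lv_other[dim].value_counts() if lv_other is not None else pd.Series(dtype=int)
        levels = sorted(set(counts_ici.index) | set(counts_other.index),
                        key=lambda l: (l == "Missing", l == "Others", l))
        for level in levels:
            ci = int(counts_ici.get(level, 0))
            co = int(counts_other.get(level, 0))
            rows.append({
                "dimension": dim, "level": level,
                "count_ici": ci, "pct_ici": percentage(ci, n_ici),
                "count_other": co, "pct_other": percentage(co, n_other),
            })
    return pd.DataFrame(rows)


def death_proportions(pairs: pd.DataFrame, event_dict) -> pd.DataFrame:
    """Per-event-class record counts with death and life-threatening proportions.

    Death is marginal presence of outcome code DE (whatever else the record
    carries); life-threatening is primary-level LT under the severity
    precedence, matching the single-assignment outcome breakdown.
    """
    rows = []

    def _row(name: str, subset: pd.DataFrame) -> dict:
        n = len(subset)
        deaths = int(subset["death"].sum())
        lt = int((subset["outcome_primary"] == "LT").sum())
        return {
            "event_class": name, "n": n,
            "deaths": deaths, "death_pct": percentage(deaths, n),
            "life_threatening": lt, "lt_pct": percentage(lt, n),
        }

    rows.append(_row("All respiratory", pairs[pairs["pt"].isin(event_dict.all_pts)]))
    for cname in event_dict.class_names:
        rows.append(_row(cname, pairs[pairs["pt"].isin(event_dict.pts_in_class(cname))]))
    return pd.DataFrame(rows)


def reporting_rate(n_class: int, n_corpus: int, ndigits: int = 2) -> float:
    """Class share of the corpus as a percentage (e.g. a 0.12% reporting rate)."""
    return percentage(n_class, n_corpus, ndigits)
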