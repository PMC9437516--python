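"""Reading FAERS-style quarterly ASCII tables into a normalized report model.

The public FAERS quarterly extracts ship five '$'-delimited tables per
quarter (DEMO, DRUG, REAC, OUTC, THER), keyed by PRIMARYID (one row set per
report *version*) and CASEID (one per case).  This module parses those
tables, trims and uppercases text fields, normalizes ages to years, retains
partially-specified dates (yyyymm / yyyy) instead of discarding them, and
joins the five tables into one :class:`CaseReport` per DEMO row.

Nothing here deduplicates: multiple versions of the same case survive
assembly and are collapsed later by :mod:`faerspv.dedup`.
"""

from __future__ import annotations

import calendar
import datetime as _dt
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "PartialDate",
    "DrugEntry",
    "CaseReport",
    "RawQuarter",
    "AssemblyStats",
    "parse_partial_date",
    "normalize_text",
    "age_to_years",
    "read_table",
    "read_quarter",
    "assemble_reports",
]


class FormatError(ValueError):
    """A FAERS table does not match the expected ASCII dialect."""


#: minimum required columns per table role
REQUIRED_COLUMNS = {
    "DEMO": ["PRIMARYID", "CASEID", "FDA_DT", "EVENT_DT", "AGE", "AGE_COD", "SEX", "OCCR_COUNTRY"],
    "DRUG": ["PRIMARYID", "DRUG_SEQ", "ROLE_COD", "DRUGNAME", "PROD_AI"],
    "REAC": ["PRIMARYID", "PT"],
    "OUTC": ["PRIMARYID", "OUTC_COD"],
    "THER": ["PRIMARYID", "DSG_DRUG_SEQ", "START_DT"],
}

#: FAERS AGE_COD units -> factor converting AGE to years
AGE_UNIT_TO_YEARS = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.143,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

OUTCOME_CODES = ("DE", "LT", "DS", "HO", "CA", "OT", "RI")

_WS = re.compile(r"\s+")


def normalize_text(value: str) -> str:
    """Uppercase and collapse internal whitespace (FAERS verbatim fields are messy)."""
    return _WS.sub(" ", value.strip()).upper()


@dataclass(frozen=True, order=True)
class PartialDate:
    """A FAERS date (yyyymmdd) that may be truncated to month or year.

    Ordering compares (year, month or 0, day or 0), so an undated component
    sorts before any dated one within the same year/month.
    """

    year: int
    month: int | None = None
    day: int | None = None

    def __post_init__(self) -> None:
        if self.month is not None and not 1 <= self.month <= 12:
            raise ValueError(f"month out of range: {self.month}")
        if self.day is not None:
            if self.month is None:
                raise ValueError("day precision requires a month")
            if not 1 <= self.day <= calendar.monthrange(self.year, self.month)[1]:
                raise ValueError(f"invalid day {self.day} for {self.year}-{self.month}")

    @property
    def precision(self) -> str:
        if self.day is not None:
            return "day"
        if self.month is not None:
            return "month"
        return "year"

    def sort_key(self) -> tuple[int, int, int]:
        return (self.year, self.month or 0, self.day or 0)

    def to_date(self) -> _dt.date:
        if self.precision != "day":
            raise ValueError(f"not a full date: {self}")
        return _dt.date(self.year, self.month, self.day)  # type: ignore[arg-type]

    def __str__(self) -> str:  # yyyymmdd / yyyymm / yyyy
        out = f"{self.year:04d}"
        if self.month is not None:
            out += f"{self.month:02d}"
        if self.day is not None:
            out += f"{self.day:02d}"
        return out


def parse_partial_date(raw: str | None, counters: dict[str, int] | None = None) -> PartialDate | None:
    """Parse a FAERS date string (8, 6 or 4 digits) into a :class:`PartialDate`.

    Lenient by contract: blank input and malformed values map to ``None``;
    invalid calendar values (e.g. day 30 of February) also map to ``None``
    and increment ``counters['invalid_date']`` when a counter dict is given.
    """
    if raw is None:
        return None
    raw = raw.strip()
    if not raw:
        return None
    if not raw.isdigit() or len(raw) not in (4, 6, 8):
        if counters is not None:
            counters["invalid_date"] = counters.get("invalid_date", 0) + 1
        return None
    try:
        year = int(raw[:4])
        month = int(raw[4:6]) if len(raw) >= 6 else None
        day = int(raw[6:8]) if len(raw) == 8 else None
        if month == 0:
            month, day = None, None
        elif day == 0:
            day = None
        return PartialDate(year, month, day)
    except ValueError:
        if counters is not None:
            counters["invalid_date"] = counters.get("invalid_date", 0) + 1
        return None


def age_to_years(age_raw: str, age_cod: str) -> float | None:
    """Convert FAERS AGE + AGE_COD to years; missing unit is read as years.

    Values outside the plausible [0, 130] range are treated as missing.
    """
    age_raw = age_raw.strip()
    if not age_raw:
        return None
    try:
        age = float(age_raw)
    except ValueError:
        return None
    factor = AGE_UNIT_TO_YEARS.get(normalize_text(age_cod) or "YR")
    if factor is None:
        factor = 1.0
    years = age * factor
    if not 0.0 <= years <= 130.0:
        return None
    return years


@dataclass
class DrugEntry:
    """One DRUG row attached to a report."""

    drug_seq: int
    role: str  # PS / SS / C / I
    verbatim_name: str
    active_ingredient: str | None = None
    therapy_start: PartialDate | None = None


@dataclass
class CaseReport:
    """One (not yet deduplicated) safety report."""

    primaryid: str
    caseid: str
    fda_dt: PartialDate | None
    event_dt: PartialDate | None
    age_years: float | None
    sex: str  # 'M' / 'F' / 'unknown'
    country: str | None
    drugs: list[DrugEntry] = field(default_factory=list)
    reactions: list[str] = field(default_factory=list)
    outcomes: set[str] = field(default_factory=set)

    @property
    def received_year(self) -> int | None:
        return self.fda_dt.year if self.fda_dt is not None else None


@dataclass
class RawQuarter:
    """All rows of one quarter, as uppercase-keyed field maps."""

    quarter_label: str
    demo_rows: list[dict[str, str]]
    drug_rows: list[dict[str, str]]
    reac_rows: list[dict[str, str]]
    outc_rows: list[dict[str, str]]
    ther_rows: list[dict[str, str]]


@dataclass
class AssemblyStats:
    """Bookkeeping from joining the five tables."""

    n_reports: int = 0
    orphan_drug: int = 0
    orphan_reac: int = 0
    orphan_outc: int = 0
    orphan_ther: int = 0
    invalid_dates: int = 0

    @property
    def n_orphans(self) -> int:
        return self.orphan_drug + self.orphan_reac + self.orphan_outc + self.orphan_ther


def read_table(path: str | Path, role: str) -> list[dict[str, str]]:
    """Read one '$'-delimited FAERS table, validating its required columns."""
    role = role.upper()
    if role not in REQUIRED_COLUMNS:
        raise ValueError(f"unknown table role {role!r}")
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{role} file not found: {path}")
    try:
        df = pd.read_csv(path, sep="$", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{role} file is empty: {path}") from None
    df.columns = [c.strip().upper() for c in df.columns]
    for col in REQUIRED_COLUMNS[role]:
        if col not in df.columns:
            raise FormatError(f"{role} file {path} lacks required column {col}")
    rows = [{k: str(v).strip() for k, v in rec.items()} for rec in df.to_dict("records")]
    logger.info("read %s: %d rows from %s", role, len(rows), path)
    return rows


def read_quarter(
    demo_path: str | Path,
    drug_path: str | Path,
    reac_path: str | Path,
    outc_path: str | Path,
    ther_path: str | Path,
    quarter_label: str = "",
) -> RawQuarter:
    """Read the five tables of one quarterly extract."""
    return RawQuarter(
        quarter_label=quarter_label,
        demo_rows=read_table(demo_path, "DEMO"),
        drug_rows=read_table(drug_path, "DRUG"),
        reac_rows=read_table(reac_path, "REAC"),
        outc_rows=read_table(outc_path, "OUTC"),
        ther_rows=read_table(ther_path, "THER"),
    )


def _group_by_primaryid(rows: Iterable[dict[str, str]]) -> dict[str, list[dict[str, str]]]:
    grouped: dict[str, list[dict[str, str]]] = {}
    for row in rows:
        grouped.setdefault(row.get("PRIMARYID", "").strip(), []).append(row)
    return grouped


def assemble_reports(quarter: RawQuarter) -> tuple[list[CaseReport], AssemblyStats]:
    """Join DEMO/DRUG/REAC/OUTC/THER into one CaseReport per DEMO row.

    Therapy start dates attach to drugs on (PRIMARYID, DSG_DRUG_SEQ ==
    DRUG_SEQ).  Rows referencing a PRIMARYID absent from DEMO are counted as
    orphans and excluded, never silently dropped.
    """
    stats = AssemblyStats()
    counters: dict[str, int] = {}

    drug_by_pid = _group_by_primaryid(quarter.drug_rows)
    reac_by_pid = _group_by_primaryid(quarter.reac_rows)
    outc_by_pid = _group_by_primaryid(quarter.outc_rows)
    ther_by_pid = _group_by_primaryid(quarter.ther_rows)

    reports: list[CaseReport] = []
    seen_pids: set[str] = set()
    for row in quarter.demo_rows:
        pid = row.get("PRIMARYID", "").strip()
        if not pid:
            continue
        seen_pids.add(pid)
        sex = normalize_text(row.get("SEX", ""))
        report = CaseReport(
            primaryid=pid,
            caseid=row.get("CASEID", "").strip(),
            fda_dt=parse_partial_date(row.get("FDA_DT", ""), counters),
            event_dt=parse_partial_date(row.get("EVENT_DT", ""), counters),
            age_years=age_to_years(row.get("AGE", ""), row.get("AGE_COD", "")),
            sex=sex if sex in ("M", "F") else "unknown",
            country=normalize_text(row.get("OCCR_COUNTRY", "")) or None,
        )

        # therapy starts keyed by DSG_DRUG_SEQ
        starts: dict[int, PartialDate] = {}
        for ther in ther_by_pid.get(pid, ()):
            try:
                seq = int(ther.get("DSG_DRUG_SEQ", ""))
            except ValueError:
                continue
            start = parse_partial_date(ther.get("START_DT", ""), counters)
            if start is None:
                continue
            # several therapy episodes: keep the earliest start per drug_seq
            if seq not in starts or start.sort_key() < starts[seq].sort_key():
                starts[seq] = start

        for drug in drug_by_pid.get(pid, ()):
            try:
                seq = int(drug.get("DRUG_SEQ", "") or 0)
            except ValueError:
                seq = 0
            ai = normalize_text(drug.get("PROD_AI", ""))
            report.drugs.append(
                DrugEntry(
                    drug_seq=seq,
                    role=normalize_text(drug.get("ROLE_COD", "")) or "C",
                    verbatim_name=normalize_text(drug.get("DRUGNAME", "")),
                    active_ingredient=ai or None,
                    therapy_start=starts.get(seq),
                )
            )
        for reac in reac_by_pid.get(pid, ()):
            pt = normalize_text(reac.get("PT", ""))
            if pt:
                report.reactions.append(pt)
        for outc in outc_by_pid.get(pid, ()):
            code = normalize_text(outc.get("OUTC_COD", ""))
            if code in OUTCOME_CODES:
                report.outcomes.add(code)
        reports.append(report)

    stats.n_reports = len(reports)
    stats.invalid_dates = counters.get("invalid_date", 0)
    stats.orphan_drug = sum(len(v) for k, v in drug_by_pid.items() if k not in seen_pids)
    stats.orphan_reac = sum(len(v) for k, v in reac_by_pid.items() if k not in seen_pids)
    stats.orphan_outc = sum(len(v) for k, v in outc_by_pid.items() if k not in seen_pids)
    stats.orphan_ther = sum(len(v) for k, v in ther_by_pid.items() if k not in seen_pids)
    if stats.n_orphans:
        logger.info(
            "assembly orphans (rows whose PRIMARYID is absent from DEMO): "
            "drug=%d reac=%d outc=%d ther=%d",
            stats.orphan_drug, stats.orphan_reac, stats.orphan_outc, stats.orphan_ther,
        )
    logger.info("assembled %d reports from quarter %s", stats.n_reports, quarter.quarter_label)
    return reports, stats


def merge_quarters(quarters: Iterable[RawQuarter]) -> tuple[list[CaseReport], AssemblyStats]:
    """Assemble several quarters and pool their reports (dedup happens later)."""
    all_reports: list[CaseReport] = []
    total = AssemblyStats()
    for quarter in quarters:
        reports, stats = assemble_reports(quarter)
        all_reports.extend(reports)
        total.n_reports += stats.n_reports
        total.orphan_drug += stats.orphan_drug
        total.orphan_reac += stats.orphan_reac
        total.orphan_outc += stats.orphan_outc
        total.orphan_ther += stats.orphan_ther
        total.invalid_dates += stats.invalid_dates
    return all_reports, total
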