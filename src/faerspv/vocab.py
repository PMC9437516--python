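"""Drug-name normalization, event classification, and drug–event pair extraction.

Two user-suppliable dictionaries drive this stage:

* a **drug dictionary** mapping verbatim/brand names to the eight canonical
  immune checkpoint inhibitors (ICIs) and their target class (anti-PD-1,
  anti-PD-L1, anti-CTLA-4);
* an **event dictionary** mapping MedDRA-style preferred terms (PTs) to the
  ten respiratory system event classes.  A PT may belong to several
  classes.  MedDRA itself is licensed and cannot be shipped, so the default
  event dictionary is a synthetic fixture of representative PTs; real
  analyses should load a dictionary derived from a licensed MedDRA copy.

The unit of analysis downstream is the **drug–event pair**: one occurrence
of a (drug, PT) combination within a deduplicated report.  A report with
two suspect drugs and three PTs contributes six pairs.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .faers_io import CaseReport, PartialDate

logger = logging.getLogger(__name__)

#: outcome severity precedence for single-assignment breakdowns
OUTCOME_PRECEDENCE = ("DE", "LT", "DS", "HO", "CA", "RI", "OT")

#: default role filter: suspect drugs only
DEFAULT_ROLE_FILTER = frozenset({"PS", "SS"})

ICI_CLASSES = ("anti-PD-1", "anti-PD-L1", "anti-CTLA-4")

#: columns of the tidy pair table produced by extract_pairs
PAIR_COLUMNS = [
    "primaryid", "caseid", "drug", "drug_name", "ici_class", "role", "pt",
    "sex", "age_years", "age_group", "year", "country",
    "death", "outcome_primary", "outcomes",
    "event_dt", "therapy_start", "monotherapy", "n_ici",
]


class DictionaryError(ValueError):
    """A drug or event dictionary fails validation."""


@dataclass
class DrugDictionary:
    """Canonical ICI names with synonyms and target-class labels."""

    entries: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()
        self._synonym_to_canonical: dict[str, str] = {}
        self._patterns: list[tuple[re.Pattern, str]] = []
        for canonical, spec in self.entries.items():
            names = {canonical.upper()} | {s.upper() for s in spec.get("synonyms", ())}
            for name in names:
                self._synonym_to_canonical[name] = canonical
                self._patterns.append((re.compile(r"\b" + re.escape(name) + r"\b"), canonical))

    def validate(self) -> None:
        seen: dict[str, str] = {}
        for canonical, spec in self.entries.items():
            if spec.get("ici_class") not in ICI_CLASSES:
                raise DictionaryError(f"{canonical}: unknown ici_class {spec.get('ici_class')!r}")
            for syn in {canonical.upper()} | {s.upper() for s in spec.get("synonyms", ())}:
                if syn in seen and seen[syn] != canonical:
                    raise DictionaryError(
                        f"synonym {syn!r} is claimed by both {seen[syn]} and {canonical}"
                    )
                seen[syn] = canonical

    @property
    def canonical_names(self) -> list[str]:
        return list(self.entries)

    def ici_class(self, canonical: str) -> str:
        return self.entries[canonical]["ici_class"]

    def drugs_in_class(self, ici_class: str) -> set[str]:
        return {c for c, s in self.entries.items() if s["ici_class"] == ici_class}

    def exact(self, name: str) -> str | None:
        return self._synonym_to_canonical.get(name)

    def substring_matches(self, text: str) -> set[str]:
        return {canon for pat, canon in self._patterns if pat.search(text)}


@dataclass
class EventDictionary:
    """Respiratory event classes: class name -> MedDRA-style code + PT set."""

    classes: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._pt_to_classes: dict[str, set[str]] = {}
        for cname, spec in self.classes.items():
            for pt in spec.get("pts", ()):
                pt_u = pt.upper()
                if pt_u != pt:
                    raise DictionaryError(f"PT not uppercase: {pt!r} in {cname}")
                self._pt_to_classes.setdefault(pt_u, set()).add(cname)

    @property
    def class_names(self) -> list[str]:
        return list(self.classes)

    @property
    def all_pts(self) -> set[str]:
        return set(self._pt_to_classes)

    def pts_in_class(self, class_name: str) -> set[str]:
        return set(self.classes[class_name]["pts"])

    def classify(self, pt: str) -> set[str]:
        return set(self._pt_to_classes.get(pt, ()))


def default_drug_dictionary() -> DrugDictionary:
    """The eight ICIs with their common brand names.

    Fixed-dose combination products are intentionally absent: a verbatim
    string matching two canonical drugs is treated as a combination and
    mapped to "other".
    """
    return DrugDictionary(entries={
        "nivolumab": {"ici_class": "anti-PD-1", "synonyms": {"OPDIVO"}},
        "pembrolizumab": {"ici_class": "anti-PD-1", "synonyms": {"KEYTRUDA", "LAMBROLIZUMAB"}},
        "cemiplimab": {"ici_class": "anti-PD-1", "synonyms": {"LIBTAYO", "CEMIPLIMAB-RWLC"}},
        "atezolizumab": {"ici_class": "anti-PD-L1", "synonyms": {"TECENTRIQ"}},
        "avelumab": {"ici_class": "anti-PD-L1", "synonyms": {"BAVENCIO"}},
        "durvalumab": {"ici_class": "anti-PD-L1", "synonyms": {"IMFINZI"}},
        "ipilimumab": {"ici_class": "anti-CTLA-4", "synonyms": {"YERVOY"}},
        "tremelimumab": {"ici_class": "anti-CTLA-4", "synonyms": {"IMJUDO", "TICILIMUMAB"}},
    })


#: the ten respiratory system event classes with their MedDRA-style codes
RESPIRATORY_CLASS_CODES = {
    "Bronchial disorders": "10006436",
    "Lower respiratory tract disorders": "10024967",
    "Pleural disorders": "10035597",
    "Pulmonary vascular disorders": "10037454",
    "Respiratory disorders NEC": "10038716",
    "Respiratory tract infections": "10024970",
    "Respiratory tract neoplasms": "10029107",
    "Respiratory tract signs and symptoms": "10079101",
    "Thoracic disorders": "10013369",
    "Upper respiratory tract disorders": "10046304",
}


def default_event_dictionary() -> EventDictionary:
    """Synthetic fixture event dictionary: representative PTs per class.

    This is NOT the licensed MedDRA hierarchy; it exists so the pipeline is
    runnable and testable end-to-end.  WHEEZING appears in two classes to
    exercise the multi-class contract (a PT may map to several groupings).
    """
    pts = {
        "Bronchial disorders": {"BRONCHOSPASM", "ASTHMA", "BRONCHIAL OBSTRUCTION", "WHEEZING"},
        "Lower respiratory tract disorders": {
            "PNEUMONITIS", "INTERSTITIAL LUNG DISEASE", "PULMONARY FIBROSIS",
            "ORGANISING PNEUMONIA", "PULMONARY TOXICITY",
        },
        "Pleural disorders": {"PLEURAL EFFUSION", "PLEURISY", "PNEUMOTHORAX"},
        "Pulmonary vascular disorders": {
            "PULMONARY EMBOLISM", "PULMONARY HYPERTENSION", "PULMONARY HAEMORRHAGE",
        },
        "Respiratory disorders NEC": {
            "RESPIRATORY FAILURE", "ACUTE RESPIRATORY DISTRESS SYNDROME", "HYPOXIA",
            "ACUTE RESPIRATORY FAILURE",
        },
        "Respiratory tract infections": {
            "PNEUMONIA", "LOWER RESPIRATORY TRACT INFECTION", "BRONCHITIS",
            "PNEUMONIA ASPIRATION",
        },
        "Respiratory tract neoplasms": {"LUNG NEOPLASM MALIGNANT", "LUNG ADENOCARCINOMA"},
        "Respiratory tract signs and symptoms": {
            "DYSPNOEA", "COUGH", "HAEMOPTYSIS", "WHEEZING", "TACHYPNOEA",
        },
        "Thoracic disorders": {"MEDIASTINAL DISORDER", "DIAPHRAGMATIC PARALYSIS"},
        "Upper respiratory tract disorders": {
            "NASAL CONGESTION", "OROPHARYNGEAL PAIN", "EPISTAXIS",
        },
    }
    return EventDictionary(classes={
        name: {"meddra_code": code, "pts": pts[name]}
        for name, code in RESPIRATORY_CLASS_CODES.items()
    })


def load_drug_dictionary(path: str | Path) -> DrugDictionary:
    """Load a drug dictionary from CSV with columns canonical,synonym,class."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"canonical", "synonym", "class"}
    if not required.issubset(df.columns):
        raise DictionaryError(f"drug dictionary {path} must have columns {sorted(required)}")
    entries: dict[str, dict] = {}
    for _, row in df.iterrows():
        entry = entries.setdefault(row["canonical"], {"ici_class": row["class"], "synonyms": set()})
        if row["synonym"]:
            entry["synonyms"].add(row["synonym"].upper())
    return DrugDictionary(entries=entries)


def load_event_dictionary(path: str | Path) -> EventDictionary:
    """Load an event dictionary from CSV with columns class,meddra_code,pt."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"class", "meddra_code", "pt"}
    if not required.issubset(df.columns):
        raise DictionaryError(f"event dictionary {path} must have columns {sorted(required)}")
    classes: dict[str, dict] = {}
    for _, row in df.iterrows():
        cls = classes.setdefault(row["class"], {"meddra_code": row["meddra_code"], "pts": set()})
        cls["pts"].add(row["pt"].upper())
    return EventDictionary(classes=classes)


def normalize_drug(
    verbatim: str,
    active_ingredient: str | None,
    drug_dict: DrugDictionary,
    counters: dict[str, int] | None = None,
) -> str:
    """Map a verbatim drug record to a canonical ICI name or "other".

    Match priority: exact active-ingredient match, then exact verbatim
    match, then word-boundary substring match of any synonym.  A record
    matching two different canonical drugs (a fixed combination such as
    "IPILIMUMAB AND NIVOLUMAB") maps to "other" and increments
    ``counters['combination']``.
    """
    verbatim = verbatim.upper().strip()
    ai = (active_ingredient or "").upper().strip()

    for tier in (ai, verbatim):
        if tier:
            hit = drug_dict.exact(tier)
            if hit is not None:
                return hit

    matches = drug_dict.substring_matches(verbatim)
    if ai:
        matches |= drug_dict.substring_matches(ai)
    if len(matches) == 1:
        return next(iter(matches))
    if len(matches) > 1:
        if counters is not None:
            counters["combination"] = counters.get("combination", 0) + 1
        return "other"
    return "other"


def classify_event(pt: str, event_dict: EventDictionary) -> set[str]:
    """All respiratory classes containing the PT (empty set = non-respiratory)."""
    return event_dict.classify(pt.upper())


def outcome_primary(outcomes: set[str]) -> str:
    """Single outcome level per record under severity precedence DE>LT>DS>HO>CA>RI>OT."""
    for code in OUTCOME_PRECEDENCE:
        if code in outcomes:
            return code
    return "Missing"


def _best_therapy_start(starts: list[PartialDate | None]) -> PartialDate | None:
    """Earliest day-precision start if any; else earliest partial start."""
    dated = [s for s in starts if s is not None]
    if not dated:
        return None
    day_precision = [s for s in dated if s.precision == "day"]
    pool = day_precision or dated
    return min(pool, key=lambda s: s.sort_key())


def extract_pairs(
    reports: list[CaseReport],
    drug_dict: DrugDictionary,
    event_dict: EventDictionary | None = None,
    role_filter: frozenset[str] | set[str] = DEFAULT_ROLE_FILTER,
    monotherapy_only: bool = False,
    counters: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Explode deduplicated reports into the tidy drug–event pair table.

    One row per distinct (report, drug, PT) combination where the drug's
    role is in ``role_filter``.  Non-ICI drugs are retained with
    ``drug == "other"`` (keyed by their normalized verbatim name) because
    the disproportionality universe must contain all drugs.  Each row
    carries the report metadata needed downstream (demographics, outcomes,
    event and therapy dates).

    ``monotherapy_only`` drops reports matching more than one canonical ICI.
    """
    role_filter = frozenset(role_filter)
    rows: list[tuple] = []
    for report in reports:
        # normalize each qualifying drug entry once
        matched: dict[str, dict] = {}  # drug_name key -> info
        for entry in report.drugs:
            if entry.role not in role_filter:
                continue
            canonical = normalize_drug(entry.verbatim_name, entry.active_ingredient, drug_dict, counters)
            key = canonical if canonical != "other" else (entry.verbatim_name or "UNSPECIFIED")
            info = matched.setdefault(key, {"canonical": canonical, "starts": [], "roles": set()})
            info["starts"].append(entry.therapy_start)
            info["roles"].add(entry.role)
        if not matched:
            continue
        ici_names = sorted(k for k, v in matched.items() if v["canonical"] != "other")
        n_ici = len(ici_names)
        if monotherapy_only and n_ici > 1:
            continue
        mono = n_ici == 1

        age = report.age_years
        age_group = "Missing" if age is None else (">=70" if age >= 70 else "<70")
        death = "DE" in report.outcomes
        outc = outcome_primary(report.outcomes)
        outcomes_str = "/".join(sorted(report.outcomes))
        year = report.received_year
        event_str = str(report.event_dt) if report.event_dt is not None else ""
        pts = sorted(set(report.reactions))
        for key, info in matched.items():
            canonical = info["canonical"]
            start = _best_therapy_start(info["starts"])
            start_str = str(start) if start is not None else ""
            role = "PS" if "PS" in info["roles"] else sorted(info["roles"])[0]
            ici_class = drug_dict.ici_class(canonical) if canonical != "other" else ""
            for pt in pts:
                rows.append((
                    report.primaryid, report.caseid, canonical, key, ici_class, role, pt,
                    report.sex, age, age_group, year, report.country or "Missing",
                    death, outc, outcomes_str,
                    event_str, start_str, mono, n_ici,
                ))
    pairs = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    logger.info("extracted %d drug-event pairs from %d reports", len(pairs), len(reports))
    return pairs


def annotate_classes(pairs: pd.DataFrame, event_dict: EventDictionary) -> pd.DataFrame:
    """Add a boolean ``respiratory`` column and per-class indicator columns."""
    out = pairs.copy()
    out["respiratory"] = out["pt"].isin(event_dict.all_pts)
    for cname in event_dict.class_names:
        out[f"class::{cname}"] = out["pt"].isin(event_dict.pts_in_class(cname))
    return out
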