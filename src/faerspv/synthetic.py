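"""Synthetic FAERS-shaped corpus generator with controllable signal structure.

The generator emulates the multi-table quarterly spontaneous-report layout
(DEMO / DRUG / REAC / OUTC / THER, '$'-delimited) so every pipeline stage
is testable without downloading real data:

* each case gets one suspect drug (categorical over a catalog of canonical
  ICIs and decoy drugs) and a set of reaction PTs drawn independently per
  PT (Bernoulli marginals) — so drug and event assignment is independent
  except for *injected signals*;
* an injected signal (drug, PT, target shrunk ROR) boosts P(PT | drug) to
  the value that makes the expected shrunk observed/expected ratio equal
  the target, solved from the closed-form expected counts.  Boosting the
  conditional probability (rather than editing counts post hoc) keeps all
  marginals mutually coherent;
* demographics, countries, outcomes (per-event-class death probabilities),
  and Weibull time-to-onset per event class are configurable, with
  missing-data and partial-date-precision probabilities;
* duplicate case versions perturb only FDA_DT / PRIMARYID, never clinical
  content, so the deduplication contract is isolated;
* ground truth (true pair table, solved boost probabilities, true duration
  sets, true death tallies) is returned alongside, and written as CSV next
  to the ASCII files.

Identical seed + config produce byte-identical output files.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .faers_io import RawQuarter

__all__ = ["SimConfig", "Corpus", "ConfigError", "generate_corpus", "generate",
           "solve_boosts", "fixture_small", "fixture_pairs_10"]


class ConfigError(ValueError):
    """The simulation configuration is invalid or unsatisfiable."""


DEFAULT_DRUG_CATALOG = {
    # canonical ICIs: small market shares, anti-PD-1 dominating, mirroring
    # the relative report volumes seen for these drugs
    "nivolumab": 0.030, "pembrolizumab": 0.022, "cemiplimab": 0.002,
    "atezolizumab": 0.010, "avelumab": 0.003, "durvalumab": 0.008,
    "ipilimumab": 0.006, "tremelimumab": 0.001,
    # decoy (non-ICI) drugs making up the bulk of the reporting universe
    "ASPIRIN": 0.17, "METFORMIN": 0.14, "ATORVASTATIN": 0.14,
    "LISINOPRIL": 0.12, "IBUPROFEN": 0.12, "ADALIMUMAB": 0.10,
    "OMEPRAZOLE": 0.118,
}

DEFAULT_EVENT_CATALOG = {
    # respiratory PTs (classes per the default event dictionary)
    "PNEUMONITIS": 0.02, "INTERSTITIAL LUNG DISEASE": 0.015, "PULMONARY FIBROSIS": 0.005,
    "PLEURAL EFFUSION": 0.015, "PNEUMOTHORAX": 0.004,
    "PULMONARY EMBOLISM": 0.012, "PULMONARY HYPERTENSION": 0.004,
    "RESPIRATORY FAILURE": 0.015, "HYPOXIA": 0.008,
    "PNEUMONIA": 0.04, "BRONCHITIS": 0.01,
    "LUNG NEOPLASM MALIGNANT": 0.004,
    "DYSPNOEA": 0.06, "COUGH": 0.04, "HAEMOPTYSIS": 0.004,
    "BRONCHOSPASM": 0.005, "ASTHMA": 0.006,
    "NASAL CONGESTION": 0.01, "EPISTAXIS": 0.005,
    "MEDIASTINAL DISORDER": 0.002,
    # non-respiratory decoy PTs
    "NAUSEA": 0.12, "HEADACHE": 0.10, "RASH": 0.08, "FATIGUE": 0.10,
    "DIARRHOEA": 0.09, "VOMITING": 0.07, "DIZZINESS": 0.06, "PYREXIA": 0.06,
}

#: event class of each respiratory PT for outcome/onset models (first class)
_PT_CLASS = {
    "PNEUMONITIS": "Lower respiratory tract disorders",
    "INTERSTITIAL LUNG DISEASE": "Lower respiratory tract disorders",
    "PULMONARY FIBROSIS": "Lower respiratory tract disorders",
    "PLEURAL EFFUSION": "Pleural disorders",
    "PNEUMOTHORAX": "Pleural disorders",
    "PULMONARY EMBOLISM": "Pulmonary vascular disorders",
    "PULMONARY HYPERTENSION": "Pulmonary vascular disorders",
    "RESPIRATORY FAILURE": "Respiratory disorders NEC",
    "HYPOXIA": "Respiratory disorders NEC",
    "PNEUMONIA": "Respiratory tract infections",
    "BRONCHITIS": "Respiratory tract infections",
    "LUNG NEOPLASM MALIGNANT": "Respiratory tract neoplasms",
    "DYSPNOEA": "Respiratory tract signs and symptoms",
    "COUGH": "Respiratory tract signs and symptoms",
    "HAEMOPTYSIS": "Respiratory tract signs and symptoms",
    "BRONCHOSPASM": "Bronchial disorders",
    "ASTHMA": "Bronchial disorders",
    "NASAL CONGESTION": "Upper respiratory tract disorders",
    "EPISTAXIS": "Upper respiratory tract disorders",
    "MEDIASTINAL DISORDER": "Thoracic disorders",
}

DEFAULT_DEATH_PROB = {
    # per-class probability that a case whose most severe event is in this
    # class is reported with a fatal outcome; ~0.3 for the severe lower
    # respiratory classes, lower elsewhere
    "Lower respiratory tract disorders": 0.31,
    "Respiratory disorders NEC": 0.33,
    "Respiratory tract infections": 0.33,
    "Respiratory tract neoplasms": 0.37,
    "Pulmonary vascular disorders": 0.33,
    "Pleural disorders": 0.30,
    "Bronchial disorders": 0.12,
    "Respiratory tract signs and symptoms": 0.15,
    "Thoracic disorders": 0.12,
    "Upper respiratory tract disorders": 0.05,
}

DEFAULT_ONSET = {
    # Weibull (shape, scale-days): shape < 1 front-loads onsets so the bulk
    # falls in the first three months, median a few weeks
    "default": (0.85, 75.0),
    "Upper respiratory tract disorders": (0.85, 55.0),
    "Pulmonary vascular disorders": (0.9, 85.0),
    "Thoracic disorders": (0.9, 85.0),
}

DEFAULT_COUNTRY_WEIGHTS = {
    "US": 0.40, "JP": 0.10, "FR": 0.05, "DE": 0.05, "IT": 0.02, "GB": 0.04,
    "CA": 0.05, "ES": 0.02, "AU": 0.02, "NL": 0.01, "CN": 0.05, "BR": 0.04,
    "": 0.15,  # missing
    "KR": 0.05,
}

_BRAND = {
    "nivolumab": "OPDIVO", "pembrolizumab": "KEYTRUDA", "cemiplimab": "LIBTAYO",
    "atezolizumab": "TECENTRIQ", "avelumab": "BAVENCIO", "durvalumab": "IMFINZI",
    "ipilimumab": "YERVOY", "tremelimumab": "IMJUDO",
}


@dataclass
class SimConfig:
    """Study conditions for one synthetic corpus.

    ``injected_signals`` is a list of (drug, pt, target_ror) triples; each
    drug may carry at most one injected signal.  ``duplicate_rate`` is the
    probability that a case ships with extra earlier versions (up to
    ``max_versions`` total).
    """

    seed: int = 0
    n_cases: int = 20_000
    duplicate_rate: float = 0.10
    max_versions: int = 3
    drug_catalog: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DRUG_CATALOG))
    event_catalog: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EVENT_CATALOG))
    injected_signals: list[tuple[str, str, float]] = field(default_factory=list)
    sex_split: dict[str, float] = field(default_factory=lambda: {"M": 0.48, "F": 0.45, "": 0.07})
    age_mean: float = 62.0
    age_sd: float = 14.0
    age_missing_rate: float = 0.15
    country_weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COUNTRY_WEIGHTS))
    death_prob: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DEATH_PROB))
    death_prob_nonresp: float = 0.08
    hosp_prob: float = 0.30
    outcome_missing_rate: float = 0.15
    onset_weibull: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_ONSET))
    event_dt_missing_rate: float = 0.30
    event_dt_month_precision_rate: float = 0.05
    start_dt_missing_rate: float = 0.15
    concomitant_rate: float = 0.30
    brand_name_rate: float = 0.25
    n_orphan_reac: int = 0
    start_date: str = "20140101"
    end_date: str = "20210630"

    def validate(self) -> None:
        for name, p in {**self.drug_catalog}.items():
            if p < 0:
                raise ConfigError(f"negative probability for drug {name}")
        for pt, p in self.event_catalog.items():
            if not 0 <= p <= 1:
                raise ConfigError(f"event probability out of [0,1] for {pt}")
        if not 0 <= self.duplicate_rate <= 1:
            raise ConfigError("duplicate_rate out of [0,1]")
        drugs_with_signal = [d for d, _, _ in self.injected_signals]
        if len(drugs_with_signal) != len(set(drugs_with_signal)):
            raise ConfigError("at most one injected signal per drug")
        for drug, pt, target in self.injected_signals:
            if drug not in self.drug_catalog:
                raise ConfigError(f"injected signal drug {drug!r} not in catalog")
            if pt not in self.event_catalog:
                raise ConfigError(f"injected signal PT {pt!r} not in catalog")
            if target <= 0:
                raise ConfigError(f"target_ror must be positive, got {target}")


@dataclass
class Corpus:
    """In-memory synthetic corpus: FAERS-format row tables plus ground truth."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    ther: pd.DataFrame
    truth: dict

    def raw_quarter(self, label: str = "SIM") -> RawQuarter:
        return RawQuarter(
            quarter_label=label,
            demo_rows=self.demo.to_dict("records"),
            drug_rows=self.drug.to_dict("records"),
            reac_rows=self.reac.to_dict("records"),
            outc_rows=self.outc.to_dict("records"),
            ther_rows=self.ther.to_dict("records"),
        )


def _expected_shrunk_ror(n_cases, p_drug, base_probs, boosted, d_idx, j_idx, q):
    """Expected shrunk ROR for combination (d_idx, j_idx) when its boost is q.

    ``boosted`` maps (drug index, event index) -> conditional probability
    for the other injected signals, held fixed.
    """
    n_drugs, n_events = len(p_drug), len(base_probs)
    probs = np.tile(base_probs, (n_drugs, 1))
    for (di, ji), qq in boosted.items():
        probs[di, ji] = qq
    probs[d_idx, j_idx] = q
    row_sums = probs.sum(axis=1)
    n_total = n_cases * float(p_drug @ row_sums)
    n_drug = n_cases * p_drug[d_idx] * row_sums[d_idx]
    n_event = n_cases * float(p_drug @ probs[:, j_idx])
    n_obs = n_cases * p_drug[d_idx] * q
    n_exp = n_drug * n_event / n_total
    return (n_obs + 0.5) / (n_exp + 0.5)


def solve_boosts(config: SimConfig) -> dict[tuple[str, str], float]:
    """Solve the boosted P(pt | drug) for each injected signal.

    Fixed-point iteration over signals (each solved by root finding with
    the others held fixed); raises :class:`ConfigError` when a target
    would require a conditional probability above 1.
    """
    if not config.injected_signals:
        return {}
    drugs = list(config.drug_catalog)
    events = list(config.event_catalog)
    weights = np.array([config.drug_catalog[d] for d in drugs], dtype=float)
    p_drug = weights / weights.sum()
    base = np.array([config.event_catalog[e] for e in events], dtype=float)
    idx = {(d, pt): (drugs.index(d), events.index(pt)) for d, pt, _ in config.injected_signals}

    boosted: dict[tuple[int, int], float] = {ij: base[ij[1]] for ij in idx.values()}
    for _ in range(8):
        for drug, pt, target in config.injected_signals:
            di, ji = idx[(drug, pt)]
            others = {ij: q for ij, q in boosted.items() if ij != (di, ji)}

            def f(q):
                return _expected_shrunk_ror(config.n_cases, p_drug, base, others, di, ji, q) - target

            hi = 1.0 - 1e-9
            if f(hi) < 0:
                raise ConfigError(
                    f"unsatisfiable boost for ({drug}, {pt}): target ROR {target} "
                    "requires P(pt|drug) > 1"
                )
            lo = 1e-12
            if f(lo) > 0:
                # target below the floor reachable at q ~ 0 (tiny expected);
                # clamp to the minimum
                boosted[(di, ji)] = lo
                continue
            boosted[(di, ji)] = float(brentq(f, lo, hi, xtol=1e-12))
    return {key: boosted[ij] for key, ij in idx.items()}


def _date_str(ordinals: np.ndarray) -> list[str]:
    return [_dt.date.fromordinal(int(o)).strftime("%Y%m%d") for o in ordinals]


def generate_corpus(config: SimConfig, build_tables: bool = True) -> Corpus:
    """Simulate one corpus; deterministic in (seed, config).

    ``build_tables=False`` skips serializing the per-report FAERS row
    tables (the slow part) and returns only the ground truth — the
    sampling model and draws for the ground truth are identical either
    way, so large replicate studies can run on the same corpora the file
    writer would emit.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    drugs = list(config.drug_catalog)
    events = list(config.event_catalog)
    weights = np.array([config.drug_catalog[d] for d in drugs], dtype=float)
    p_drug = weights / weights.sum()
    base = np.array([config.event_catalog[e] for e in events], dtype=float)

    boosts = solve_boosts(config)
    boost_idx = {(drugs.index(d), events.index(pt)): q for (d, pt), q in boosts.items()}

    N = config.n_cases
    drug_idx = rng.choice(len(drugs), size=N, p=p_drug)

    probs = base[np.newaxis, :].repeat(N, axis=0)
    for (di, ji), q in boost_idx.items():
        probs[drug_idx == di, ji] = q
    event_mat = rng.random((N, len(events))) < probs

    keep = event_mat.any(axis=1)
    n_no_event = int((~keep).sum())
    drug_idx = drug_idx[keep]
    event_mat = event_mat[keep]
    n = int(keep.sum())

    # demographics
    sex_levels = list(config.sex_split)
    sex_w = np.array([config.sex_split[s] for s in sex_levels], dtype=float)
    sex = np.array(sex_levels)[rng.choice(len(sex_levels), n, p=sex_w / sex_w.sum())]
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 18, 95).round(0)
    age_missing = rng.random(n) < config.age_missing_rate
    country_levels = list(config.country_weights)
    cw = np.array([config.country_weights[c] for c in country_levels], dtype=float)
    country = np.array(country_levels)[rng.choice(len(country_levels), n, p=cw / cw.sum())]

    # event class per case: most severe respiratory class (max death prob)
    resp_cols = [j for j, e in enumerate(events) if e in _PT_CLASS]
    death_p_col = np.array([
        config.death_prob.get(_PT_CLASS.get(events[j], ""), 0.0) for j in range(len(events))
    ])
    case_death_p = np.where(
        event_mat[:, resp_cols].any(axis=1) if resp_cols else False,
        (event_mat * death_p_col).max(axis=1),
        config.death_prob_nonresp,
    )
    died = rng.random(n) < case_death_p
    hosp = rng.random(n) < config.hosp_prob
    outc_missing = rng.random(n) < config.outcome_missing_rate

    # dates: therapy start uniform over the window, onset ~ class Weibull
    start_ord = _dt.datetime.strptime(config.start_date, "%Y%m%d").date().toordinal()
    end_ord = _dt.datetime.strptime(config.end_date, "%Y%m%d").date().toordinal()
    ther_start = rng.integers(start_ord, end_ord, n)

    shapes = np.empty(n)
    scales = np.empty(n)
    default_k, default_lam = config.onset_weibull.get("default", (0.85, 75.0))
    case_class = np.full(n, "", dtype=object)
    first_resp = np.argmax(event_mat[:, resp_cols], axis=1) if resp_cols else None
    has_resp = event_mat[:, resp_cols].any(axis=1) if resp_cols else np.zeros(n, bool)
    for i in range(n):
        if has_resp[i]:
            case_class[i] = _PT_CLASS[events[resp_cols[first_resp[i]]]]
        k, lam = config.onset_weibull.get(case_class[i], (default_k, default_lam))
        shapes[i], scales[i] = k, lam
    durations = np.floor(scales * rng.weibull(shapes, n)).astype(int)
    event_ord = ther_start + durations
    delay = rng.integers(5, 90, n)
    fda_ord = np.minimum(event_ord + delay,
                         _dt.date(2021, 9, 30).toordinal())

    ev_missing = rng.random(n) < config.event_dt_missing_rate
    ev_month = (~ev_missing) & (rng.random(n) < config.event_dt_month_precision_rate /
                                max(1e-12, 1 - config.event_dt_missing_rate))
    st_missing = rng.random(n) < config.start_dt_missing_rate

    # duplicates: extra earlier versions, identical clinical content
    dup_mask = rng.random(n) < config.duplicate_rate
    extra_versions = np.where(
        dup_mask, rng.integers(1, max(2, config.max_versions), n), 0
    )

    caseids = np.array([f"C{i + 1:07d}" for i in range(n)])
    conco_mask = rng.random(n) < config.concomitant_rate
    conco_idx = rng.choice(len(drugs), size=n, p=p_drug)
    use_brand = rng.random(n) < config.brand_name_rate

    # ground truth, vectorized: one pair per (retained case, sampled event)
    drug_arr = np.array(drugs, dtype=object)[drug_idx]
    survivor_pid = ((np.arange(n) + 1) * 100 + extra_versions).astype(str)
    ci, ej = np.nonzero(event_mat)
    fully_dated = (~ev_missing) & (~ev_month) & (~st_missing)
    pair_df = pd.DataFrame({
        "caseid": caseids[ci], "primaryid": survivor_pid[ci],
        "drug": drug_arr[ci], "pt": np.array(events, dtype=object)[ej],
    })
    dated_pairs = fully_dated[ci]
    duration_df = pd.DataFrame({
        "caseid": caseids[ci][dated_pairs],
        "drug": drug_arr[ci][dated_pairs],
        "pt": np.array(events, dtype=object)[ej][dated_pairs],
        "days": durations[ci][dated_pairs],
        "event_class": np.where(case_class == "", "non-respiratory", case_class)[ci][dated_pairs],
    })

    demo_rows, drug_rows, reac_rows, outc_rows, ther_rows = [], [], [], [], []
    if build_tables:
        event_str = _date_str(event_ord)
        fda_str_base = fda_ord  # per-version receipt dates derived below
        start_str = _date_str(ther_start)
        for i in range(n):
            cid = caseids[i]
            n_versions = 1 + int(extra_versions[i])
            ev = "" if ev_missing[i] else (event_str[i][:6] if ev_month[i] else event_str[i])
            dname = drugs[drug_idx[i]]
            verbatim = _BRAND.get(dname, dname.upper()) if use_brand[i] else dname.upper()
            prod_ai = dname.upper() if dname in _BRAND else dname
            for v in range(n_versions):
                pid = str((i + 1) * 100 + v)
                # earlier versions get strictly earlier receipt dates
                fda = _dt.date.fromordinal(int(fda_str_base[i]) - (n_versions - 1 - v) * 17).strftime("%Y%m%d")
                demo_rows.append((pid, cid, fda, ev,
                                  "" if age_missing[i] else str(int(age[i])), "YR",
                                  sex[i], country[i]))
                drug_rows.append((pid, "1", "PS", verbatim, prod_ai))
                for j in np.nonzero(event_mat[i])[0]:
                    reac_rows.append((pid, events[j]))
                if not outc_missing[i]:
                    if died[i]:
                        outc_rows.append((pid, "DE"))
                    if hosp[i]:
                        outc_rows.append((pid, "HO"))
                    if not died[i] and not hosp[i]:
                        outc_rows.append((pid, "OT"))
                if not st_missing[i]:
                    ther_rows.append((pid, "1", start_str[i]))
            # concomitant drug on the survivor version only (role C, not a pair)
            if conco_mask[i]:
                cname = drugs[conco_idx[i]]
                drug_rows.append((survivor_pid[i], "2", "C", cname.upper(),
                                  cname.upper() if cname in _BRAND else cname))

        # orphan REAC rows: PRIMARYIDs that exist in no DEMO row
        for k in range(config.n_orphan_reac):
            reac_rows.append((str(90_000_000 + k), "NAUSEA"))

    demo = pd.DataFrame(demo_rows, columns=["PRIMARYID", "CASEID", "FDA_DT", "EVENT_DT",
                                            "AGE", "AGE_COD", "SEX", "OCCR_COUNTRY"])
    drug = pd.DataFrame(drug_rows, columns=["PRIMARYID", "DRUG_SEQ", "ROLE_COD",
                                            "DRUGNAME", "PROD_AI"])
    reac = pd.DataFrame(reac_rows, columns=["PRIMARYID", "PT"])
    outc = pd.DataFrame(outc_rows, columns=["PRIMARYID", "OUTC_COD"])
    ther = pd.DataFrame(ther_rows, columns=["PRIMARYID", "DSG_DRUG_SEQ", "START_DT"])
    truth = {
        "n_cases": n,
        "n_cases_no_event": n_no_event,
        "n_versions": len(demo),
        "n_duplicate_versions": int(extra_versions.sum()),
        "n_orphan_reac": config.n_orphan_reac,
        "n_pairs": len(pair_df),
        "pairs": pair_df,
        "durations": duration_df,
        "n_deaths": int(died[~outc_missing].sum()),
        "boosts": {f"{d}|{pt}": q for (d, pt), q in boosts.items()},
        "injected_signals": list(config.injected_signals),
    }
    return Corpus(demo=demo, drug=drug, reac=reac, outc=outc, ther=ther, truth=truth)


def generate(config: SimConfig, out_dir: str | Path) -> dict:
    """Write the corpus as quarterly FAERS ASCII files plus ground-truth CSVs.

    Rows are split into quarters by FDA receipt date; returns a manifest of
    written files and bookkeeping counts (also saved as manifest.json).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    corpus = generate_corpus(config)

    q_of = corpus.demo["FDA_DT"].str.slice(0, 4) + "Q" + (
        (corpus.demo["FDA_DT"].str.slice(4, 6).astype(int) - 1) // 3 + 1
    ).astype(str)
    pid_quarter = dict(zip(corpus.demo["PRIMARYID"], q_of))

    files: dict[str, dict[str, str]] = {}
    tables = {"DEMO": corpus.demo, "DRUG": corpus.drug, "REAC": corpus.reac,
              "OUTC": corpus.outc, "THER": corpus.ther}
    labels = sorted(q_of.unique())
    for label in labels:
        files[label] = {}
        for role, table in tables.items():
            if role == "DEMO":
                sub = table[q_of == label]
            else:
                in_quarter = table["PRIMARYID"].map(pid_quarter).eq(label)
                if role == "REAC" and label == labels[0]:
                    # orphan rows belong to no DEMO quarter; park them in the first
                    in_quarter |= ~table["PRIMARYID"].isin(pid_quarter.keys())
                sub = table[in_quarter]
            path = out_dir / f"{role}{label}.txt"
            sub.to_csv(path, sep="$", index=False, lineterminator="\n")
            files[label][role] = str(path)

    corpus.truth["pairs"].to_csv(out_dir / "truth_pairs.csv", index=False)
    corpus.truth["durations"].to_csv(out_dir / "truth_durations.csv", index=False)
    manifest = {
        "quarters": files,
        "counts": {k: v for k, v in corpus.truth.items()
                   if isinstance(v, (int, float, str))},
        "boosts": corpus.truth["boosts"],
        "injected_signals": list(config.injected_signals),
        "seed": config.seed,
        "n_cases": config.n_cases,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# hand-checkable fixture corpus
# ---------------------------------------------------------------------------

def fixture_small() -> RawQuarter:
    """Deterministic ~20-case corpus where every count is verifiable by hand.

    Documented ground truth (role filter {PS, SS}, default dictionaries),
    after deduplication (22 raw versions -> 20 reports, 2 removed):

    * pair universe: 22 pairs; nivolumab 6, PNEUMONITIS 5,
      nivolumab x PNEUMONITIS 2 -> contingency (2, 6, 5, 22),
      expected 6*5/22 = 1.363636, shrunk ROR 2.5/1.863636 = 1.341463,
      IC = log2(1.341463) = 0.423866;
    * ICI pairs 15 (14 respiratory), other-drug pairs 7; respiratory 18;
    * dedup block: case C001 versions (20190501, 7001), (20190701, 7005),
      (20190701, 7010) -> survivor 7010 (latest FDA_DT, tie broken by
      higher PRIMARYID);
    * nivolumab day-precision onset durations {14, 36, 98} -> median 36;
      one month-precision therapy start (C020) excluded as partial
      precision;
    * deaths: C001 (nivolumab/PNEUMONITIS), C005 (pembrolizumab/ILD).
    """
    demo, drug, reac, outc, ther = [], [], [], [], []

    def case(pid, cid, fda, event="", age="64", sex="M", country="US",
             drugs_=(), pts=(), outcomes=(), thers=()):
        demo.append({"PRIMARYID": pid, "CASEID": cid, "FDA_DT": fda, "EVENT_DT": event,
                     "AGE": age, "AGE_COD": "YR", "SEX": sex, "OCCR_COUNTRY": country})
        for seq, role, name, ai in drugs_:
            drug.append({"PRIMARYID": pid, "DRUG_SEQ": seq, "ROLE_COD": role,
                         "DRUGNAME": name, "PROD_AI": ai})
        for pt in pts:
            reac.append({"PRIMARYID": pid, "PT": pt})
        for oc in outcomes:
            outc.append({"PRIMARYID": pid, "OUTC_COD": oc})
        for seq, start in thers:
            ther.append({"PRIMARYID": pid, "DSG_DRUG_SEQ": seq, "START_DT": start})

    nivo = ("1", "PS", "NIVOLUMAB", "NIVOLUMAB")
    # C001: three versions, identical clinical content; onset 14 days; death
    for pid, fda in (("7001", "20190501"), ("7005", "20190701"), ("7010", "20190701")):
        case(pid, "C001", fda, event="20190315", sex="M",
             drugs_=[nivo], pts=["PNEUMONITIS"], outcomes=["DE"],
             thers=[("1", "20190301")])
    # C002: onset 36 days (20190331 -> 20190506)
    case("7020", "C002", "20190601", event="20190506", sex="F",
         drugs_=[nivo], pts=["PNEUMONITIS"], outcomes=["HO"], thers=[("1", "20190331")])
    # C003: onset 98 days (20190402 -> 20190709)
    case("7030", "C003", "20190801", event="20190709", sex="M", age="72",
         drugs_=[nivo], pts=["DYSPNOEA"], thers=[("1", "20190402")])
    # C004: two suspect ICIs, one PT -> two pairs; not monotherapy
    case("7040", "C004", "20190901", sex="M",
         drugs_=[nivo, ("2", "SS", "YERVOY", "IPILIMUMAB")], pts=["COUGH"])
    case("7050", "C005", "20190901", sex="F", age="58",
         drugs_=[("1", "PS", "KEYTRUDA", "PEMBROLIZUMAB")],
         pts=["INTERSTITIAL LUNG DISEASE"], outcomes=["DE"])
    case("7060", "C006", "20190901", sex="F",
         drugs_=[("1", "PS", "PEMBROLIZUMAB", "PEMBROLIZUMAB")], pts=["NAUSEA"])
    case("7070", "C007", "20190901", sex="M",
         drugs_=[("1", "PS", "YERVOY", "IPILIMUMAB")], pts=["PLEURAL EFFUSION"])
    case("7080", "C008", "20190901", sex="F", age="45",
         drugs_=[("1", "PS", "ASPIRIN", "ASPIRIN")], pts=["PNEUMONITIS", "HEADACHE"])
    case("7090", "C009", "20190901", sex="M", age="77",
         drugs_=[("1", "PS", "METFORMIN", "METFORMIN")], pts=["PNEUMONIA"])
    case("7100", "C010", "20190901", sex="F",
         drugs_=[("1", "PS", "ASPIRIN", "ASPIRIN")], pts=["DYSPNOEA"])
    case("7110", "C011", "20190901", sex="M",
         drugs_=[("1", "PS", "TECENTRIQ", "ATEZOLIZUMAB")], pts=["PNEUMONIA"],
         outcomes=["LT"])
    case("7120", "C012", "20190901", sex="M", age="69",
         drugs_=[("1", "PS", "IMFINZI", "DURVALUMAB")], pts=["PNEUMONITIS"])
    case("7130", "C013", "20190901", sex="F",
         drugs_=[("1", "PS", "BAVENCIO", "AVELUMAB")], pts=["PLEURAL EFFUSION"])
    case("7140", "C014", "20190901", sex="M",
         drugs_=[("1", "PS", "LIBTAYO", "CEMIPLIMAB")], pts=["INTERSTITIAL LUNG DISEASE"])
    case("7150", "C015", "20190901", sex="M", age="81",
         drugs_=[("1", "PS", "TREMELIMUMAB", "TREMELIMUMAB")], pts=["COUGH"])
    case("7160", "C016", "20190901", sex="F",
         drugs_=[("1", "PS", "IBUPROFEN", "IBUPROFEN")], pts=["RASH"])
    # verbatim with dose suffix: matched by word-boundary substring / PROD_AI
    case("7170", "C017", "20190901", sex="M",
         drugs_=[("1", "PS", "OPDIVO 10MG/ML", "NIVOLUMAB")], pts=["PNEUMONIA"])
    case("7180", "C018", "20190901", sex="F",
         drugs_=[("1", "PS", "OMEPRAZOLE", "OMEPRAZOLE")], pts=["PNEUMONITIS"])
    case("7190", "C019", "20190901", sex="M",
         drugs_=[("1", "PS", "ATORVASTATIN", "ATORVASTATIN")], pts=["NAUSEA"])
    # month-precision therapy start: onset excluded as partial precision
    case("7200", "C020", "20190901", event="20190620", sex="F",
         drugs_=[nivo], pts=["DYSPNOEA"], thers=[("1", "201905")])

    return RawQuarter(quarter_label="FIXTURE", demo_rows=demo, drug_rows=drug,
                      reac_rows=reac, outc_rows=outc, ther_rows=ther)


def fixture_pairs_10() -> pd.DataFrame:
    """A 10-pair toy universe with contingency (2, 4, 5, 10) for drug D x event E.

    Expected count 4*5/10 = 2.0, shrunk ROR (2+0.5)/(2+0.5) = 1.0, IC = 0.
    """
    rows = [
        ("D", "E"), ("D", "E"), ("D", "X"), ("D", "Y"),
        ("A", "E"), ("B", "E"), ("C", "E"),
        ("A", "X"), ("B", "Y"), ("C", "Z"),
    ]
    return pd.DataFrame(rows, columns=["drug", "pt"])
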