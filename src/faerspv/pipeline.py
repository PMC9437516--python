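"""Orchestration: ingest -> dedup -> map -> analyze -> report.

Drives the whole analysis from a single YAML/JSON config and emits tidy
CSV outputs plus a run manifest.  Every CSV carries the config hash in a
leading ``#`` comment line so outputs are traceable to the run that
produced them; the manifest records the filter funnel

    raw report versions >= deduplicated reports            (report level)
    all pairs >= ICI pairs >= respiratory ICI pairs        (pair level)

and funnel monotonicity is asserted at run time (a violation is a bug in
the pipeline, not a data property, so it is a hard error).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import descriptives, disprop, onset as onset_mod
from .dedup import deduplicate
from .faers_io import merge_quarters, read_quarter
from .vocab import (
    DEFAULT_ROLE_FILTER,
    annotate_classes,
    default_drug_dictionary,
    default_event_dictionary,
    extract_pairs,
    load_drug_dictionary,
    load_event_dictionary,
)

logger = logging.getLogger(__name__)

#: the five most frequently reported respiratory PTs, analyzed drug-by-drug
TOP_PTS = ["DYSPNOEA", "INTERSTITIAL LUNG DISEASE", "PNEUMONITIS",
           "PNEUMONIA", "PLEURAL EFFUSION"]


class FunnelError(RuntimeError):
    """Filter-funnel counts increased along a stage sequence."""


@dataclass
class RunManifest:
    config_hash: str
    input_files: list[str]
    funnel: dict[str, int]
    dedup: dict[str, int]
    orphans: int
    output_files: list[str] = field(default_factory=list)
    seed: int | None = None
    tool_version: str = "0.1.0"

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def write_csv(df: pd.DataFrame, path: Path, chash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={chash}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_output_csv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)


def _assert_funnel(counts: list[tuple[str, int]]) -> None:
    for (na, a), (nb, b) in zip(counts, counts[1:]):
        if b > a:
            raise FunnelError(f"funnel increased: {na}={a} -> {nb}={b}")


def build_pair_table(config: dict) -> tuple[pd.DataFrame, RunManifest]:
    """Ingest the configured quarters through dedup and pair extraction."""
    drug_dict = (load_drug_dictionary(config["drug_dictionary"])
                 if config.get("drug_dictionary") else default_drug_dictionary())
    event_dict = (load_event_dictionary(config["event_dictionary"])
                  if config.get("event_dictionary") else default_event_dictionary())

    quarters = []
    input_files: list[str] = []
    for q in config["quarters"]:
        quarters.append(read_quarter(q["demo"], q["drug"], q["reac"], q["outc"], q["ther"],
                                     quarter_label=q.get("label", "")))
        input_files += [q[k] for k in ("demo", "drug", "reac", "outc", "ther")]

    reports, asm_stats = merge_quarters(quarters)
    deduped, dstats = deduplicate(reports)

    role_filter = frozenset(config.get("role_filter", DEFAULT_ROLE_FILTER))
    pairs = extract_pairs(deduped, drug_dict, event_dict, role_filter=role_filter,
                          monotherapy_only=bool(config.get("monotherapy", False)))
    pairs = annotate_classes(pairs, event_dict)

    n_ici = int((pairs["drug"] != "other").sum())
    n_ici_resp = int(((pairs["drug"] != "other") & pairs["respiratory"]).sum())
    n_other_resp = int(((pairs["drug"] == "other") & pairs["respiratory"]).sum())
    funnel = {
        "raw_report_versions": dstats.n_input,
        "deduplicated_reports": dstats.n_output,
        "pairs_total": len(pairs),
        "pairs_ici": n_ici,
        "pairs_ici_respiratory": n_ici_resp,
        "pairs_other_respiratory": n_other_resp,
    }
    _assert_funnel([("raw_report_versions", dstats.n_input),
                    ("deduplicated_reports", dstats.n_output)])
    _assert_funnel([("pairs_total", len(pairs)), ("pairs_ici", n_ici),
                    ("pairs_ici_respiratory", n_ici_resp)])

    manifest = RunManifest(
        config_hash=config_hash(config),
        input_files=input_files,
        funnel=funnel,
        dedup={"n_input": dstats.n_input, "n_output": dstats.n_output,
               "n_removed": dstats.n_removed},
        orphans=asm_stats.n_orphans,
        seed=config.get("seed"),
    )
    return pairs, manifest


def run(config: dict | str | Path, out_dir: str | Path | None = None) -> RunManifest:
    """Execute the full analysis and write all outputs under ``out_dir``."""
    if not isinstance(config, dict):
        config = load_config(config)
    out_dir = Path(out_dir or config.get("out_dir", "results"))
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    interval_method = config.get("interval_method", "umc")

    drug_dict = (load_drug_dictionary(config["drug_dictionary"])
                 if config.get("drug_dictionary") else default_drug_dictionary())
    event_dict = (load_event_dictionary(config["event_dictionary"])
                  if config.get("event_dictionary") else default_event_dictionary())

    pairs, manifest = build_pair_table(config)
    ici_drugs = set(drug_dict.canonical_names)
    resp_pts = event_dict.all_pts

    # class-specific signals: all ICIs x each respiratory class (+ overall)
    event_sets = {name: event_dict.pts_in_class(name) for name in event_dict.class_names}
    event_sets["All respiratory"] = resp_pts
    by_class = disprop.signal_table(pairs, {"ICI (all)": ici_drugs}, event_sets,
                                    interval_method=interval_method)

    # drug-specific signals: each ICI x all respiratory events
    by_drug = disprop.signal_table(pairs, {d: {d} for d in sorted(ici_drugs)},
                                   {"All respiratory": resp_pts},
                                   interval_method=interval_method)

    # PT-level signals: each ICI x each top PT
    by_pt = disprop.signal_table(pairs, {d: {d} for d in sorted(ici_drugs)},
                                 {pt: {pt} for pt in TOP_PTS},
                                 interval_method=interval_method)

    # subgroup contrasts on respiratory pairs
    sub_rows = []
    for name, strat, la, lb in (("men_vs_women", "sex", "M", "F"),
                                ("age70_vs_under70", "age_group", ">=70", "<70"),
                                ("death_vs_nondeath", "death", True, False)):
        r = disprop.subgroup_ror(pairs, strat, la, lb, resp_pts)
        sub_rows.append({"contrast": name, "odds_ratio": r.odds_ratio,
                         "ci_low": r.ci_low, "ci_high": r.ci_high,
                         "a": r.a, "b": r.b, "c": r.c, "d": r.d,
                         "continuity_corrected": r.continuity_corrected,
                         "formula": r.formula})
    subgroups = pd.DataFrame(sub_rows)

    ici_pairs = pairs[(pairs["drug"] != "other") & pairs["respiratory"]]
    other_pairs = pairs[(pairs["drug"] == "other") & pairs["respiratory"]]
    chars = descriptives.characteristics(ici_pairs, other_pairs)
    deaths = descriptives.death_proportions(ici_pairs, event_dict)
    onsets = onset_mod.onset_by_class(ici_pairs, event_dict)

    outputs = {
        "signals_by_class.csv": by_class,
        "signals_by_drug.csv": by_drug,
        "signals_by_pt.csv": by_pt,
        "subgroups.csv": subgroups,
        "characteristics.csv": chars,
        "death_by_class.csv": deaths,
        "onset_by_class.csv": onsets,
    }
    for fname, df in outputs.items():
        path = out_dir / fname
        write_csv(df, path, chash)
        manifest.output_files.append(str(path))

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(manifest.to_json())
    manifest.output_files.append(str(manifest_path))
    logger.info("run complete: %d outputs in %s", len(manifest.output_files), out_dir)
    return manifest
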