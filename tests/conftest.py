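from pathlib import Path

import pandas as pd
import pytest

from faerspv.dedup import deduplicate
from faerspv.faers_io import assemble_reports
from faerspv.synthetic import fixture_small
from faerspv.vocab import (
    annotate_classes,
    default_drug_dictionary,
    default_event_dictionary,
    extract_pairs,
)


@pytest.fixture(scope="session")
def drug_dict():
    return default_drug_dictionary()


@pytest.fixture(scope="session")
def event_dict():
    return default_event_dictionary()


@pytest.fixture(scope="session")
def fixture_quarter():
    return fixture_small()


@pytest.fixture(scope="session")
def fixture_reports(fixture_quarter):
    """Deduplicated reports of the hand-checkable fixture corpus (20 cases)."""
    reports, _ = assemble_reports(fixture_quarter)
    deduped, _ = deduplicate(reports)
    return deduped


@pytest.fixture(scope="session")
def fixture_pairs(fixture_reports, drug_dict, event_dict):
    """The fixture's 22-pair universe, annotated with respiratory classes."""
    pairs = extract_pairs(fixture_reports, drug_dict, event_dict)
    return annotate_classes(pairs, event_dict)


def write_fixture_quarter(out_dir: Path) -> dict:
    """Serialize the hand-checkable fixture corpus as one quarterly extract."""
    out_dir.mkdir(parents=True, exist_ok=True)
    quarter = fixture_small()
    files = {}
    for role, rows in (("demo", quarter.demo_rows), ("drug", quarter.drug_rows),
                       ("reac", quarter.reac_rows), ("outc", quarter.outc_rows),
                       ("ther", quarter.ther_rows)):
        path = out_dir / f"{role}.txt"
        pd.DataFrame(rows).to_csv(path, sep="$", index=False, lineterminator="\n")
        files[role] = str(path)
    files["label"] = "FIXTURE"
    return files
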