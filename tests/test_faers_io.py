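"""Parsing and assembly of the '$'-delimited quarterly tables."""

import pytest

from faerspv.faers_io import (
    FormatError,
    PartialDate,
    RawQuarter,
    age_to_years,
    assemble_reports,
    parse_partial_date,
    read_quarter,
    read_table,
)
from faerspv.synthetic import SimConfig, generate


@pytest.mark.parametrize(
    "raw,expected",
    [
        ("20140215", PartialDate(2014, 2, 15)),
        ("201402", PartialDate(2014, 2)),
        ("2014", PartialDate(2014)),
        ("", None),
        ("   ", None),
        ("20140230", None),  # invalid calendar day
        ("20141315", None),  # invalid month
        ("2014-02", None),   # non-digit
    ],
)
def test_parse_partial_date(raw, expected):
    assert parse_partial_date(raw) == expected


def test_parse_partial_date_precision_and_warning_counter():
    assert parse_partial_date("20140215").precision == "day"
    assert parse_partial_date("201402").precision == "month"
    assert parse_partial_date("2014").precision == "year"
    counters = {}
    parse_partial_date("20140230", counters)
    parse_partial_date("20140215", counters)
    assert counters == {"invalid_date": 1}


@pytest.mark.parametrize(
    "age,cod,expected",
    [
        ("64", "YR", 64.0),
        ("6", "DEC", 60.0),
        ("24", "MON", 2.0),
        ("52.143", "WK", 1.0),
        ("365.25", "DY", 1.0),
        ("8766", "HR", 1.0),
        ("64", "", 64.0),      # missing unit read as years
        ("500", "YR", None),   # out of plausible range
        ("", "YR", None),
        ("abc", "YR", None),
    ],
)
def test_age_normalization(age, cod, expected):
    result = age_to_years(age, cod)
    if expected is None:
        assert result is None
    else:
        assert result == pytest.approx(expected)


def _write(path, lines):
    path.write_text("\n".join(lines) + "\n")
    return path


def test_read_table_minimal_demo(tmp_path):
    demo = _write(tmp_path / "demo.txt", [
        "primaryid$caseid$fda_dt$event_dt$age$age_cod$sex$occr_country",
        "101$C1$20200101$20191215$64$YR$M$US",
        "102$C2$20200102$$$$F$JP",
    ])
    rows = read_table(demo, "DEMO")
    assert len(rows) == 2
    assert rows[0]["PRIMARYID"] == "101"  # header case-insensitive, keys uppercased


def test_read_table_missing_column_names_file_and_column(tmp_path):
    demo = _write(tmp_path / "demo.txt", [
        "PRIMARYID$CASEID$EVENT_DT$AGE$AGE_COD$SEX$OCCR_COUNTRY",
        "101$C1$20191215$64$YR$M$US",
    ])
    with pytest.raises(FormatError, match="FDA_DT"):
        read_table(demo, "DEMO")
    with pytest.raises(FormatError, match="demo.txt"):
        read_table(demo, "DEMO")


def test_read_table_empty_file(tmp_path):
    empty = tmp_path / "demo.txt"
    empty.write_text("")
    with pytest.raises(FormatError, match="empty"):
        read_table(empty, "DEMO")


def _quarter(demo=(), drug=(), reac=(), outc=(), ther=()):
    return RawQuarter("T", list(demo), list(drug), list(reac), list(outc), list(ther))


def test_assemble_join_semantics():
    quarter = _quarter(
        demo=[{"PRIMARYID": "1", "CASEID": "C1", "FDA_DT": "20200101", "EVENT_DT": "",
               "AGE": "60", "AGE_COD": "YR", "SEX": "F", "OCCR_COUNTRY": "US"}],
        drug=[{"PRIMARYID": "1", "DRUG_SEQ": "1", "ROLE_COD": "PS",
               "DRUGNAME": "nivolumab", "PROD_AI": "NIVOLUMAB"},
              {"PRIMARYID": "1", "DRUG_SEQ": "2", "ROLE_COD": "C",
               "DRUGNAME": "aspirin", "PROD_AI": ""}],
        reac=[{"PRIMARYID": "1", "PT": "Pneumonitis"},
              {"PRIMARYID": "1", "PT": "dyspnoea"},
              {"PRIMARYID": "1", "PT": "COUGH"}],
        ther=[{"PRIMARYID": "1", "DSG_DRUG_SEQ": "2", "START_DT": "20191201"}],
    )
    reports, stats = assemble_reports(quarter)
    assert len(reports) == 1 and stats.n_orphans == 0
    r = reports[0]
    assert len(r.drugs) == 2 and len(r.reactions) == 3
    assert r.reactions == ["PNEUMONITIS", "DYSPNOEA", "COUGH"]  # uppercased
    # therapy start attached to drug_seq 2 only
    by_seq = {d.drug_seq: d for d in r.drugs}
    assert by_seq[2].therapy_start == PartialDate(2019, 12, 1)
    assert by_seq[1].therapy_start is None


def test_assemble_earliest_therapy_start_per_drug_seq():
    quarter = _quarter(
        demo=[{"PRIMARYID": "1", "CASEID": "C1", "FDA_DT": "20200101", "EVENT_DT": "",
               "AGE": "", "AGE_COD": "", "SEX": "M", "OCCR_COUNTRY": ""}],
        drug=[{"PRIMARYID": "1", "DRUG_SEQ": "1", "ROLE_COD": "PS",
               "DRUGNAME": "X", "PROD_AI": ""}],
        ther=[{"PRIMARYID": "1", "DSG_DRUG_SEQ": "1", "START_DT": "20190601"},
              {"PRIMARYID": "1", "DSG_DRUG_SEQ": "1", "START_DT": "20190301"}],
    )
    reports, _ = assemble_reports(quarter)
    assert reports[0].drugs[0].therapy_start == PartialDate(2019, 3, 1)


def test_assemble_counts_orphans():
    quarter = _quarter(
        demo=[{"PRIMARYID": "1", "CASEID": "C1", "FDA_DT": "20200101", "EVENT_DT": "",
               "AGE": "", "AGE_COD": "", "SEX": "M", "OCCR_COUNTRY": ""}],
        reac=[{"PRIMARYID": "1", "PT": "NAUSEA"},
              {"PRIMARYID": "99", "PT": "NAUSEA"},
              {"PRIMARYID": "98", "PT": "RASH"}],
    )
    reports, stats = assemble_reports(quarter)
    assert len(reports) == 1
    assert stats.orphan_reac == 2 and stats.n_orphans == 2


def test_no_report_lost_or_duplicated(fixture_quarter):
    reports, _ = assemble_reports(fixture_quarter)
    pids = {row["PRIMARYID"] for row in fixture_quarter.demo_rows}
    assert len(reports) == len(pids)
    assert len({r.primaryid for r in reports}) == len(reports)


def test_generator_round_trip_row_counts(tmp_path):
    """Writing a synthetic quarter and reading it back preserves every row."""
    config = SimConfig(seed=5, n_cases=300, n_orphan_reac=4)
    manifest = generate(config, tmp_path)
    total_demo = total_reac = 0
    n_reports = 0
    for label, files in manifest["quarters"].items():
        quarter = read_quarter(files["DEMO"], files["DRUG"], files["REAC"],
                               files["OUTC"], files["THER"], quarter_label=label)
        total_demo += len(quarter.demo_rows)
        total_reac += len(quarter.reac_rows)
        reports, stats = assemble_reports(quarter)
        n_reports += len(reports)
    assert total_demo == manifest["counts"]["n_versions"]
    assert n_reports == manifest["counts"]["n_versions"]
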