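"""Drug normalization, event classification, and pair extraction."""

import pytest

from faerspv.faers_io import CaseReport, DrugEntry
from faerspv.vocab import (
    DictionaryError,
    DrugDictionary,
    classify_event,
    default_drug_dictionary,
    extract_pairs,
    normalize_drug,
)


@pytest.mark.parametrize(
    "verbatim,ai,expected",
    [
        ("OPDIVO", None, "nivolumab"),                    # exact synonym
        ("opdivo", None, "nivolumab"),                    # case-insensitive
        ("NIVOLUMAB 10MG/ML INJ", None, "nivolumab"),     # word-boundary substring
        ("KEYTRUDA (PEMBROLIZUMAB)", None, "pembrolizumab"),
        ("SOME DRUG", "NIVOLUMAB", "nivolumab"),          # active ingredient wins
        ("ASPIRIN", None, "other"),
        ("NIVOLUMABX", None, "other"),                    # no boundary match
        ("", None, "other"),
    ],
)
def test_normalize_drug(verbatim, ai, expected, drug_dict):
    assert normalize_drug(verbatim, ai, drug_dict) == expected


def test_combination_strings_map_to_other_with_counter(drug_dict):
    counters = {}
    for verbatim in ("IPILIMUMAB AND NIVOLUMAB", "NIVOLUMAB/IPILIMUMAB",
                     "OPDIVO + YERVOY"):
        assert normalize_drug(verbatim, None, drug_dict, counters) == "other"
    assert counters["combination"] == 3


def test_active_ingredient_priority_over_substring(drug_dict):
    # AI names one drug exactly; verbatim would substring-match another
    assert normalize_drug("GIVEN WITH NIVOLUMAB", "IPILIMUMAB", drug_dict) == "ipilimumab"


def test_dictionary_rejects_shared_synonyms():
    with pytest.raises(DictionaryError, match="claimed by both"):
        DrugDictionary(entries={
            "nivolumab": {"ici_class": "anti-PD-1", "synonyms": {"OPDIVO"}},
            "pembrolizumab": {"ici_class": "anti-PD-1", "synonyms": {"OPDIVO"}},
        })


def test_default_dictionary_has_the_eight_icis(drug_dict):
    assert set(drug_dict.canonical_names) == {
        "nivolumab", "cemiplimab", "pembrolizumab",
        "atezolizumab", "avelumab", "durvalumab",
        "ipilimumab", "tremelimumab",
    }
    assert drug_dict.drugs_in_class("anti-PD-1") == {"nivolumab", "cemiplimab", "pembrolizumab"}
    assert drug_dict.drugs_in_class("anti-CTLA-4") == {"ipilimumab", "tremelimumab"}


def test_classify_event(event_dict):
    assert classify_event("PNEUMONITIS", event_dict) == {"Lower respiratory tract disorders"}
    assert classify_event("pneumonitis", event_dict) == {"Lower respiratory tract disorders"}
    # multi-class PT returns every containing class
    assert classify_event("WHEEZING", event_dict) == {
        "Bronchial disorders", "Respiratory tract signs and symptoms"}
    assert classify_event("NAUSEA", event_dict) == set()


def test_event_dictionary_covers_the_ten_classes(event_dict):
    from faerspv.vocab import RESPIRATORY_CLASS_CODES
    assert set(event_dict.class_names) == set(RESPIRATORY_CLASS_CODES)
    assert event_dict.classes["Bronchial disorders"]["meddra_code"] == "10006436"
    assert event_dict.classes["Upper respiratory tract disorders"]["meddra_code"] == "10046304"


def _report(pid, caseid, drugs, pts):
    return CaseReport(primaryid=pid, caseid=caseid, fda_dt=None, event_dt=None,
                      age_years=None, sex="M", country="US",
                      drugs=drugs, reactions=list(pts))


def test_pair_unit_semantics(drug_dict, event_dict):
    # one suspect ICI x two PTs -> 2 pairs
    r1 = _report("1", "C1",
                 [DrugEntry(1, "PS", "NIVOLUMAB", "NIVOLUMAB")],
                 ["PNEUMONITIS", "DYSPNOEA"])
    # two suspect ICIs x one PT -> 2 pairs under role filter {PS, SS}
    r2 = _report("2", "C2",
                 [DrugEntry(1, "PS", "NIVOLUMAB", "NIVOLUMAB"),
                  DrugEntry(2, "SS", "YERVOY", "IPILIMUMAB")],
                 ["COUGH"])
    pairs = extract_pairs([r1, r2], drug_dict, event_dict)
    assert len(pairs) == 4
    assert len(pairs[pairs["primaryid"] == "1"]) == 2
    assert set(pairs[pairs["primaryid"] == "2"]["drug"]) == {"nivolumab", "ipilimumab"}


def test_role_filter_excludes_concomitants(drug_dict, event_dict):
    r = _report("1", "C1",
                [DrugEntry(1, "PS", "ASPIRIN", None),
                 DrugEntry(2, "C", "NIVOLUMAB", "NIVOLUMAB")],
                ["PNEUMONITIS"])
    pairs = extract_pairs([r], drug_dict, event_dict)
    assert list(pairs["drug"]) == ["other"]
    pairs_all = extract_pairs([r], drug_dict, event_dict, role_filter={"PS", "SS", "C"})
    assert set(pairs_all["drug"]) == {"other", "nivolumab"}


def test_duplicate_pt_in_report_yields_one_pair(drug_dict, event_dict):
    r = _report("1", "C1", [DrugEntry(1, "PS", "NIVOLUMAB", "NIVOLUMAB")],
                ["PNEUMONITIS", "PNEUMONITIS"])
    assert len(extract_pairs([r], drug_dict, event_dict)) == 1


def test_monotherapy_filter(fixture_reports, drug_dict, event_dict):
    all_pairs = extract_pairs(fixture_reports, drug_dict, event_dict)
    mono = extract_pairs(fixture_reports, drug_dict, event_dict, monotherapy_only=True)
    # the fixture's combination case (nivolumab + ipilimumab) is dropped: 2 pairs
    assert len(all_pairs) - len(mono) == 2
    assert not (mono["n_ici"] > 1).any()


def test_pair_count_is_sum_of_products(fixture_reports, drug_dict, event_dict):
    pairs = extract_pairs(fixture_reports, drug_dict, event_dict)
    expected = 0
    for r in fixture_reports:
        keys = set()
        for d in r.drugs:
            if d.role not in {"PS", "SS"}:
                continue
            canonical = normalize_drug(d.verbatim_name, d.active_ingredient, drug_dict)
            keys.add(canonical if canonical != "other" else d.verbatim_name)
        expected += len(keys) * len(set(r.reactions))
    assert len(pairs) == expected == 22
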