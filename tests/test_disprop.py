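"""Shrinkage ROR / IC statistics against hand computations and brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from faerspv.disprop import (
    ContingencyCounts,
    build_contingency,
    compute_signal,
    expected_count,
    ic_credibility_interval,
    ic_interval,
    information_component,
    odds_ratio_2x2,
    ror_interval,
    round_half_up,
    shrunk_ror,
    signal_flags,
    signal_table,
    subgroup_ror,
)


def C(n_obs, n_drug, n_event, n_total):
    return ContingencyCounts(n_obs, n_drug, n_event, n_total)


class TestExpectedCount:
    def test_formula(self):
        assert expected_count(C(10, 100, 50, 1000)) == pytest.approx(5.0)
        assert expected_count(C(2, 4, 5, 10)) == pytest.approx(2.0)

    def test_zero_drug_margin(self):
        assert expected_count(C(0, 0, 5, 10)) == 0.0

    def test_empty_universe_is_an_error(self):
        with pytest.raises(ValueError):
            expected_count(C(0, 0, 0, 0))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            C(5, 4, 10, 20)  # n_observed > n_drug


class TestShrunkRatio:
    def test_hand_computation(self):
        # observed 20 against expected 100*50/1000 = 5
        c = C(20, 100, 50, 1000)
        assert shrunk_ror(c) == pytest.approx(20.5 / 5.5)
        assert shrunk_ror(c) == pytest.approx(3.7273, abs=1e-4)
        assert information_component(c) == pytest.approx(1.8982, abs=1e-3)

    def test_shrinkage_null_at_zero(self):
        c = C(0, 0, 5, 10)  # expected 0, observed 0
        assert shrunk_ror(c) == 1.0
        assert information_component(c) == 0.0

    def test_fixture_universe(self, fixture_pairs):
        c = build_contingency(fixture_pairs, {"nivolumab"}, {"PNEUMONITIS"})
        assert (c.n_observed, c.n_drug, c.n_event, c.n_total) == (2, 6, 5, 22)
        assert shrunk_ror(c) == pytest.approx(2.5 / (30 / 22 + 0.5))


class TestIntervals:
    # printed-table spot checks: (n_observed, ROR) -> rounded IC bounds
    @pytest.mark.parametrize(
        "n_obs,ror,ic025",
        [(318, 1.40, 0.30), (2989, 3.11, 1.58), (414, 1.29, 0.21)],
    )
    def test_umc_lower_bound_reproduces_published_values(self, n_obs, ror, ic025):
        lo, _ = ic_credibility_interval(math.log2(ror), n_obs)
        assert round_half_up(lo, 2) == ic025

    def test_umc_upper_bound_reproduces_published_value(self):
        _, hi = ic_credibility_interval(math.log2(1.47), 13241)
        assert round_half_up(hi, 2) == 0.58

    def test_ror_bounds_are_ic_consistent_by_default(self):
        c = C(50, 400, 600, 20000)
        ic_lo, ic_hi = ic_interval(c)
        ror_lo, ror_hi = ror_interval(c)
        assert ror_lo == pytest.approx(2.0 ** ic_lo)
        assert ror_hi == pytest.approx(2.0 ** ic_hi)

    def test_wald_close_to_umc_at_large_counts(self):
        # with n_observed >= 1000 and rare margins (odds ratio ~ relative
        # ratio) the two interval constructions agree within 5% relative
        c = C(1200, 100_000, 100_000, 10_000_000)
        lo_u, hi_u = ror_interval(c, "umc")
        lo_w, hi_w = ror_interval(c, "wald")
        assert lo_w == pytest.approx(lo_u, rel=0.05)
        assert hi_w == pytest.approx(hi_u, rel=0.05)

    def test_wald_undefined_on_zero_cell(self):
        lo, hi = ror_interval(C(0, 0, 5, 10), "wald")
        assert math.isnan(lo) and math.isnan(hi)

    def test_interval_width_shrinks_with_count(self):
        widths = []
        for n_obs in (10, 100, 1000, 10000):
            lo, hi = ic_credibility_interval(1.0, n_obs)
            widths.append(hi - lo)
        assert widths == sorted(widths, reverse=True)
        assert widths[-1] < 0.1


class TestSignalFlags:
    def test_strict_inequalities(self):
        assert signal_flags(1.0, 0.0) == (False, False)
        assert signal_flags(1.0001, 0.0001) == (True, True)

    def test_published_nonsignal_and_signal(self):
        # ipilimumab-style: ROR025 0.70, IC025 -0.54 -> no signal
        assert signal_flags(0.70, -0.54) == (False, False)
        # durvalumab-style: ROR025 2.99, IC025 1.58 -> signal
        assert signal_flags(2.99, 1.58) == (True, True)


@st.composite
def counts_strategy(draw):
    n_total = draw(st.integers(1, 5000))
    n_drug = draw(st.integers(0, n_total))
    n_event = draw(st.integers(0, n_total))
    n_obs = draw(st.integers(max(0, n_drug + n_event - n_total), min(n_drug, n_event)))
    return (n_obs, n_drug, n_event, n_total)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(counts_strategy())
def test_ic_is_log2_of_ror_to_machine_precision(t):
    r = compute_signal(C(*t))
    assert r.ic == math.log2(r.ror)
    assert r.ic_025 <= r.ic <= r.ic_975
    assert r.signal_ic == (r.ic_025 > 0.0)
    assert r.signal_ror == (r.ror_025 > 1.0)


def test_monotone_in_observed_count():
    rors, ics = [], []
    for n_obs in range(0, 50):
        c = C(n_obs, 100, 80, 10000)
        rors.append(shrunk_ror(c))
        ics.append(information_component(c))
    assert all(b > a for a, b in zip(rors, rors[1:]))
    assert all(b > a for a, b in zip(ics, ics[1:]))


def test_vectorized_counts_equal_brute_force():
    """signal_table vs a naive per-combination loop on a random universe."""
    rng = np.random.default_rng(17)
    drugs = [f"D{i}" for i in range(8)]
    events = [f"E{j}" for j in range(20)]
    pairs = pd.DataFrame({
        "drug": rng.choice(drugs, 5000),
        "pt": rng.choice(events, 5000),
    })
    table = signal_table(pairs, {d: {d} for d in drugs}, {e: {e} for e in events})
    for _, row in table.sample(40, random_state=3).iterrows():
        d, e = row["drug_set"], row["event_set"]
        n_obs = sum((pairs["drug"] == d) & (pairs["pt"] == e))
        n_drug = sum(pairs["drug"] == d)
        n_event = sum(pairs["pt"] == e)
        assert (row["n_observed"], row["n_drug"], row["n_event"], row["n_total"]) == \
               (n_obs, n_drug, n_event, len(pairs))
        ref = compute_signal(C(n_obs, n_drug, n_event, len(pairs)))
        assert row["ror"] == pytest.approx(ref.ror)
        assert row["ic_025"] == pytest.approx(ref.ic_025)


def test_degenerate_event_set_covers_universe(fixture_pairs):
    all_events = set(fixture_pairs["pt"])
    c = build_contingency(fixture_pairs, {"nivolumab"}, all_events)
    assert c.n_event == c.n_total
    assert c.n_observed == c.n_drug


class TestSubgroupOddsRatio:
    def test_hand_computation(self):
        r = odds_ratio_2x2(10, 10, 5, 20)
        assert r.odds_ratio == pytest.approx(4.0)
        assert not r.continuity_corrected

    def test_zero_cell_continuity_correction(self):
        r = odds_ratio_2x2(5, 0, 3, 7)
        assert r.continuity_corrected
        assert math.isfinite(r.odds_ratio)

    def test_null_case_identical_distributions(self):
        pairs = pd.DataFrame({
            "pt": ["E"] * 400,
            "sex": (["M"] * 100 + ["F"] * 100) * 2,
            "ici_class": ["anti-PD-1"] * 200 + [""] * 200,
        })
        r = subgroup_ror(pairs, "sex", "M", "F", {"E"})
        assert r.odds_ratio == pytest.approx(1.0)

    def test_recovers_injected_twofold_male_excess(self):
        rng = np.random.default_rng(29)
        n_ici, n_other = 4000, 8000
        # ICI stratum: odds M:F = 2:1; control stratum: 1:1
        sex_ici = rng.choice(["M", "F"], n_ici, p=[2 / 3, 1 / 3])
        sex_other = rng.choice(["M", "F"], n_other, p=[0.5, 0.5])
        pairs = pd.DataFrame({
            "pt": ["E"] * (n_ici + n_other),
            "sex": np.concatenate([sex_ici, sex_other]),
            "ici_class": ["anti-PD-1"] * n_ici + [""] * n_other,
        })
        r = subgroup_ror(pairs, "sex", "M", "F", {"E"})
        assert r.ci_low < 2.0 < r.ci_high

    def test_missing_stratum_levels_excluded(self):
        pairs = pd.DataFrame({
            "pt": ["E"] * 6,
            "sex": ["M", "F", "unknown", "M", "F", "unknown"],
            "ici_class": ["anti-PD-1"] * 3 + [""] * 3,
        })
        r = subgroup_ror(pairs, "sex", "M", "F", {"E"})
        assert r.a + r.b + r.c + r.d == 4


def test_round_half_up():
    assert round_half_up(0.305, 2) == 0.31
    assert round_half_up(0.304999, 2) == 0.30
    assert round_half_up(2.675, 2) == 2.68
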