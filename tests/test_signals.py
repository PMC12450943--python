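"""Disproportionality statistics: frozen examples and structural properties."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from faersig import (
    ContingencyTable,
    bcpnn_ic,
    build_contingency,
    evaluate_signal,
    mgps_ebgm,
    prr_chi2,
    rank_signals,
    ror_stat,
    signal_table,
)

from conftest import make_case_data

TABLE = ContingencyTable(10, 90, 100, 9900)
INDEPENDENCE = ContingencyTable(10, 90, 100, 900)  # a/b == c/d


class TestRor:
    def test_point_estimate(self):
        assert ror_stat(TABLE)[0] == pytest.approx(11.0, rel=1e-12)

    def test_delta_method_interval(self):
        _, lo, hi = ror_stat(TABLE)
        assert lo == pytest.approx(5.56, abs=0.01)
        assert hi == pytest.approx(21.77, abs=0.01)

    def test_independence_gives_unity(self):
        assert ror_stat(INDEPENDENCE)[0] == pytest.approx(1.0, rel=1e-12)


class TestPrrChi2:
    def test_point_estimate(self):
        assert prr_chi2(TABLE)[0] == pytest.approx(10.0, rel=1e-12)

    def test_pearson_chi2_with_and_without_yates(self):
        _, _, _, yates, uncorrected = prr_chi2(TABLE)
        assert uncorrected == pytest.approx(74.45, abs=0.01)
        assert yates == pytest.approx(66.32, abs=0.01)

    def test_independence_gives_unity_and_zero_chi2(self):
        prr, _, _, _, uncorrected = prr_chi2(INDEPENDENCE)
        assert prr == pytest.approx(1.0)
        assert uncorrected == pytest.approx(0.0, abs=1e-12)

    def test_empty_background_event_column_gives_infinite_prr(self):
        prr, lo, hi, _, _ = prr_chi2(ContingencyTable(5, 95, 0, 900))
        assert math.isinf(prr)
        assert math.isnan(lo) and math.isnan(hi)


class TestBayesianPair:
    def test_ic_zero_when_observed_equals_expected(self):
        t = ContingencyTable(10, 90, 990, 8910)  # E = 100*1000/10000 = 10
        assert bcpnn_ic(t)[0] == pytest.approx(0.0, abs=1e-12)

    def test_ic_equals_log2_relative_reporting_ratio(self):
        ic, _ = bcpnn_ic(TABLE)
        assert ic == pytest.approx(math.log2(9.1818), abs=1e-4)

    def test_ebgm_point_estimate_and_independence(self):
        assert mgps_ebgm(TABLE)[0] == pytest.approx(9.1818, abs=1e-4)
        assert mgps_ebgm(INDEPENDENCE)[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("cells", [(10, 90, 100, 9900), (3, 7, 11, 200), (50, 5, 9, 2)])
    def test_ic_is_exactly_log2_of_ebgm(self, cells):
        t = ContingencyTable(*cells)
        assert bcpnn_ic(t)[0] == pytest.approx(math.log2(mgps_ebgm(t)[0]), abs=1e-14)


class TestEvaluateSignal:
    def test_mhra_flag_on_strong_table(self):
        r = evaluate_signal(TABLE)
        assert r.flag_prr_mhra  # prr=10>=2, chi2>=4, n=10>=3
        assert r.positive

    def test_minimum_case_count_blocks_frequentist_flags(self):
        r = evaluate_signal(ContingencyTable(2, 1, 5, 5000))
        assert r.ror > 100  # enormous ROR, but n < 3
        assert not r.flag_ror and not r.flag_prr_mhra and not r.flag_mgps

    def test_independence_is_not_positive(self):
        assert not evaluate_signal(INDEPENDENCE).positive

    def test_positive_equals_or_of_flags(self):
        r = evaluate_signal(TABLE)
        assert r.positive == (r.flag_ror or r.flag_prr_mhra or r.flag_bcpnn or r.flag_mgps)


@given(
    st.tuples(
        st.integers(1, 400), st.integers(1, 400), st.integers(1, 400), st.integers(1, 400)
    )
)
@settings(max_examples=300, deadline=None)
def test_ordering_and_row_swap_properties(cells):
    """ROR >= PRR >= EBGM when ROR > 1 (reversed below 1); row swap inverts ROR."""
    t = ContingencyTable(*cells)
    ror = ror_stat(t)[0]
    prr = prr_chi2(t)[0]
    ebgm = mgps_ebgm(t)[0]
    eps = 1e-9
    if ror > 1:
        assert ror >= prr - eps >= ebgm - 2 * eps
    elif ror < 1:
        assert ror <= prr + eps <= ebgm + 2 * eps
    swapped = ContingencyTable(t.c, t.d, t.a, t.b)
    assert ror_stat(swapped)[0] == pytest.approx(1.0 / ror, rel=1e-9)


class TestBuildContingency:
    def test_two_by_two_toy(self):
        data = make_case_data(
            [
                {"caseid": "1", "drugs": [("X", "PS")], "events": ["E"]},
                {"caseid": "2", "drugs": [("X", "PS")], "events": ["F"]},
                {"caseid": "3", "drugs": [("Y", "PS")], "events": ["E"]},
                {"caseid": "4", "drugs": [("Y", "PS")], "events": ["F"]},
            ]
        )
        t = build_contingency(data, "X", "E")
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_repeated_event_counts_once_per_report(self):
        data = make_case_data(
            [
                {"caseid": "1", "drugs": [("X", "PS")], "events": ["E", "E"]},
                {"caseid": "2", "drugs": [("Y", "PS")], "events": ["F"]},
            ]
        )
        t = build_contingency(data, "X", "E")
        assert t.a == 1

    def test_a_cell_matches_generator_bookkeeping(self, injected_cohort):
        data, manifest, config = injected_cohort
        key = manifest.pair_key(config.target_drug, "Alopecia")
        t = build_contingency(data, config.target_drug, "Alopecia")
        assert t.a == manifest.drug_event_counts[key]


class TestRankSignals:
    def _table(self, rows):
        import pandas as pd

        return pd.DataFrame(rows)

    def test_frequency_descending(self):
        df = self._table(
            [{"event": "A", "n": 5, "ror": 1.0}, {"event": "B", "n": 9, "ror": 1.0}, {"event": "C", "n": 7, "ror": 1.0}]
        )
        assert rank_signals(df, by="frequency")["n"].tolist() == [9, 7, 5]

    def test_ties_broken_alphabetically(self):
        df = self._table(
            [{"event": "Zeta", "n": 7, "ror": 1.0}, {"event": "Alpha", "n": 7, "ror": 1.0}]
        )
        assert rank_signals(df, by="frequency")["event"].tolist() == ["Alpha", "Zeta"]

    def test_injected_pair_ranks_first_by_ror_among_positives(self, injected_cohort):
        data, _, config = injected_cohort
        table = signal_table(data, config.target_drug)
        positives = table[table["positive"]]
        top = rank_signals(positives, by="ror").iloc[0]["event"]
        injected = {i["event"] for i in (inj.model_dump() for inj in config.signal_injections)}
        assert top in injected
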