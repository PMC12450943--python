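"""Omega shrinkage drug-drug interaction statistics and screening."""

from __future__ import annotations

import math

import numpy as np
import pytest

from faersig import (
    CaseData,
    DDIInjection,
    GeneratorConfig,
    PairEventCounts,
    detect_ddi,
    omega_interval,
    omega_statistic,
    pair_counts,
    simulate_quarter,
)

from conftest import make_case_data


def counts_with(n11: int, e11: float, n_total: int = 10000) -> PairEventCounts:
    """Construct margins realizing a wanted E11 = n1dot*ndot1/n_total."""
    n1dot = max(n11, 50)
    ndot1 = round(e11 * n_total / n1dot)
    return PairEventCounts("A", "B", "E", n11, n1dot, ndot1, n_total)


class TestOmegaStatistic:
    def test_shrinkage_preserves_equality(self):
        r = omega_statistic(counts_with(12, 12.0))
        assert r.omega == pytest.approx(0.0, abs=1e-12)

    def test_point_estimate_and_interval(self):
        r = omega_statistic(counts_with(20, 5.0))
        assert r.omega == pytest.approx(math.log2(20.5 / 5.5), rel=1e-12)
        se = 1 / (math.log(2) * math.sqrt(20))
        assert r.omega_lo == pytest.approx(r.omega - 1.96 * se, rel=1e-12)
        assert (round(r.omega_lo, 2), round(r.omega_hi, 2)) == (1.27, 2.53)

    def test_interval_from_point_estimate_alone(self):
        lo, hi = omega_interval(0.61, 23)
        assert (round(lo, 2), round(hi, 2)) == (0.02, 1.20)

    def test_zero_co_reports_never_significant(self):
        r = omega_statistic(PairEventCounts("A", "B", "E", 0, 10, 40, 1000))
        assert math.isnan(r.omega_lo)
        assert not r.significant

    def test_shrinkage_contraction(self):
        for n11, e11 in [(3, 1.0), (9, 2.5), (4, 11.0), (40, 12.0)]:
            r = omega_statistic(counts_with(n11, e11))
            assert abs(r.omega) <= abs(math.log2(n11 / e11)) + 1e-12

    def test_monotonicity_in_observed_and_expected(self):
        base = omega_statistic(counts_with(10, 5.0)).omega
        assert omega_statistic(counts_with(20, 5.0)).omega > base
        assert omega_statistic(counts_with(10, 9.0)).omega < base

    def test_vanishing_shrinkage_recovers_raw_ratio(self):
        c = counts_with(20, 5.0)
        raw = math.log2(20 / omega_statistic(c).e11)
        assert omega_statistic(c, alpha_shrink=1e-12).omega == pytest.approx(raw, abs=1e-9)

    @pytest.mark.parametrize("n11", [4, 16, 64])
    def test_ci_width_halves_as_n11_quadruples(self, n11):
        lo, hi = omega_interval(1.0, n11)
        assert hi - lo == pytest.approx(2 * 1.96 / (math.log(2) * math.sqrt(n11)), rel=1e-12)


class TestPairCounts:
    def _toy(self):
        specs = []
        for i, (drugs, events) in enumerate(
            [
                ([("A", "PS"), ("B", "C")], ["E"]),
                ([("A", "PS"), ("B", "SS")], ["E"]),
                ([("A", "PS"), ("B", "C")], ["F"]),
                ([("A", "PS")], ["E"]),
                ([("B", "PS")], ["E"]),
                ([("C", "PS")], ["F"]),
            ]
        ):
            specs.append({"caseid": str(i), "drugs": drugs, "events": events})
        return make_case_data(specs)

    def test_report_level_counting_any_corole(self):
        c = pair_counts(self._toy(), "A", "B", "E")
        assert c.n11 == 2  # co-drug matched in C and SS roles alike
        assert c.n1dot == 3
        assert c.ndot1 == 4
        assert c.n_total == 6

    def test_absent_co_drug_gives_zero_margins(self):
        c = pair_counts(self._toy(), "A", "ZZZ", "E")
        assert c.n11 == 0 and c.n1dot == 0

    def test_counts_match_generator_bookkeeping(self):
        config = GeneratorConfig(
            n_cases=4000,
            seed=77,
            ddi_injections=[DDIInjection(drug_a="SARILUMAB", drug_b="UPADACITINIB", event="Malaise", multiplier=8.0)],
        )
        tables, manifest, _ = simulate_quarter(config)
        data = CaseData.from_tables(tables)
        c = pair_counts(data, "SARILUMAB", "UPADACITINIB", "Malaise", role_filter_a=("PS",))
        key = manifest.ddi_key("SARILUMAB", "UPADACITINIB", "Malaise")
        assert c.n11 == manifest.pair_event_counts[key]


class TestDetectDdi:
    def test_zero_co_reports_yield_no_rows(self):
        data = make_case_data(
            [{"caseid": "1", "drugs": [("A", "PS")], "events": ["E"]},
             {"caseid": "2", "drugs": [("B", "PS")], "events": ["E"]}]
        )
        assert detect_ddi(data, "A", ["C"]).empty

    def test_injected_interaction_flagged_significant(self):
        config = GeneratorConfig(
            n_cases=20000,
            seed=99,
            ddi_injections=[DDIInjection(drug_a="SARILUMAB", drug_b="UPADACITINIB", event="Malaise", multiplier=10.0)],
        )
        tables, _, _ = simulate_quarter(config)
        data = CaseData.from_tables(tables)
        screen = detect_ddi(data, "SARILUMAB", ["UPADACITINIB"], top_k_events=20)
        row = screen[screen["event_pt"] == "Malaise"].iloc[0]
        assert row["n11"] >= 30
        assert row["significant"]

    def test_null_pair_significance_rate_calibrated(self):
        """An independent pair signals in <= 10% of null simulations."""
        hits = 0
        n_sims = 100
        for seed in range(n_sims):
            config = GeneratorConfig(n_cases=900, seed=10_000 + seed, duplicate_rate=0.0, deletion_rate=0.0)
            tables, _, _ = simulate_quarter(config)
            data = CaseData.from_tables(tables)
            c = pair_counts(data, "SARILUMAB", "UPADACITINIB", "Pain")
            if omega_statistic(c).significant:
                hits += 1
        assert hits / n_sims <= 0.10
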