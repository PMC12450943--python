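"""Time-to-onset arithmetic, binning, Weibull fitting and hazard typing."""

from __future__ import annotations

import numpy as np
import pytest

from faersig import (
    TTORecord,
    WeibullFit,
    bin_tto,
    classify_failure,
    compute_tto,
    cumulative_incidence,
    fit_weibull,
    sample_onset_days,
)
from faersig.tto import assign_bin, tto_summary

from conftest import make_case_data


class TestComputeTto:
    def _data(self, start, event):
        return make_case_data(
            [{"caseid": "1", "drugs": [("SARILUMAB", "PS")], "events": ["Pain"],
              "start_dt": start, "event_dt": event}]
        )

    def test_whole_day_difference(self):
        records, tally = compute_tto(self._data("20240101", "20240131"), "SARILUMAB")
        assert records[0].tto_days == 30
        assert tally["missing_or_outlier"] == 0

    def test_same_day_onset_is_zero(self):
        records, _ = compute_tto(self._data("20240115", "20240115"), "SARILUMAB")
        assert records[0].tto_days == 0

    @pytest.mark.parametrize("start,event", [("20240131", "20240101"), ("202401", "20240131"), ("", "20240131")])
    def test_negative_or_partial_dates_excluded_and_tallied(self, start, event):
        records, tally = compute_tto(self._data(start, event), "SARILUMAB")
        assert records == []
        assert tally["missing_or_outlier"] == 1

    def test_earliest_target_start_date_used(self):
        data = make_case_data(
            [{"caseid": "1", "drugs": [("SARILUMAB", "PS")], "events": ["Pain"],
              "start_dt": "20240110", "event_dt": "20240120"}]
        )
        extra = data.ther.iloc[0].copy()
        extra["start_dt"] = "20240101"
        data.ther.loc[len(data.ther)] = extra
        records, _ = compute_tto(data, "SARILUMAB")
        assert records[0].tto_days == 19


class TestBinning:
    @pytest.mark.parametrize(
        "days,label",
        [(0, "0-30"), (30, "0-30"), (31, "31-60"), (360, "181-360"), (361, ">360"), (4000, ">360")],
    )
    def test_closed_bin_boundaries(self, days, label):
        assert assign_bin(days) == label

    def test_counts_sum_to_n_and_dual_denominators(self):
        records = [TTORecord(str(i), d) for i, d in enumerate([5, 10, 45, 400])]
        bins = bin_tto(records, n_all_reports=40)
        assert bins["n"].sum() == 4
        row = bins[bins["bin"] == "0-30"].iloc[0]
        assert row["pct_of_known"] == pytest.approx(50.0)
        assert row["pct_of_all"] == pytest.approx(5.0)


class TestWeibullFit:
    def test_exponential_sample_has_shape_ci_containing_one(self):
        rng = np.random.default_rng(3)
        days = np.rint(rng.exponential(100.0, size=3000))
        fit = fit_weibull(days)
        lo, hi = fit.shape_ci
        assert lo < 1.0 < hi
        assert fit.failure_type == "random"

    def test_parameter_recovery_at_study_scale(self):
        days = sample_onset_days(1951, 0.60, 161.14, rng=1)
        fit = fit_weibull(days.astype(float))
        assert 0.58 < fit.shape_beta < 0.63
        assert 147.45 < fit.scale_alpha < 176.09
        assert fit.failure_type == "early"

    def test_fitted_median_closed_form(self):
        fit = WeibullFit(0.60, 161.14, (0.58, 0.63), (147.45, 176.09), n=1951)
        assert fit.median == pytest.approx(161.14 * np.log(2) ** (1 / 0.60), rel=1e-12)
        assert fit.median == pytest.approx(87.5, abs=0.1)

    def test_scale_equivariance_shape_invariance(self):
        rng = np.random.default_rng(8)
        t = rng.weibull(0.8, 500) * 50.0 + 1.0
        f1 = fit_weibull(t)
        f7 = fit_weibull(7.0 * t)
        assert f7.shape_beta == pytest.approx(f1.shape_beta, rel=1e-9)
        assert f7.scale_alpha == pytest.approx(7.0 * f1.scale_alpha, rel=1e-9)

    def test_agreement_with_lifelines_mle(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(12)
        t = rng.weibull(0.7, 1500) * 120.0
        t = np.where(t <= 0, 0.5, t)
        ours = fit_weibull(t)
        wf = lifelines.WeibullFitter().fit(t)
        assert ours.shape_beta == pytest.approx(wf.rho_, rel=1e-4)
        assert ours.scale_alpha == pytest.approx(wf.lambda_, rel=1e-4)

    def test_degenerate_and_tiny_samples_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_weibull(np.full(50, 7.0))
        with pytest.raises(ValueError, match="at least 10"):
            fit_weibull(np.array([1.0, 2.0, 3.0]))


@pytest.mark.parametrize(
    "ci,expected",
    [((0.58, 0.63), "early"), ((0.9, 1.2), "random"), ((1.3, 1.8), "wear-out")],
)
def test_failure_classification_from_shape_ci(ci, expected):
    fit = WeibullFit(sum(ci) / 2, 100.0, ci, (90.0, 110.0), n=100)
    assert classify_failure(fit) == expected


class TestCumulativeIncidence:
    def test_step_curve_values(self):
        records = [TTORecord("1", 0), TTORecord("2", 0), TTORecord("3", 30)]
        curve = cumulative_incidence(records)
        assert curve[curve["day"] == 0]["cumulative_fraction"].iloc[0] == pytest.approx(2 / 3)
        assert curve["cumulative_fraction"].iloc[-1] == 1.0

    def test_monotone_nondecreasing(self):
        rng = np.random.default_rng(4)
        records = [TTORecord(str(i), int(d)) for i, d in enumerate(rng.integers(0, 500, 200))]
        curve = cumulative_incidence(records)
        assert (np.diff(curve["cumulative_fraction"]) >= 0).all()

    def test_curve_median_equals_sample_median(self):
        rng = np.random.default_rng(9)
        days = sample_onset_days(801, 0.60, 161.14, rng)
        records = [TTORecord(str(i), int(d)) for i, d in enumerate(days)]
        curve = cumulative_incidence(records)
        median_from_curve = curve.loc[curve["cumulative_fraction"] >= 0.5, "day"].iloc[0]
        assert median_from_curve == tto_summary(records)["median"]
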