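"""Confidence, tolerance (I-chart) and action limits."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from protonqa.spc import (
    QASeries,
    RateSummary,
    action_limits,
    confidence_limit,
    i_chart,
    limits_report,
    moving_range,
    spc_limits,
    summarize_rates,
)


class TestConfidenceLimit:
    @pytest.mark.parametrize(
        "mean, sd, expected",
        [(95.8, 2.6, 90.7), (96.9, 1.8, 93.4), (100.0, 0.0, 100.0)],
    )
    def test_closed_form(self, mean, sd, expected):
        assert round(confidence_limit(RateSummary(mean, sd, 10)), 1) == expected

    def test_exact_against_hand_formula(self, rng):
        for _ in range(50):
            m, s = rng.uniform(80, 100), rng.uniform(0, 5)
            assert confidence_limit(RateSummary(m, s, 10)) == pytest.approx(
                100.0 - (abs(100.0 - m) + 1.96 * s), abs=1e-9
            )

    @given(
        mean=st.floats(80, 100),
        sd1=st.floats(0.1, 5),
        sd2=st.floats(0.1, 5),
    )
    def test_strictly_decreasing_in_sd(self, mean, sd1, sd2):
        if sd1 == sd2:
            return
        lo, hi = sorted([sd1, sd2])
        assert confidence_limit(RateSummary(mean, hi, 10)) < confidence_limit(
            RateSummary(mean, lo, 10)
        )


class TestMovingRange:
    def test_printed_formula(self):
        assert moving_range(QASeries("s", "c", [90, 92, 91])) == pytest.approx(1.5)

    def test_constant_series(self):
        assert moving_range(QASeries("s", "c", [97, 97, 97, 97])) == 0.0

    def test_order_sensitivity(self):
        """The moving range indexes consecutive observations: a permutation
        of the same values can change it."""
        assert moving_range(QASeries("s", "c", [1, 3, 2])) != moving_range(
            QASeries("s", "c", [1, 2, 3])
        )

    def test_n_below_2_rejected(self):
        with pytest.raises(ValueError):
            moving_range(QASeries("s", "c", [95.0]))


class TestIChart:
    def test_hand_evaluation(self):
        center, ucl, lcl = i_chart(QASeries("s", "c", [1, 2, 3, 4]))
        assert center == pytest.approx(2.5)
        assert ucl == pytest.approx(5.16)
        assert lcl == pytest.approx(-0.16)

    def test_constant_series_collapses(self):
        center, ucl, lcl = i_chart(QASeries("s", "c", [97, 97, 97]))
        assert center == ucl == lcl == 97.0

    def test_lcl_below_center_below_ucl(self, rng):
        s = QASeries("s", "c", rng.uniform(90, 100, 30))
        center, ucl, lcl = i_chart(s)
        assert lcl <= center <= ucl

    def test_iid_normal_recovers_three_sigma(self):
        """E[moving range] = 1.128 sigma, so LCL ~= mean - 3 sigma for an
        in-control normal process."""
        rng = np.random.default_rng(314)
        sigma, mean = 2.0, 95.0
        x = rng.normal(mean, sigma, 10_000)
        _, _, lcl = i_chart(QASeries("s", "c", np.clip(x, 1, 100)))
        assert lcl == pytest.approx(mean - 3 * sigma, abs=0.1 * sigma)


class TestActionLimits:
    @pytest.mark.parametrize(
        "mean, sd, expected_delta, expected_lower",
        [(98.4, 1.2, 12.0, 94.0), (95.8, 1.9, None, 86.2)],
    )
    def test_published_cells(self, mean, sd, expected_delta, expected_lower):
        delta, upper, lower = action_limits(RateSummary(mean, sd, 10))
        if expected_delta is not None:
            assert round(delta, 1) == expected_delta
        assert round(lower, 1) == expected_lower
        assert upper - lower == pytest.approx(delta)

    def test_perfect_process(self):
        delta, upper, lower = action_limits(RateSummary(100.0, 0.0, 10))
        assert delta == 0.0 and upper == lower == 100.0

    @given(mean=st.floats(85, 100), sd=st.floats(0, 5))
    def test_lower_decreasing_in_deviation_and_sd(self, mean, sd):
        _, _, lower = action_limits(RateSummary(mean, sd, 10))
        _, _, lower_worse = action_limits(RateSummary(mean - 1, sd + 1, 10))
        assert lower_worse < lower

    def test_bad_beta(self):
        with pytest.raises(ValueError):
            action_limits(RateSummary(95, 1, 10), beta=0.0)


class TestLimitsReport:
    def test_pooled_row_equals_single_site(self):
        s = QASeries("Pelvis", "3%/3mm", [97.0, 98.5, 96.0, 99.0, 98.0])
        rep = limits_report([s]).set_index("site")
        assert (
            rep.loc["All regions"].drop("n").tolist()
            == rep.loc["Pelvis"].drop("n").tolist()
        )

    def test_sd_zero_cl_equals_mean(self):
        s = QASeries("A", "c", [95.5] * 6)
        rep = limits_report([s])
        assert (rep["confidence_limit"] == 95.5).all()

    def test_row_count_and_caps(self, rng):
        serieses = [
            QASeries(site, "3%/3mm", rng.uniform(94, 100, 10))
            for site in ["H&N", "Breast", "Chest"]
        ]
        rep = limits_report(serieses)
        assert len(rep) == 4  # three sites + pooled
        assert (rep[["confidence_limit", "tolerance_limit", "action_limit"]] <= 100).all().all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            limits_report([])


def test_spc_limits_internal_consistency(rng):
    s = QASeries("s", "c", rng.uniform(92, 100, 25))
    lim = spc_limits(s)
    assert lim.lcl <= lim.center_line <= lim.ucl
    assert lim.lower_action <= lim.upper_action
    assert lim.delta_a == pytest.approx(lim.upper_action - lim.lower_action)


def test_rate_validation():
    with pytest.raises(ValueError, match="outside"):
        QASeries("s", "c", [95.0, 101.0])
    with pytest.raises(ValueError, match="outside"):
        QASeries("s", "c", [0.0, 95.0])


def test_summarize_rates_uses_sample_sd():
    s = summarize_rates([1.0, 2.0, 3.0])
    assert s.mean == 2.0
    assert s.sd == pytest.approx(1.0)  # n-1 denominator
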