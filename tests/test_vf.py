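"""VF reliability, trend fits, and the four progression criteria."""

from datetime import date, timedelta

import numpy as np
import pytest
from scipy import stats

from rnflt.errors import EligibilityError, InsufficientDataError
from rnflt.vf import (
    SlopeFit,
    VFExam,
    VFSeries,
    fit_series_slope,
    is_eligible,
    is_reliable,
    label_progression,
)


def make_exam(day, md=0.0, vfi=100.0, td=None, fl=0.1, fp=0.1, fn=0.1):
    return VFExam(
        exam_date=date(2015, 1, 1) + timedelta(days=day),
        md=md,
        vfi=vfi,
        td=np.zeros(52) if td is None else td,
        fixation_loss=fl,
        false_pos=fp,
        false_neg=fn,
    )


def make_series(md_values, years, td_rows=None, vfi=None, eye="E"):
    exams = []
    for i, (md, y) in enumerate(zip(md_values, years)):
        exams.append(
            make_exam(
                round(y * 365.25),
                md=md,
                vfi=vfi[i] if vfi is not None else max(0.0, 100.0 + 3 * md),
                td=td_rows[i] if td_rows is not None else np.full(52, md),
            )
        )
    return VFSeries(eye_id=eye, exams=exams)


class TestReliability:
    @pytest.mark.parametrize(
        "fl,fp,fn,expected",
        [
            (0.33, 0.20, 0.20, True),    # printed thresholds are inclusive
            (0.34, 0.10, 0.10, False),
            (0.0, 0.0, 0.0, True),
            (0.10, 0.21, 0.10, False),
            (0.10, 0.10, 0.21, False),
        ],
    )
    def test_threshold_logic(self, fl, fp, fn, expected):
        assert is_reliable(make_exam(0, fl=fl, fp=fp, fn=fn)) is expected

    def test_missing_index_is_unreliable(self):
        e = make_exam(0)
        e.fixation_loss = float("nan")
        assert not is_reliable(e)


class TestSlopeFit:
    def test_noiseless_line(self):
        years = np.arange(5.0)
        fit = fit_series_slope(-1.0 * years, years)
        assert fit.slope == pytest.approx(-1.0)
        assert fit.p_value == 0.0

    def test_constant_series(self):
        years = np.arange(5.0)
        fit = fit_series_slope(np.full(5, -3.0), years)
        assert fit.slope == pytest.approx(0.0)

    def test_hand_ols_oracle(self):
        # closed-form OLS and slope t-test computed by hand for this series
        years = np.arange(5.0)
        vals = np.array([0.1, -0.8, -2.1, -2.9, -4.1])
        sxx = ((years - years.mean()) ** 2).sum()
        sxy = ((years - years.mean()) * (vals - vals.mean())).sum()
        slope = sxy / sxx
        intercept = vals.mean() - slope * years.mean()
        resid = vals - (intercept + slope * years)
        se = np.sqrt((resid**2).sum() / 3.0 / sxx)
        t = slope / se
        p = 2 * stats.t.sf(abs(t), 3)
        fit = fit_series_slope(vals, years)
        assert np.isclose(fit.slope, slope, atol=1e-10)
        assert np.isclose(fit.intercept, intercept, atol=1e-10)
        assert np.isclose(fit.p_value, p, atol=1e-10)

    def test_matches_closed_form_on_random_series(self, rng):
        for _ in range(25):
            n = int(rng.integers(3, 12))
            years = np.sort(rng.uniform(0, 8, size=n))
            while np.any(np.diff(years) <= 0):
                years = np.sort(rng.uniform(0, 8, size=n))
            vals = rng.normal(-2, 3, size=n)
            fit = fit_series_slope(vals, years)
            sxx = ((years - years.mean()) ** 2).sum()
            sxy = ((years - years.mean()) * (vals - vals.mean())).sum()
            slope = sxy / sxx
            resid = vals - (vals.mean() + slope * (years - years.mean()))
            se = np.sqrt((resid**2).sum() / (n - 2) / sxx)
            p = 2 * stats.t.sf(abs(slope / se), n - 2)
            assert np.isclose(fit.slope, slope, atol=1e-10)
            assert np.isclose(fit.p_value, p, atol=1e-10)

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            fit_series_slope(np.array([1.0, 2.0]), np.array([0.0, 1.0]))


class TestProgressionLabels:
    def test_fast_decline_sets_md_and_fast(self):
        years = np.arange(5.0)
        s = make_series(-1.2 * years, years)
        lab = label_progression(s)
        assert lab.md_prog and lab.md_fast

    def test_slow_decline_progresses_but_not_fast(self):
        years = np.arange(5.0)
        s = make_series(-0.5 * years, years)
        lab = label_progression(s)
        assert lab.md_prog and not lab.md_fast

    def test_slope_minus_one_exactly_counts_as_fast(self):
        # 4-year exam spacing: 1461 days is exactly 4.0 years in floating
        # point, so the fitted slope is exactly -1.0 at the boundary
        years = np.array([0.0, 4.0, 8.0, 12.0, 16.0])
        s = make_series(-1.0 * years, years)
        lab = label_progression(s)
        assert lab.md_fit.slope == -1.0
        assert lab.md_fast          # criterion is <= -1 dB/year

    def test_stable_series_has_no_progression(self):
        years = np.arange(5.0)
        s = make_series(np.zeros(5), years, vfi=[100.0] * 5)
        lab = label_progression(s)
        assert not (lab.md_prog or lab.vfi_prog or lab.td_pointwise_prog
                    or lab.md_fast)

    @pytest.mark.parametrize("n_locations,expected", [(2, False), (3, True)])
    def test_td_pointwise_needs_three_locations(self, n_locations, expected):
        years = np.arange(5.0)
        td_rows = []
        for y in years:
            td = np.zeros(52)
            td[:n_locations] = -1.5 * y      # declining at 1.5 dB/year
            td_rows.append(td)
        s = make_series(np.zeros(5), years, td_rows=td_rows, vfi=[100.0] * 5)
        lab = label_progression(s)
        assert lab.td_pointwise_prog is expected
        assert lab.n_td_progressing == n_locations

    def test_vfi_criterion(self):
        years = np.arange(5.0)
        s = make_series(np.zeros(5), years, vfi=list(100.0 - 2.0 * years))
        assert label_progression(s).vfi_prog

    def test_short_span_is_ineligible(self):
        years = np.linspace(0, 3.0, 5)      # only 3 years
        s = make_series(-1.0 * years, years)
        assert not is_eligible(s)
        with pytest.raises(EligibilityError):
            label_progression(s)

    def test_unreliable_exams_do_not_count_for_eligibility(self):
        years = np.arange(5.0)
        exams = [
            make_exam(round(y * 365.25), md=-y, fl=0.9 if i == 4 else 0.1)
            for i, y in enumerate(years)
        ]
        s = VFSeries(eye_id="E", exams=exams)
        assert not is_eligible(s)       # only 4 reliable exams remain

    def test_md_fast_implies_md_prog_invariant(self):
        with pytest.raises(ValueError):
            from rnflt.vf import ProgressionLabels

            ProgressionLabels(
                md_prog=False, vfi_prog=False, td_pointwise_prog=False,
                md_fast=True,
                md_fit=SlopeFit(-1.5, 0.0, 0.5, 5),
                vfi_fit=SlopeFit(0.0, 0.0, 1.0, 5),
            )
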