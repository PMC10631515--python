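"""Visual-field (VF) exam containers, reliability filtering, trend fits,
and glaucoma progression criteria.

Works with 24-2 Humphrey-style exams: a global mean deviation (MD, dB),
a visual field index (VFI, %), 52 pointwise total deviations (TDs, dB),
and the three standard reliability indices. Progression is trend-based:
ordinary least squares of an index on time in years, with a two-sided
t-test on the slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np
from scipy import stats

from .errors import EligibilityError, InsufficientDataError

#: Reliability cutoffs: fixation loss <= 33%, false positives <= 20%,
#: false negatives <= 20% (inclusive, as printed on clinical reports).
MAX_FIXATION_LOSS = 0.33
MAX_FALSE_POS = 0.20
MAX_FALSE_NEG = 0.20

#: Eligibility for progression labelling: at least 5 reliable exams
#: spanning at least 4 years.
MIN_EXAMS = 5
MIN_SPAN_YEARS = 4.0

#: Trend-criterion thresholds.
P_CUTOFF = 0.05
FAST_SLOPE_DB_PER_YEAR = -1.0
MIN_TD_LOCATIONS = 3

DAYS_PER_YEAR = 365.25


@dataclass
class VFExam:
    """One 24-2 visual field exam."""

    exam_date: date
    md: float                 # mean deviation, dB
    vfi: float                # visual field index, percent in [0, 100]
    td: np.ndarray            # 52 total deviations, dB
    fixation_loss: float      # fraction in [0, 1]
    false_pos: float
    false_neg: float

    def __post_init__(self) -> None:
        self.td = np.asarray(self.td, dtype=float)
        if self.td.shape != (52,):
            raise ValueError(f"td must have 52 entries, got {self.td.shape}")
        for name in ("fixation_loss", "false_pos", "false_neg"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.vfi <= 100.0:
            raise ValueError(f"vfi must be in [0, 100], got {self.vfi}")


@dataclass
class VFSeries:
    """Time-ordered VF exams for one eye (dates strictly increasing)."""

    eye_id: str
    exams: list[VFExam]

    def __post_init__(self) -> None:
        dates = [e.exam_date for e in self.exams]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("exam dates must be strictly increasing")

    def reliable_exams(self) -> list[VFExam]:
        return [e for e in self.exams if is_reliable(e)]

    def years_from_first(self, exams: list[VFExam] | None = None) -> np.ndarray:
        exams = self.exams if exams is None else exams
        t0 = exams[0].exam_date
        return np.array(
            [(e.exam_date - t0).days / DAYS_PER_YEAR for e in exams], dtype=float
        )


def is_reliable(exam: VFExam) -> bool:
    """Reliability filter: FL <= 33%, FP <= 20%, FN <= 20%.

    A missing index makes the exam unreliable by policy.
    """
    for v, cutoff in (
        (exam.fixation_loss, MAX_FIXATION_LOSS),
        (exam.false_pos, MAX_FALSE_POS),
        (exam.false_neg, MAX_FALSE_NEG),
    ):
        if v is None or not np.isfinite(v) or v > cutoff:
            return False
    return True


def is_eligible(series: VFSeries) -> bool:
    """Progression-labelling eligibility: >= 5 reliable exams over >= 4 years."""
    rel = series.reliable_exams()
    if len(rel) < MIN_EXAMS:
        return False
    span = (rel[-1].exam_date - rel[0].exam_date).days / DAYS_PER_YEAR
    return span >= MIN_SPAN_YEARS


@dataclass
class SlopeFit:
    """OLS trend fit of an index on time (years)."""

    slope: float       # units/year
    intercept: float
    p_value: float     # two-sided t-test on the slope
    n: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must be in [0, 1]")


def fit_series_slope(values: np.ndarray, years: np.ndarray) -> SlopeFit:
    """OLS of ``values`` on ``years`` with a two-sided slope t-test.

    A numerically perfect fit (zero residual) gets p = 0. Requires at
    least 3 points so the t-test has positive degrees of freedom.
    """
    values = np.asarray(values, dtype=float)
    years = np.asarray(years, dtype=float)
    if values.shape != years.shape or values.ndim != 1:
        raise ValueError("values and years must be equal-length 1-D arrays")
    if len(values) < 3:
        raise InsufficientDataError(f"need >= 3 exams for a trend, got {len(values)}")
    if np.any(np.diff(years) <= 0):
        raise ValueError("years must be strictly increasing")

    res = stats.linregress(years, values)
    slope, intercept = float(res.slope), float(res.intercept)
    resid = values - (intercept + slope * years)
    # rss on the scale of the data: treat as an exact fit -> p = 0
    if np.sum(resid**2) <= 1e-24 * max(1.0, float(np.sum(values**2))):
        p = 0.0
    else:
        p = float(res.pvalue)
    return SlopeFit(slope=slope, intercept=intercept, p_value=p, n=len(values))


@dataclass
class ProgressionLabels:
    """The four trend-based progression labels for one eye.

    * ``md_prog``: MD slope < 0 with p < 0.05
    * ``td_pointwise_prog``: >= 3 TD locations with slope <= -1 dB/year
      and p < 0.05
    * ``vfi_prog``: VFI slope < 0 with p < 0.05
    * ``md_fast``: MD slope <= -1 dB/year with p < 0.05
    """

    md_prog: bool
    vfi_prog: bool
    td_pointwise_prog: bool
    md_fast: bool
    md_fit: SlopeFit
    vfi_fit: SlopeFit
    td_fits: list[SlopeFit] = field(default_factory=list)
    n_td_progressing: int = 0

    def __post_init__(self) -> None:
        if self.md_fast and not self.md_prog:
            raise ValueError("md_fast implies md_prog")


def label_progression(series: VFSeries) -> ProgressionLabels:
    """Compute all four progression labels from the reliable exams.

    Raises :class:`EligibilityError` if the series has fewer than 5
    reliable exams or they span less than 4 years.
    """
    rel = series.reliable_exams()
    if not is_eligible(series):
        raise EligibilityError(
            f"series {series.eye_id!r}: needs >= {MIN_EXAMS} reliable exams "
            f"over >= {MIN_SPAN_YEARS} years ({len(rel)} reliable exams found)"
        )
    years = series.years_from_first(rel)
    md_fit = fit_series_slope(np.array([e.md for e in rel]), years)
    vfi_fit = fit_series_slope(np.array([e.vfi for e in rel]), years)
    td_matrix = np.stack([e.td for e in rel])            # (n_exams, 52)
    td_fits = [fit_series_slope(td_matrix[:, j], years) for j in range(52)]

    md_prog = md_fit.slope < 0 and md_fit.p_value < P_CUTOFF
    vfi_prog = vfi_fit.slope < 0 and vfi_fit.p_value < P_CUTOFF
    n_td = sum(
        1
        for f in td_fits
        if f.slope <= FAST_SLOPE_DB_PER_YEAR and f.p_value < P_CUTOFF
    )
    td_prog = n_td >= MIN_TD_LOCATIONS
    md_fast = md_fit.slope <= FAST_SLOPE_DB_PER_YEAR and md_fit.p_value < P_CUTOFF

    return ProgressionLabels(
        md_prog=md_prog,
        vfi_prog=vfi_prog,
        td_pointwise_prog=td_prog,
        md_fast=md_fast,
        md_fit=md_fit,
        vfi_fit=vfi_fit,
        td_fits=td_fits,
        n_td_progressing=n_td,
    )
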