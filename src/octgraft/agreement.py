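"""Observer-agreement statistics for paired measurement series.

The reproducibility toolkit used to validate the measurement pipeline:
Bland-Altman limits of agreement (bias ± 1.96 x SD of the paired
differences, with t-based confidence intervals), the two-way
absolute-agreement single-measures intraclass correlation coefficient
ICC(A,1) with its F-distribution confidence interval, the Pearson
correlation, and the paired t-test.  Difference direction is always the
first-listed arm minus the second.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, ParameterError

__all__ = ["MeasurementSeries", "AgreementReport", "bland_altman",
           "icc_two_way", "pearson_r", "paired_t", "agreement_table",
           "series_from_frame"]

#: limits-of-agreement multiplier, fixed by the Bland-Altman convention
LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class MeasurementSeries:
    """Paired measurements (a_i, b_i) of the same subjects by two arms
    (observers, sessions, or analysis modes)."""

    a: np.ndarray
    b: np.ndarray
    label_a: str = "A"
    label_b: str = "B"

    def __post_init__(self):
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        if a.ndim != 1 or a.shape != b.shape:
            raise ParameterError("arms must be equal-length 1-D arrays")
        if a.size < 3:
            raise ParameterError(f"need n >= 3 pairs, got {a.size}")
        if not (np.isfinite(a).all() and np.isfinite(b).all()):
            raise ParameterError("missing or non-finite pairs are not allowed")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    @property
    def n(self) -> int:
        return int(self.a.size)

    def swapped(self) -> "MeasurementSeries":
        return MeasurementSeries(self.b, self.a, self.label_b, self.label_a)


@dataclass(frozen=True)
class AgreementReport:
    """Bland-Altman quantities, optionally extended with ICC / r / t."""

    n: int
    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    bias_ci: tuple[float, float]
    loa_lower_ci: tuple[float, float]
    loa_upper_ci: tuple[float, float]
    icc: float | None = None
    icc_ci: tuple[float, float] | None = None
    r: float | None = None
    t_stat: float | None = None
    p_value: float | None = None
    labels: tuple[str, str] = ("A", "B")


def bland_altman(series: MeasurementSeries) -> AgreementReport:
    """Limits of agreement for the paired differences a - b.

    bias = mean difference, sd_diff = sample SD (n-1 denominator),
    LoA = bias ± 1.96 sd.  95% CIs: bias ± t(n-1) sd/sqrt(n) for the bias
    and limit ± t(n-1) sd sqrt(3/n) for each limit.
    """
    d = series.a - series.b
    n = series.n
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_lo = bias - LOA_MULTIPLIER * sd
    loa_hi = bias + LOA_MULTIPLIER * sd
    tq = float(stats.t.ppf(0.975, n - 1))
    half_bias = tq * sd / np.sqrt(n)
    half_loa = tq * sd * np.sqrt(3.0 / n)
    return AgreementReport(
        n=n, bias=bias, sd_diff=sd, loa_lower=loa_lo, loa_upper=loa_hi,
        bias_ci=(bias - half_bias, bias + half_bias),
        loa_lower_ci=(loa_lo - half_loa, loa_lo + half_loa),
        loa_upper_ci=(loa_hi - half_loa, loa_hi + half_loa),
        labels=(series.label_a, series.label_b),
    )


def _anova_mean_squares(series: MeasurementSeries) -> tuple[float, float, float]:
    """Two-way (subjects x raters) ANOVA mean squares: MSR, MSC, MSE."""
    x = np.column_stack([series.a, series.b])  # n subjects x k raters
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)
    return float(msr), float(msc), float(mse)


def icc_two_way(series: MeasurementSeries, kind: str = "absolute",
                alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Two-way mixed-effects single-measures ICC with its 95% CI.

    ``kind="absolute"`` (default) is ICC(A,1): absolute agreement —
    sensitive to systematic offsets between arms.  ``kind="consistency"``
    is ICC(C,1).  Confidence bounds follow the F-distribution formulas of
    the two-way ANOVA decomposition (McGraw & Wong).
    """
    if kind not in ("absolute", "consistency"):
        raise ParameterError(f"kind must be absolute|consistency, got {kind!r}")
    x = np.column_stack([series.a, series.b])
    if np.allclose(x, x.mean()):
        raise DegenerateDataError("zero total variance: ICC undefined")
    n, k = x.shape
    msr, msc, mse = _anova_mean_squares(series)

    if kind == "consistency":
        icc = (msr - mse) / (msr + (k - 1) * mse)
        if mse == 0.0:
            return 1.0, (1.0, 1.0)
        f_obs = msr / mse
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
        fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
        return float(icc), (float(lo), float(hi))

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0:
        raise DegenerateDataError("degenerate variance decomposition: ICC undefined")
    icc = (msr - mse) / denom
    if mse == 0.0 and msc == mse:
        return 1.0, (1.0, 1.0)
    # Satterthwaite df for the absolute-agreement CI
    a = (k * icc) / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + (k * icc * (n - 1)) / (n * (1 - icc)) if icc < 1 else np.inf
    if not np.isfinite(a):
        return float(icc), (1.0, 1.0)
    num = (a * msc + b * mse) ** 2
    den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = num / den if den > 0 else 1.0
    f2u = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f2l = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lo = n * (msr - f2u * mse) / (f2u * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi = n * (f2l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2l * msr)
    return float(icc), (float(lo), float(hi))


def pearson_r(series: MeasurementSeries) -> float:
    """Pearson linear correlation between the two arms."""
    if series.a.std() == 0 or series.b.std() == 0:
        raise DegenerateDataError("zero variance in an arm: correlation undefined")
    r, _ = stats.pearsonr(series.a, series.b)
    return float(r)


def paired_t(series: MeasurementSeries) -> tuple[float, float]:
    """Paired t-test on the differences a - b; two-sided p from t(n-1).

    With identically zero differences the statistic is defined as 0 (p=1);
    zero spread around a non-zero bias gives an infinite statistic (p=0).
    """
    d = series.a - series.b
    n = series.n
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() == 0.0:
            return 0.0, 1.0
        return float(np.sign(d.mean()) * np.inf), 0.0
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * stats.t.sf(abs(t), n - 1))
    return t, p


def analyze(series: MeasurementSeries, icc_kind: str = "absolute") -> AgreementReport:
    """Full agreement report: Bland-Altman + ICC + Pearson r + paired t."""
    ba = bland_altman(series)
    try:
        icc, icc_ci = icc_two_way(series, kind=icc_kind)
    except DegenerateDataError:
        icc, icc_ci = None, None
    try:
        r = pearson_r(series)
    except DegenerateDataError:
        r = None
    t, p = paired_t(series)
    return AgreementReport(
        n=ba.n, bias=ba.bias, sd_diff=ba.sd_diff,
        loa_lower=ba.loa_lower, loa_upper=ba.loa_upper,
        bias_ci=ba.bias_ci, loa_lower_ci=ba.loa_lower_ci,
        loa_upper_ci=ba.loa_upper_ci,
        icc=icc, icc_ci=icc_ci, r=r, t_stat=t, p_value=p,
        labels=ba.labels,
    )


def agreement_table(series_list: Sequence[MeasurementSeries],
                    icc_kind: str = "absolute") -> pd.DataFrame:
    """One row per comparison, mirroring the standard reporting layout:
    mean ± SD per arm, p, r, ICC (95% CI), bias (95% CI) and the upper and
    lower limits of agreement (95% CIs).

    A comparison whose differences have zero spread is flagged in the
    ``degenerate`` column and its p-value reported as NaN (undefined).
    """
    rows = []
    for s in series_list:
        rep = analyze(s, icc_kind=icc_kind)
        degenerate = rep.sd_diff == 0.0
        rows.append({
            "arm_a": s.label_a, "arm_b": s.label_b, "n": rep.n,
            "mean_a": float(s.a.mean()), "sd_a": float(s.a.std(ddof=1)),
            "mean_b": float(s.b.mean()), "sd_b": float(s.b.std(ddof=1)),
            "p_value": np.nan if degenerate else rep.p_value,
            "r": rep.r if rep.r is not None else np.nan,
            "icc": rep.icc if rep.icc is not None else np.nan,
            "icc_ci_low": rep.icc_ci[0] if rep.icc_ci else np.nan,
            "icc_ci_high": rep.icc_ci[1] if rep.icc_ci else np.nan,
            "bias": rep.bias,
            "bias_ci_low": rep.bias_ci[0], "bias_ci_high": rep.bias_ci[1],
            "loa_upper": rep.loa_upper,
            "loa_upper_ci_low": rep.loa_upper_ci[0],
            "loa_upper_ci_high": rep.loa_upper_ci[1],
            "loa_lower": rep.loa_lower,
            "loa_lower_ci_low": rep.loa_lower_ci[0],
            "loa_lower_ci_high": rep.loa_lower_ci[1],
            "degenerate": degenerate,
        })
    return pd.DataFrame(rows)


def series_from_frame(df: pd.DataFrame, col_a: str = "arm_a",
                      col_b: str = "arm_b") -> MeasurementSeries:
    """Build a series from a data frame with one row per subject."""
    return MeasurementSeries(df[col_a].to_numpy(float), df[col_b].to_numpy(float),
                             label_a=col_a, label_b=col_b)
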