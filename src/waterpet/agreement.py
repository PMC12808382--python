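"""Rater-agreement statistics for repeated perfusion measurements.

Reliability of repeated K1 measurements is summarized by the intraclass
correlation coefficient ICC(2,1): two-way random effects, absolute
agreement, single measures — both raters and subjects (legs) are treated
as random samples, and systematic between-rater offsets count against
agreement. The 95% CI follows the F-distribution construction of McGraw &
Wong for this form.

Measurement error is summarized by Bland-Altman limits of agreement,
mean difference +/- 1.96 * SD of the differences (1.96 used literally,
not a t quantile).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "RatingsMatrix",
    "AgreementResult",
    "icc_2_1",
    "icc_3_1",
    "interpret_icc",
    "bland_altman",
    "mean_with_ci",
]


@dataclass(frozen=True)
class RatingsMatrix:
    """n subjects x k measurements, complete (no missing cells)."""

    values: np.ndarray
    subjects: tuple = ()
    raters: tuple = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("ratings must be a 2D matrix (subjects x measurements)")
        n, k = v.shape
        if n < 2 or k < 2:
            raise ValueError("need at least 2 subjects and 2 measurements")
        if not np.all(np.isfinite(v)):
            raise ValueError("ratings matrix has missing or non-finite cells")
        object.__setattr__(self, "values", v)
        if not self.subjects:
            object.__setattr__(self, "subjects", tuple(f"subject{i}" for i in range(n)))
        if not self.raters:
            object.__setattr__(self, "raters", tuple(f"rater{j}" for j in range(k)))


@dataclass(frozen=True)
class AgreementResult:
    """ICC with CI and mean squares, plus Bland-Altman summaries."""

    icc: float
    ci_lower: float
    ci_upper: float
    ms_rows: float
    ms_cols: float
    ms_error: float
    interpretation: str
    status: str = "ok"
    bland_altman: dict | None = field(default=None)


def _anova_mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    """Two-way (subjects x raters, one observation per cell) mean squares."""
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
    mse = max(ss_err, 0.0) / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def interpret_icc(icc_value: float) -> str:
    """Qualitative reliability band of an ICC.

    poor < 0.5 <= moderate < 0.75 <= good <= 0.9 < excellent. The 0.75 and
    0.9 boundaries follow the half-open/closed convention stated here;
    published band descriptions overlap at the endpoints.
    """
    if not (-1.0 < icc_value <= 1.0):
        raise ValueError(f"ICC must lie in (-1, 1], got {icc_value}")
    if icc_value < 0.5:
        return "poor"
    if icc_value < 0.75:
        return "moderate"
    if icc_value <= 0.9:
        return "good"
    return "excellent"


def icc_2_1(m: RatingsMatrix, confidence: float = 0.95) -> AgreementResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)), with the
    McGraw-Wong F-based confidence interval. A constant matrix has no
    subject variance to agree on; the result is then flagged
    ``degenerate`` with an NaN estimate rather than raising.
    """
    x = m.values
    n, k = x.shape
    msr, msc, mse = _anova_mean_squares(x)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0 or not np.isfinite(denom) or np.allclose(x, x.flat[0]):
        return AgreementResult(
            icc=float("nan"),
            ci_lower=float("nan"),
            ci_upper=float("nan"),
            ms_rows=msr,
            ms_cols=msc,
            ms_error=mse,
            interpretation="undefined",
            status="degenerate: no between-subject variance",
        )
    icc = (msr - mse) / denom

    alpha = 1.0 - confidence
    if mse == 0.0:
        # perfect agreement: zero residual variance
        lo, hi = icc, 1.0
    else:
        a = (k * icc) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
        b = 1.0 + (k * icc * (n - 1.0)) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1.0) + (b * mse) ** 2 / ((n - 1.0) * (k - 1.0))
        )
        f_l = stats.f.ppf(1.0 - alpha / 2.0, n - 1.0, v)
        f_u = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1.0)
        lo = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
        lo, hi = min(lo, icc), max(hi, icc)
    return AgreementResult(
        icc=float(icc),
        ci_lower=float(lo),
        ci_upper=float(hi),
        ms_rows=msr,
        ms_cols=msc,
        ms_error=mse,
        interpretation=interpret_icc(float(np.clip(icc, -0.999999, 1.0))),
    )


def icc_3_1(m: RatingsMatrix) -> float:
    """ICC(3,1), two-way mixed, consistency — a labelled extra, never the
    default agreement measure here."""
    x = m.values
    _, k = x.shape
    msr, _, mse = _anova_mean_squares(x)
    denom = msr + (k - 1) * mse
    if denom <= 0:
        return float("nan")
    return float((msr - mse) / denom)


def bland_altman(x, y) -> tuple[float, float, float, float]:
    """Bland-Altman summary of paired measurements.

    Returns ``(bias, sd_diff, loa_lower, loa_upper)`` where d = x - y,
    bias = mean(d), sd_diff = sample SD(d) and the limits of agreement are
    bias -/+ 1.96 * sd_diff.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D vectors of equal length")
    if len(x) < 2:
        raise ValueError("need at least two pairs")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, sd, bias - 1.96 * sd, bias + 1.96 * sd


def mean_with_ci(values, level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Mean with a t-distribution confidence interval."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise ValueError("need at least two values")
    n = len(v)
    mean = float(v.mean())
    sem = float(v.std(ddof=1) / np.sqrt(n))
    t = stats.t.ppf(0.5 + level / 2.0, n - 1)
    return mean, (mean - t * sem, mean + t * sem)


def plot_bland_altman(x, y, ax=None, label: str = ""):
    """Bland-Altman plot: mean vs difference with bias and limits of agreement."""
    import matplotlib.pyplot as plt

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    bias, sd, lo, hi = bland_altman(x, y)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter((x + y) / 2.0, x - y, s=20)
    for val, style in ((bias, "-"), (lo, "--"), (hi, "--")):
        ax.axhline(val, linestyle=style, color="gray")
    ax.set_xlabel("mean of measurements")
    ax.set_ylabel("difference")
    if label:
        ax.set_title(label)
    return ax
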