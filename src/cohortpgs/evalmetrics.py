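"""Evaluation statistics for predicted versus actual height.

Includes the Pearson correlation with its tabulated spread formula
``pcc_sd = sqrt((1 - r^2) / (n - 2))`` (the large-sample standard error
of r, labelled "SD" in cohort report tables and kept under that name
here), the fraction of samples whose relative prediction error exceeds a
threshold (default 5%), descriptive height summaries, and the fitted
secular trendline of mean height on birth year.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class HeightSummary:
    n: int
    mean: float
    sd: float
    median: float
    min: float
    max: float


@dataclass
class MetricReport:
    """Cohort-level agreement between actual and predicted heights."""

    n: int
    actual: HeightSummary
    predicted: HeightSummary
    discrepancy_count: int
    discrepancy_percent: float
    pcc: float
    pcc_sd: float

    def to_dict(self) -> dict:
        d = asdict(self)
        d["actual"] = asdict(self.actual)
        d["predicted"] = asdict(self.predicted)
        return d

    def rounded(self) -> dict:
        """Values at report precision: r and its SD to 4 decimals, percent
        and heights to 2 (round-half-to-even)."""
        return {
            "n": self.n,
            "pcc": round(self.pcc, 4),
            "pcc_sd": round(self.pcc_sd, 4),
            "discrepancy_count": self.discrepancy_count,
            "discrepancy_percent": round(self.discrepancy_percent, 2),
            "actual_mean": round(self.actual.mean, 2),
            "actual_sd": round(self.actual.sd, 2),
            "predicted_mean": round(self.predicted.mean, 2),
            "predicted_sd": round(self.predicted.sd, 2),
        }


@dataclass
class TrendlineFit:
    """OLS of per-birth-year mean height on birth year."""

    slope: float  # cm per birth year
    intercept: float  # cm at year 0
    slope_se: float
    n_years: int

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        tcrit = stats.t.ppf(0.5 + level / 2, self.n_years - 2)
        return (self.slope - tcrit * self.slope_se,
                self.slope + tcrit * self.slope_se)


def pearson_with_sd(actual, predicted) -> tuple[float, float]:
    """Sample Pearson correlation and sqrt((1 - r^2) / (n - 2))."""
    a = np.asarray(actual, dtype=float)
    b = np.asarray(predicted, dtype=float)
    if a.size != b.size:
        raise ValueError("vectors differ in length")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(stats.pearsonr(a, b).statistic)
    return r, pcc_sd(r, a.size)


def pcc_sd(r: float, n: int) -> float:
    """Tabulated spread of a Pearson correlation: sqrt((1-r^2)/(n-2))."""
    if n < 3:
        raise ValueError("need n >= 3")
    return float(np.sqrt(max(1.0 - r * r, 0.0) / (n - 2)))


def discrepancy_fraction(
    actual, predicted, threshold: float = 0.05
) -> tuple[int, float]:
    """Count and percent of samples with |predicted - actual| / actual
    strictly greater than ``threshold``."""
    a = np.asarray(actual, dtype=float)
    b = np.asarray(predicted, dtype=float)
    if np.any(a <= 0):
        bad = np.flatnonzero(a <= 0)[:5]
        raise ValueError(f"non-positive actual heights at indices {bad.tolist()}")
    rel = np.abs(b - a) / a
    count = int((rel > threshold).sum())
    return count, round(100.0 * count / a.size, 2)


def summarize(heights) -> HeightSummary:
    """n, mean, SD (n-1 denominator; 0 for a singleton), median, min, max."""
    h = np.asarray(heights, dtype=float)
    if h.size == 0:
        raise ValueError("empty height vector")
    sd = float(h.std(ddof=1)) if h.size > 1 else 0.0
    return HeightSummary(
        n=int(h.size),
        mean=float(h.mean()),
        sd=sd,
        median=float(np.median(h)),
        min=float(h.min()),
        max=float(h.max()),
    )


def evaluate(actual, predicted, threshold: float = 0.05) -> MetricReport:
    """Full metric report for one cohort and one covariate combination."""
    a = np.asarray(actual, dtype=float)
    b = np.asarray(predicted, dtype=float)
    count, percent = discrepancy_fraction(a, b, threshold)
    r, r_sd = pearson_with_sd(a, b)
    return MetricReport(
        n=int(a.size),
        actual=summarize(a),
        predicted=summarize(b),
        discrepancy_count=count,
        discrepancy_percent=percent,
        pcc=r,
        pcc_sd=r_sd,
    )


def trendline(pheno: pd.DataFrame, per_individual: bool = False) -> TrendlineFit:
    """Secular trend: OLS slope of height on birth year.

    By default each birth year contributes one point (its mean height),
    matching how cohort trendlines over birth year are usually drawn;
    ``per_individual=True`` regresses raw individual heights instead.
    """
    if pheno["birth_year"].nunique() < 2:
        raise ValueError("need at least two distinct birth years")
    if per_individual:
        x = pheno["birth_year"].to_numpy(dtype=float)
        y = pheno["height_cm"].to_numpy(dtype=float)
    else:
        by_year = pheno.groupby("birth_year")["height_cm"].mean()
        x = by_year.index.to_numpy(dtype=float)
        y = by_year.to_numpy(dtype=float)
    fit = stats.linregress(x, y)
    return TrendlineFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        slope_se=float(fit.stderr),
        n_years=int(x.size),
    )
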