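"""Obesity prevalence series and variance-trend association.

Prevalence is computed per birth year over all individuals (not only paired
ones) with the WHO cut-point BMI ≥ 30 by default, with a Wilson score
interval. The association between a variance-component trend and the
prevalence series is the plain Pearson correlation over year points (Fisher
z interval, n = number of years) plus an OLS slope with its t-test; no
autocorrelation correction is applied, and reports note as much.

Also here: the single-locus contribution p(1−p)a² to additive genetic
variance, useful for reasoning about which changes (allele frequency p or
allelic effect a) could move V_A between strata with a constant gene pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import ConfigError, DataError
from .sibling import correlation_ci


@dataclass
class TrendAssociation:
    pearson_r: float
    pearson_ci: tuple[float, float]
    n_points: int
    ols_slope: float | None = None
    ols_p: float | None = None

    def as_dict(self) -> dict:
        return {
            "pearson_r": self.pearson_r, "pearson_ci": self.pearson_ci,
            "n_points": self.n_points, "ols_slope": self.ols_slope,
            "ols_p": self.ols_p,
            "note": "plain Pearson over year points; no autocorrelation correction",
        }


def prevalence_by_year(
    individuals: pd.DataFrame,
    cutoff: float = 30.0,
    level: float = 0.95,
    method: str = "wilson",
) -> pd.DataFrame:
    """Per-birth-year obesity prevalence with a binomial interval.

    Obese iff ``bmi >= cutoff`` (cut-point inclusive). ``method`` is
    ``"wilson"`` (score, default) or ``"beta"`` (Clopper–Pearson exact).
    Returns columns ``year, n, n_obese, prevalence, lo, hi``.
    """
    if cutoff <= 0:
        raise ConfigError("cutoff must be positive")
    if method not in ("wilson", "beta"):
        raise ConfigError(f"unknown interval method {method!r}")
    grouped = individuals.groupby("birth_year")["bmi"]
    n = grouped.size()
    n_obese = grouped.apply(lambda s: int((s >= cutoff).sum()))
    lo, hi = proportion_confint(n_obese.to_numpy(), n.to_numpy(),
                                alpha=1 - level, method=method)
    return pd.DataFrame({
        "year": n.index.to_numpy(dtype=np.int64),
        "n": n.to_numpy(dtype=np.int64),
        "n_obese": n_obese.to_numpy(dtype=np.int64),
        "prevalence": (n_obese / n).to_numpy(dtype=float),
        "lo": np.asarray(lo, dtype=float),
        "hi": np.asarray(hi, dtype=float),
    }).reset_index(drop=True)


def pearson_with_ci(x, y, level: float = 0.95) -> TrendAssociation:
    """Pearson correlation of two year-indexed series with a Fisher z CI.

    The effective sample size is the number of year points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise DataError("need two equal-length 1-d series with >= 3 points")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DataError("series contain non-finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DataError("correlation undefined: a series has zero variance")
    r = float(stats.pearsonr(x, y).statistic)
    ci = correlation_ci(r, len(x), level) if len(x) >= 4 else (np.nan, np.nan)
    return TrendAssociation(pearson_r=r, pearson_ci=ci, n_points=len(x))


def ols_slope_test(x, y) -> tuple[float, float]:
    """OLS slope of y on x with its two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise DataError("need two equal-length series with >= 3 points")
    if np.std(x) == 0:
        raise DataError("slope undefined: x is constant")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.pvalue)


def trend_association(x, y, level: float = 0.95) -> TrendAssociation:
    """Pearson correlation and OLS slope of a joined pair of year series."""
    assoc = pearson_with_ci(x, y, level)
    assoc.ols_slope, assoc.ols_p = ols_slope_test(x, y)
    return assoc


def join_on_year(prevalence: pd.DataFrame, trend: pd.DataFrame) -> pd.DataFrame:
    """Inner-join a prevalence series and a variance trend on year."""
    return prevalence.merge(trend, on="year", how="inner", suffixes=("_prev", "_trend"))


def locus_variance_contribution(p: float, a: float) -> float:
    """Additive-variance contribution of one biallelic locus: p(1−p)a²."""
    p = float(p)
    if not 0.0 <= p <= 1.0:
        raise ConfigError(f"allele frequency {p} outside [0, 1]")
    return p * (1.0 - p) * float(a) ** 2
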