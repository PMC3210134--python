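"""Cohort-stratified sibling-pair variance decomposition.

With common-environment and dominance influences assumed negligible (an
assumption the twin analysis of :mod:`twinvar.ace` is there to check), full
siblings share half the additive genetic variance, so twice the within-pair
covariance estimates V_A, the remainder of the phenotypic variance is the
unique-environment variance V_E, and heritability is twice the sibling
correlation. Applied per birth cohort, this turns a large sibling register
into a secular-trend estimator for the genetic variance of BMI.

All pair statistics use the double-entry (ML intraclass) form: each pair
enters in both orderings, with a common mean and divisor n, which makes
every statistic invariant to within-pair ordering and makes the correlation
identically covariance/variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

logger = logging.getLogger(__name__)


@dataclass
class PairSummary:
    """Double-entry summary of one stratum of pairs (a Table-1-style row)."""

    stratum: str
    n_pairs: int
    mean: float
    variance: float
    covariance: float
    correlation: float
    covariance_ci: tuple[float, float] | None = None
    correlation_ci: tuple[float, float] | None = None
    boot_cov: np.ndarray | None = None  # joint bootstrap draws, for propagation
    boot_var: np.ndarray | None = None

    def as_dict(self) -> dict:
        return {
            "stratum": self.stratum, "n_pairs": self.n_pairs,
            "mean": self.mean, "variance": self.variance,
            "covariance": self.covariance, "correlation": self.correlation,
            "covariance_ci": self.covariance_ci,
            "correlation_ci": self.correlation_ci,
        }


@dataclass
class CohortTrendRow:
    """Additive-genetic and unique-environment decomposition of one cohort."""

    cohort_year: int
    n_pairs: int
    total_var: float
    var_a: float
    var_e: float
    heritability: float  # uncapped 2·correlation
    var_a_ci: tuple[float, float] | None = None
    var_e_ci: tuple[float, float] | None = None
    consistent: bool = True  # False when correlation > 0.5 (var_a > total)

    def as_dict(self) -> dict:
        return {
            "cohort_year": self.cohort_year, "n_pairs": self.n_pairs,
            "total_var": self.total_var, "var_a": self.var_a,
            "var_e": self.var_e, "heritability": self.heritability,
            "var_a_ci": self.var_a_ci, "var_e_ci": self.var_e_ci,
            "consistent": self.consistent,
        }


def _double_entry(a: np.ndarray, b: np.ndarray):
    x = np.concatenate([a, b])
    m = float(x.mean())
    var = float(np.mean((x - m) ** 2))
    cov = float(np.mean((a - m) * (b - m)))
    return m, var, cov


def summarize_pairs(
    pairs: pd.DataFrame,
    stratum: str = "all",
    *,
    ci: str | None = "bootstrap",
    b: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> PairSummary:
    """Double-entry mean, variance, covariance and correlation of a stratum.

    ``ci`` selects the covariance interval: ``"bootstrap"`` (seeded pair
    resampling, default), ``"delta"`` (normal-theory large-sample), or
    ``None``. The correlation interval is always the Fisher-z form with the
    number of pairs as effective sample size.
    """
    n = len(pairs)
    if n < 2:
        raise DataError(f"stratum {stratum!r} has {n} pairs; need at least 2")
    a = pairs["bmi_a"].to_numpy(dtype=float)
    bb = pairs["bmi_b"].to_numpy(dtype=float)
    m, var, cov = _double_entry(a, bb)
    if var <= 0:
        raise DataError(f"stratum {stratum!r} has zero variance")
    corr = cov / var
    summary = PairSummary(stratum=stratum, n_pairs=n, mean=m,
                          variance=var, covariance=cov, correlation=corr)
    if abs(corr) < 1.0:
        summary.correlation_ci = correlation_ci(corr, n, level)
    if ci == "bootstrap":
        rng = np.random.default_rng(seed)
        boot_cov = np.empty(b)
        boot_var = np.empty(b)
        for i in range(b):
            idx = rng.integers(0, n, size=n)
            _, bv, bc = _double_entry(a[idx], bb[idx])
            boot_cov[i] = bc
            boot_var[i] = bv
        lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
        summary.covariance_ci = (float(np.quantile(boot_cov, lo)),
                                 float(np.quantile(boot_cov, hi)))
        summary.boot_cov = boot_cov
        summary.boot_var = boot_var
    elif ci == "delta":
        # large-sample variance of a bivariate-normal covariance estimate
        se = np.sqrt((var**2 + cov**2) / n)
        z = stats.norm.ppf(1 - (1 - level) / 2)
        summary.covariance_ci = (cov - z * se, cov + z * se)
    elif ci is not None:
        raise DataError(f"unknown ci method {ci!r}")
    return summary


def correlation_ci(correlation: float, n_pairs: int, level: float = 0.95):
    """Fisher z-transform interval for an intraclass correlation.

    Effective sample size is the number of pairs (not the doubled sample);
    the interval is symmetric in z-space. ``level`` 0 collapses to a point;
    |r| = 1 returns the degenerate interval (r, r).
    """
    if n_pairs < 4:
        raise DataError("need at least 4 pairs for a correlation CI")
    r = float(correlation)
    if abs(r) >= 1.0:
        logger.warning("degenerate correlation %g; returning point interval", r)
        return (r, r)
    if level == 0:
        return (r, r)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n_pairs - 3)
    zc = stats.norm.ppf(1 - (1 - level) / 2)
    return (float(np.tanh(z - zc * se)), float(np.tanh(z + zc * se)))


def additive_and_env(summary: PairSummary, level: float = 0.95) -> CohortTrendRow:
    """Decompose one stratum: V_A = 2·cov, V_E = V − V_A, h² = 2·r.

    CIs are propagated from the summary's joint bootstrap draws when present
    (percentile), otherwise from the covariance interval by the linear maps
    V_A = 2·cov and, lacking joint draws, V_E is left without an interval.
    A correlation above 0.5 makes V_A exceed the total; the row is then
    flagged inconsistent rather than rejected.
    """
    try:
        year = int(summary.stratum)
    except (TypeError, ValueError):
        year = -1
    var_a = 2.0 * summary.covariance
    var_e = summary.variance - var_a
    row = CohortTrendRow(
        cohort_year=year, n_pairs=summary.n_pairs,
        total_var=summary.variance, var_a=var_a, var_e=var_e,
        heritability=2.0 * summary.correlation,
        consistent=var_a <= summary.variance,
    )
    if not row.consistent:
        logger.warning("stratum %s: correlation %.3f > 0.5, additive variance "
                       "exceeds total; row flagged inconsistent",
                       summary.stratum, summary.correlation)
    if summary.boot_cov is not None:
        lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
        a_draws = 2.0 * summary.boot_cov
        e_draws = summary.boot_var - a_draws
        row.var_a_ci = (float(np.quantile(a_draws, lo)), float(np.quantile(a_draws, hi)))
        row.var_e_ci = (float(np.quantile(e_draws, lo)), float(np.quantile(e_draws, hi)))
    elif summary.covariance_ci is not None:
        row.var_a_ci = (2.0 * summary.covariance_ci[0], 2.0 * summary.covariance_ci[1])
    return row


def build_trend(
    pairs: pd.DataFrame,
    *,
    min_pairs: int = 50,
    ci: str | None = "bootstrap",
    b: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    window: int = 1,
) -> list[CohortTrendRow]:
    """One decomposition row per cohort year, ordered by year.

    Cohorts are calendar birth years (``cohort_year`` must be assigned);
    ``window`` > 1 pools each year with its neighbours in a centred rolling
    window, for small synthetic datasets. Cohorts below ``min_pairs`` are
    skipped with a log entry.
    """
    if pairs["cohort_year"].isna().any():
        raise DataError("pairs lack cohort_year; run assign_cohort first")
    years = sorted(int(y) for y in pairs["cohort_year"].unique())
    rows = []
    half = (window - 1) // 2
    for i, year in enumerate(years):
        if window > 1:
            members = [y for y in years if abs(y - year) <= half]
            grp = pairs[pairs["cohort_year"].isin(members)]
        else:
            grp = pairs[pairs["cohort_year"] == year]
        if len(grp) < min_pairs:
            logger.info("cohort %d skipped: %d pairs < min_pairs=%d",
                        year, len(grp), min_pairs)
            continue
        summary = summarize_pairs(grp, stratum=str(year), ci=ci, b=b,
                                  seed=seed + i, level=level)
        rows.append(additive_and_env(summary, level=level))
    if not rows:
        raise DataError("no cohort reached min_pairs")
    return rows


def trend_frame(rows: list[CohortTrendRow]) -> pd.DataFrame:
    """Flatten trend rows into the tabular (TSV-ready) layout."""
    rec = []
    for r in rows:
        a_lo, a_hi = r.var_a_ci if r.var_a_ci else (np.nan, np.nan)
        e_lo, e_hi = r.var_e_ci if r.var_e_ci else (np.nan, np.nan)
        rec.append({
            "year": r.cohort_year, "n": r.n_pairs, "total_var": r.total_var,
            "var_a": r.var_a, "var_a_lo": a_lo, "var_a_hi": a_hi,
            "var_e": r.var_e, "var_e_lo": e_lo, "var_e_hi": e_hi,
            "h2": r.heritability,
        })
    return pd.DataFrame.from_records(rec)
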