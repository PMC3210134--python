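"""Maximum-likelihood variance-component models for relative pairs.

The classical biometric model writes the phenotypic variance of a trait as
V = A + C + D + E (additive genetic, common environment, dominance, unique
environment). A pair of relatives is bivariate normal with common mean, both
marginal variances V, and within-pair covariance w_a·A + w_c·C + w_d·D,
where the weights depend only on the relation (MZ 1/1/1, DZ and full
siblings 1/2, 1, 1/4). Fitting several relation groups jointly identifies
the components; with pairs reared together C and D cannot be estimated
simultaneously, so the ACE and ADE models are compared instead and reduced
models tested by likelihood ratio.

Likelihood evaluation uses per-group sufficient statistics (n, Σx, Σx²,
Σxy), so a fit on hundreds of thousands of pairs costs microseconds per
objective evaluation, and an analytic gradient keeps the optimum sharp.
Non-negativity of the components is enforced by optimizing unconstrained
path coefficients and squaring them (a², c², e²), the behaviour-genetics
convention; variances are reported.

Also provided: Falconer's closed-form estimates from the two twin
correlations, the equal-means-and-variances assumption test, and
likelihood-ratio model comparison with the parsimony rule (prefer the
reduced model unless the test rejects it).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import BoundaryError, ConfigError, DataError, IdentificationError
from .simulate import pair_covariance_weights

logger = logging.getLogger(__name__)

LOG_2PI = math.log(2.0 * math.pi)

#: Variance components of each supported model, in path order.
MODELS = {
    "ACE": ("a", "c", "e"),
    "ADE": ("a", "d", "e"),
    "AE": ("a", "e"),
    "CE": ("c", "e"),
    "E": ("e",),
}


def _component_weight(comp: str, relation: str) -> float:
    wa, wc, wd = pair_covariance_weights(relation)
    return {"a": wa, "c": wc, "d": wd, "e": 0.0}[comp]


@dataclass(frozen=True)
class VarianceComponents:
    """Raw variance components (kg²/m⁴) plus the phenotype mean.

    Standardized shares are derived properties; components absent from the
    model are exactly zero.
    """

    model: str
    var_a: float = 0.0
    var_c: float = 0.0
    var_d: float = 0.0
    var_e: float = 0.0
    mean: float = 0.0

    @property
    def total(self) -> float:
        return self.var_a + self.var_c + self.var_d + self.var_e

    @property
    def std_a(self) -> float:
        return self.var_a / self.total

    @property
    def std_c(self) -> float:
        return self.var_c / self.total

    @property
    def std_d(self) -> float:
        return self.var_d / self.total

    @property
    def std_e(self) -> float:
        return self.var_e / self.total

    def as_dict(self) -> dict:
        return {
            "model": self.model, "mean": self.mean,
            "var_a": self.var_a, "var_c": self.var_c,
            "var_d": self.var_d, "var_e": self.var_e,
            "std_a": self.std_a, "std_c": self.std_c,
            "std_d": self.std_d, "std_e": self.std_e,
            "total": self.total,
        }


@dataclass
class ModelFit:
    components: VarianceComponents
    loglik: float
    n_params: int
    converged: bool
    ci: dict = field(default_factory=dict)
    ci_method: str | None = None
    ci_level: float = 0.95
    n_pairs: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "components": self.components.as_dict(),
            "loglik": self.loglik,
            "n_params": self.n_params,
            "converged": self.converged,
            "ci": {k: list(v) for k, v in self.ci.items()},
            "ci_method": self.ci_method,
            "ci_level": self.ci_level,
            "n_pairs": self.n_pairs,
        }


@dataclass
class ModelComparison:
    chi_square: float
    df: int
    p_value: float
    preferred: str
    p_value_mixture: float | None = None
    alpha: float = 0.05

    def as_dict(self) -> dict:
        return {
            "chi_square": self.chi_square, "df": self.df,
            "p_value": self.p_value, "preferred": self.preferred,
            "p_value_mixture": self.p_value_mixture, "alpha": self.alpha,
        }


def expected_pair_matrix(components: VarianceComponents, relation: str) -> np.ndarray:
    """2×2 expected covariance of a pair under the model: V on the diagonal,
    the relation-weighted component sum off it."""
    for name in ("var_a", "var_c", "var_d", "var_e"):
        if getattr(components, name) < 0:
            raise ConfigError(f"negative component {name}")
    v = components.total
    c = (
        _component_weight("a", relation) * components.var_a
        + _component_weight("c", relation) * components.var_c
        + _component_weight("d", relation) * components.var_d
    )
    return np.array([[v, c], [c, v]])


# ---------------------------------------------------------------------------
# Sufficient statistics and the pair likelihood


@dataclass(frozen=True)
class GroupStats:
    """Sufficient statistics of one relation group of pairs."""

    relation: str
    n: int
    s1a: float
    s1b: float
    s2a: float
    s2b: float
    sab: float

    @classmethod
    def from_pairs(cls, relation: str, pairs: pd.DataFrame) -> "GroupStats":
        a = pairs["bmi_a"].to_numpy(dtype=float)
        b = pairs["bmi_b"].to_numpy(dtype=float)
        return cls(
            relation=relation, n=len(pairs),
            s1a=float(a.sum()), s1b=float(b.sum()),
            s2a=float(a @ a), s2b=float(b @ b), sab=float(a @ b),
        )


def group_stats(pairs: pd.DataFrame) -> dict[str, GroupStats]:
    """Sufficient statistics per relation present in a pair table."""
    out = {}
    for relation, grp in pairs.groupby("relation", sort=True):
        pair_covariance_weights(relation)  # validate early
        out[str(relation)] = GroupStats.from_pairs(str(relation), grp)
    if not out:
        raise DataError("empty pair table")
    return out


def _group_loglik_terms(g: GroupStats, mu: float, v: float, c: float):
    """Log-likelihood of one group and its partials w.r.t. (mu, v, c)."""
    det = v * v - c * c
    if det <= 0.0 or v <= 0.0:
        return None
    saa = g.s2a - 2.0 * mu * g.s1a + g.n * mu * mu
    sbb = g.s2b - 2.0 * mu * g.s1b + g.n * mu * mu
    sab = g.sab - mu * (g.s1a + g.s1b) + g.n * mu * mu
    q = v * (saa + sbb) - 2.0 * c * sab
    ll = -g.n * LOG_2PI - 0.5 * g.n * math.log(det) - q / (2.0 * det)
    dsum_dmu = (-2.0 * g.s1a + 2.0 * g.n * mu) + (-2.0 * g.s1b + 2.0 * g.n * mu)
    dsab_dmu = -(g.s1a + g.s1b) + 2.0 * g.n * mu
    dq_dmu = v * dsum_dmu - 2.0 * c * dsab_dmu
    dll_dmu = -dq_dmu / (2.0 * det)
    dll_dv = -g.n * v / det - ((saa + sbb) * det - q * 2.0 * v) / (2.0 * det * det)
    dll_dc = g.n * c / det - (-2.0 * sab * det + q * 2.0 * c) / (2.0 * det * det)
    return ll, dll_dmu, dll_dv, dll_dc


def pair_loglik(pairs: pd.DataFrame, components: VarianceComponents) -> float:
    """Joint log-likelihood of a pair table under fixed components.

    Sums the bivariate-normal log-density over pairs, each relation using
    its expected 2×2 matrix; invariant to within-pair ordering.
    """
    stats_by_rel = pairs if isinstance(pairs, dict) else group_stats(pairs)
    total = 0.0
    v = components.total
    for rel, g in stats_by_rel.items():
        c = float(expected_pair_matrix(components, rel)[0, 1])
        terms = _group_loglik_terms(g, components.mean, v, c)
        if terms is None:
            raise BoundaryError(
                f"singular expected matrix for relation {rel} "
                "(within-pair correlation of 1 requires var_e > 0)"
            )
        total += terms[0]
    return total


# ---------------------------------------------------------------------------
# Model fitting


class _Objective:
    """Negative log-likelihood in (mu, path...) coordinates with gradient.

    Normalized per pair (divided by the total pair count) so optimizer
    tolerances and the returned function scale are sample-size independent;
    multiply by ``norm`` to recover the joint NLL.
    """

    _PENALTY = 1e12

    def __init__(self, comps: tuple[str, ...], stats_by_rel: dict[str, GroupStats]):
        self.comps = comps
        self.stats = stats_by_rel
        self.norm = float(sum(g.n for g in stats_by_rel.values()))
        self.weights = {
            rel: np.array([_component_weight(cp, rel) for cp in comps])
            for rel in stats_by_rel
        }

    def variances(self, x: np.ndarray) -> np.ndarray:
        return np.square(x[1:])

    def __call__(self, x: np.ndarray):
        mu = x[0]
        var = self.variances(x)
        v = float(var.sum())
        nll = 0.0
        grad = np.zeros_like(x)
        for rel, g in self.stats.items():
            w = self.weights[rel]
            c = float(w @ var)
            terms = _group_loglik_terms(g, mu, v, c)
            if terms is None:
                return self._PENALTY, np.zeros_like(x)
            ll, dmu, dv, dc = terms
            nll -= ll
            grad[0] -= dmu
            grad[1:] -= (dv + dc * w) * 2.0 * x[1:]
        return nll / self.norm, grad / self.norm


def _moment_start(comps, stats_by_rel) -> np.ndarray:
    """Method-of-moments starting values on the path scale."""
    n_tot = sum(g.n for g in stats_by_rel.values())
    mu = sum(g.s1a + g.s1b for g in stats_by_rel.values()) / (2 * n_tot)
    v_hat = sum(g.s2a + g.s2b for g in stats_by_rel.values()) / (2 * n_tot) - mu * mu
    v_hat = max(v_hat, 1e-6)
    rows, rhs = [], []
    for rel, g in stats_by_rel.items():
        cov = g.sab / g.n - mu * (g.s1a + g.s1b) / g.n + mu * mu
        rows.append([_component_weight(cp, rel) for cp in comps])
        rhs.append(cov)
    rows.append([1.0] * len(comps))
    rhs.append(v_hat)
    sol, *_ = np.linalg.lstsq(np.array(rows), np.array(rhs), rcond=None)
    sol = np.clip(sol, 0.05 * v_hat / len(comps), None)
    sol *= v_hat / sol.sum()
    return np.concatenate([[mu], np.sqrt(sol)])


def _minimize(obj: _Objective, x0: np.ndarray, tol: float):
    res = optimize.minimize(
        obj, x0, jac=True, method="L-BFGS-B",
        options={"maxiter": 2000, "ftol": tol, "gtol": 1e-12},
    )
    return res


def fit_model(
    pairs: pd.DataFrame,
    model: str = "AE",
    *,
    seed: int = 0,
    n_starts: int = 5,
    ci: str | None = "profile",
    level: float = 0.95,
    tol: float = 1e-14,
    bootstrap_b: int = 1000,
) -> ModelFit:
    """Fit a variance-component model to relative pairs by maximum likelihood.

    Parameters
    ----------
    pairs
        Pair table with columns ``relation, bmi_a, bmi_b`` (further columns
        ignored), or a precomputed ``{relation: GroupStats}`` mapping.
    model
        One of ``ACE, ADE, AE, CE, E``. Requesting C and D together is
        refused: with pairs reared together the two are not simultaneously
        identifiable.
    ci
        ``"profile"`` (likelihood-profile intervals, default), ``"bootstrap"``
        (seeded pair resampling, ``bootstrap_b`` replicates), or ``None``.

    Returns a :class:`ModelFit`; the components maximize the pair likelihood
    under non-negativity (squared-path parameterization, multi-start
    quasi-Newton).
    """
    label = model.upper()
    if set(label) >= {"C", "D"}:
        logger.warning("refusing to fit C and D simultaneously (not identifiable "
                       "from pairs reared together); fit ACE and ADE separately")
        raise IdentificationError("C and D cannot be estimated simultaneously")
    if label not in MODELS:
        raise ConfigError(f"unknown model {label!r}; choose from {sorted(MODELS)}")
    comps = MODELS[label]
    stats_by_rel = pairs if isinstance(pairs, dict) else group_stats(pairs)
    if label in ("ACE", "ADE"):
        distinct = {tuple(pair_covariance_weights(r)) for r in stats_by_rel}
        if len(distinct) < 2:
            raise IdentificationError(
                f"model {label} needs at least two relation groups with "
                f"distinct sharing weights; got {sorted(stats_by_rel)}"
            )

    obj = _Objective(comps, stats_by_rel)
    x0 = _moment_start(comps, stats_by_rel)
    rng = np.random.default_rng(seed)
    starts = [x0]
    for _ in range(max(0, n_starts - 1)):
        jitter = rng.uniform(0.5, 1.5, size=x0.size)
        jitter[0] = 1.0
        starts.append(x0 * jitter + np.concatenate([[rng.normal(0, 0.1)], np.zeros(x0.size - 1)]))
    best = None
    for s in starts:
        res = _minimize(obj, s, tol)
        if best is None or res.fun < best.fun:
            best = res
    var = obj.variances(best.x)
    fitted = VarianceComponents(
        model=label, mean=float(best.x[0]),
        **{f"var_{cp}": float(v) for cp, v in zip(comps, var)},
    )
    # a line search stopping at machine precision still counts as converged
    # when the projected gradient (per pair) is negligible
    converged = bool(best.success) or float(np.max(np.abs(best.jac))) < 1e-6
    fit = ModelFit(
        components=fitted,
        loglik=float(-best.fun * obj.norm),
        n_params=1 + len(comps),
        converged=converged,
        ci_method=ci,
        ci_level=level,
        n_pairs={rel: g.n for rel, g in stats_by_rel.items()},
    )
    if not converged:
        logger.warning("fit_model(%s) did not report convergence: %s", label, best.message)
    if ci == "profile":
        fit.ci = _profile_cis(obj, best, comps, level)
    elif ci == "bootstrap":
        if isinstance(pairs, dict):
            raise DataError("bootstrap CIs need the raw pair table, not "
                            "precomputed sufficient statistics")
        fit.ci = _bootstrap_cis_from_pairs(pairs, label, level, bootstrap_b, seed)
    elif ci is not None:
        raise ConfigError(f"unknown ci method {ci!r}")
    return fit


# -- profile confidence intervals -------------------------------------------


def _profile_nll(obj: _Objective, x_mle: np.ndarray, j: int, kind: str, value: float) -> float:
    """Minimized NLL with component j fixed at ``value`` (raw or std scale)."""
    free_idx = [0] + [i for i in range(1, x_mle.size) if i != j + 1]

    if kind == "raw":
        def fun(z):
            x = np.empty(x_mle.size)
            x[free_idx] = z
            x[j + 1] = math.sqrt(max(value, 0.0))
            f, g = obj(x)
            return f, g[free_idx]
    else:  # std share s: p_j^2 = s/(1-s) * sum of other squared paths
        ratio = value / (1.0 - value)

        def fun(z):
            x = np.empty(x_mle.size)
            x[free_idx] = z
            other = float(np.square(x[free_idx[1:]]).sum())
            pj = math.sqrt(ratio * other)
            x[j + 1] = pj
            f, g = obj(x)
            gz = g[free_idx].copy()
            if pj > 0:  # chain rule through the dependent path coefficient
                gz[1:] += g[j + 1] * ratio * x[free_idx[1:]] / pj
            return f, gz

    z0 = x_mle[free_idx].copy()
    if kind == "std" and np.square(z0[1:]).sum() < 1e-12:
        z0[1:] += 1e-4
    res = optimize.minimize(fun, z0, jac=True, method="L-BFGS-B",
                            options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-12})
    return float(res.fun)


def _profile_interval(obj, best, j, kind, mle_value, scale, crit):
    def deviance(val):
        return 2.0 * obj.norm * (_profile_nll(obj, best.x, j, kind, val) - best.fun)

    hi_cap = 1.0 - 1e-9 if kind == "std" else None
    # lower bound
    if mle_value <= 1e-12 or deviance(0.0) <= crit:
        lo = 0.0
    else:
        lo = optimize.brentq(lambda v: deviance(v) - crit, 0.0, mle_value, xtol=1e-6 * scale)
    # upper bound: expand a bracket
    hi = None
    step = max(mle_value, 0.05 * scale)
    upper = mle_value
    for _ in range(60):
        upper = upper + step
        if hi_cap is not None and upper >= hi_cap:
            if deviance(hi_cap) <= crit:
                hi = 1.0
            else:
                hi = optimize.brentq(lambda v: deviance(v) - crit,
                                     max(mle_value, 1e-12), hi_cap, xtol=1e-8)
            break
        if deviance(upper) > crit:
            hi = optimize.brentq(lambda v: deviance(v) - crit,
                                 max(mle_value, 1e-12), upper, xtol=1e-6 * scale)
            break
        step *= 2.0
    if hi is None:
        hi = float("inf")
    return lo, hi


def _profile_cis(obj: _Objective, best, comps, level) -> dict:
    crit = stats.chi2.ppf(level, 1)
    var = obj.variances(best.x)
    total = float(var.sum())
    out = {}
    for j, cp in enumerate(comps):
        out[f"var_{cp}"] = _profile_interval(obj, best, j, "raw", float(var[j]), total, crit)
        if len(comps) > 1:
            out[f"std_{cp}"] = _profile_interval(
                obj, best, j, "std", float(var[j]) / total, 1.0, crit)
    return out


def _bootstrap_cis_from_pairs(pairs: pd.DataFrame, model: str, level: float,
                              b: int, seed: int) -> dict:
    rng = np.random.default_rng(seed)
    comps = MODELS[model]
    cols = {}
    groups = {rel: grp.reset_index(drop=True) for rel, grp in pairs.groupby("relation")}
    records = []
    for _ in range(b):
        boot_stats = {}
        for rel, grp in groups.items():
            idx = rng.integers(0, len(grp), size=len(grp))
            boot_stats[rel] = GroupStats.from_pairs(rel, grp.iloc[idx])
        fit = fit_model(boot_stats, model, ci=None, n_starts=1)
        records.append(fit.components.as_dict())
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    for key in [f"var_{cp}" for cp in comps] + [f"std_{cp}" for cp in comps]:
        vals = np.array([r[key] for r in records])
        cols[key] = (float(np.quantile(vals, lo_q)), float(np.quantile(vals, hi_q)))
    return cols


def bootstrap_fit_cis(pairs: pd.DataFrame, model: str = "AE", *, level: float = 0.95,
                      b: int = 1000, seed: int = 0) -> dict:
    """Nonparametric pair-resampling bootstrap CIs for a fitted model."""
    return _bootstrap_cis_from_pairs(pairs, model.upper(), level, b, seed)


# ---------------------------------------------------------------------------
# Model comparison and closed-form estimators


def compare_models(full: ModelFit, reduced: ModelFit, alpha: float = 0.05) -> ModelComparison:
    """Likelihood-ratio comparison of nested fits with the parsimony rule.

    The naive chi-square reference is used for the headline p-value (matching
    common structural-equation practice even when a variance sits on the
    boundary); for single-constraint comparisons the 50:50 mixture p-value is
    reported alongside.
    """
    full_comps = set(MODELS.get(full.components.model, ()))
    red_comps = set(MODELS.get(reduced.components.model, ()))
    if not (red_comps < full_comps):
        raise ConfigError(
            f"{reduced.components.model} is not nested in {full.components.model}"
        )
    chi = 2.0 * (full.loglik - reduced.loglik)
    if chi < -1e-6:
        logger.warning("nested fit has higher likelihood than nesting fit "
                       "(Δ=%g); treating chi-square as 0", chi)
    chi = max(chi, 0.0)
    df = full.n_params - reduced.n_params
    p = float(stats.chi2.sf(chi, df)) if df > 0 else 1.0
    mixture = None
    if df == 1:
        mixture = 1.0 if chi == 0.0 else float(0.5 * stats.chi2.sf(chi, 1))
    preferred = reduced.components.model if p > alpha else full.components.model
    return ModelComparison(chi_square=float(chi), df=df, p_value=p,
                           preferred=preferred, p_value_mixture=mixture, alpha=alpha)


@dataclass(frozen=True)
class FalconerEstimates:
    """Closed-form standardized components from the two twin correlations."""

    a2: float
    c2: float
    e2: float

    @property
    def clipped(self) -> tuple[float, float, float]:
        return tuple(float(np.clip(v, 0.0, 1.0)) for v in (self.a2, self.c2, self.e2))


def falconer_estimates(r_mz: float, r_dz: float) -> FalconerEstimates:
    """a² = 2(r_MZ − r_DZ), c² = 2r_DZ − r_MZ, e² = 1 − r_MZ (unclipped)."""
    for r in (r_mz, r_dz):
        if not -1.0 <= r <= 1.0:
            raise ConfigError(f"correlation {r} outside [-1, 1]")
    return FalconerEstimates(
        a2=2.0 * (r_mz - r_dz), c2=2.0 * r_dz - r_mz, e2=1.0 - r_mz,
    )


# ---------------------------------------------------------------------------
# Equal means and variances assumption test


def _saturated_loglik(pairs: pd.DataFrame) -> float:
    x = pairs[["bmi_a", "bmi_b"]].to_numpy(dtype=float)
    n = len(x)
    s = np.cov(x, rowvar=False, bias=True)
    det = float(np.linalg.det(s))
    if det <= 0 or s[0, 0] <= 0 or s[1, 1] <= 0:
        raise DataError("degenerate within-group covariance")
    return -n * LOG_2PI - 0.5 * n * math.log(det) - n


def test_equal_means_variances(
    mz_pairs: pd.DataFrame, dz_pairs: pd.DataFrame, alpha: float = 0.05,
) -> ModelComparison:
    """LRT of group- and order-specific means/variances against a shared
    mean and variance (covariances stay group-specific in both models).

    The saturated model gives each group free member means and a free 2×2
    covariance (10 parameters); the constrained model shares one mean and
    one variance across groups and pair order but keeps per-group
    covariances (4 parameters), hence df = 6. A small p-value signals that
    the equal-means-and-variances premise of the twin design is violated.
    """
    for name, grp in (("MZ", mz_pairs), ("DZ", dz_pairs)):
        if len(grp) < 2:
            raise DataError(f"{name} group needs at least 2 pairs")
    ll_sat = _saturated_loglik(mz_pairs) + _saturated_loglik(dz_pairs)

    gs = {rel: GroupStats.from_pairs(rel, grp)
          for rel, grp in (("MZ", mz_pairs), ("DZ", dz_pairs))}

    def nll(theta):
        mu, log_v, z_mz, z_dz = theta
        v = math.exp(log_v)
        total = 0.0
        for rel, z in (("MZ", z_mz), ("DZ", z_dz)):
            c = v * math.tanh(z)
            terms = _group_loglik_terms(gs[rel], mu, v, c)
            if terms is None:
                return 1e12
            total -= terms[0]
        return total

    pooled = pd.concat([mz_pairs, dz_pairs])
    x = pooled[["bmi_a", "bmi_b"]].to_numpy(dtype=float)
    mu0 = float(x.mean())
    v0 = float(x.var())
    if v0 <= 0:
        raise DataError("degenerate pooled variance")

    def start_z(grp):
        a, b = grp["bmi_a"].to_numpy(float), grp["bmi_b"].to_numpy(float)
        r = float(np.mean((a - mu0) * (b - mu0)) / v0)
        return np.arctanh(np.clip(r, -0.99, 0.99))

    theta0 = np.array([mu0, math.log(v0), start_z(mz_pairs), start_z(dz_pairs)])
    res = optimize.minimize(nll, theta0, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 8000})
    chi = max(0.0, 2.0 * (ll_sat + res.fun))
    df = 10 - 4
    p = float(stats.chi2.sf(chi, df))
    preferred = "constrained" if p > alpha else "saturated"
    return ModelComparison(chi_square=float(chi), df=df, p_value=p,
                           preferred=preferred, alpha=alpha)
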