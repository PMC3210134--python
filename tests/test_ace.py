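"""ML variance-component fitting, model comparison, closed-form estimators."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import optimize, stats

import twinvar as tv
from twinvar.ace import GroupStats, MODELS, _Objective, group_stats
from twinvar.errors import ConfigError, IdentificationError

from conftest import AE_SPEC


class TestExpectedPairMatrix:
    def test_ae_mz_matrix(self):
        comp = tv.VarianceComponents(model="AE", var_a=4.6, var_e=1.0)
        m = tv.expected_pair_matrix(comp, "MZ")
        assert m == pytest.approx(np.array([[5.6, 4.6], [4.6, 5.6]]))

    def test_ae_dz_halves_additive_share(self):
        comp = tv.VarianceComponents(model="AE", var_a=4.6, var_e=1.0)
        m = tv.expected_pair_matrix(comp, "DZ")
        assert m[0, 1] == pytest.approx(2.3)

    def test_pure_environment_gives_diagonal(self):
        comp = tv.VarianceComponents(model="E", var_e=1.0)
        m = tv.expected_pair_matrix(comp, "FS")
        assert m == pytest.approx(np.eye(2))

    def test_negative_component_rejected(self):
        comp = tv.VarianceComponents(model="AE", var_a=-0.1, var_e=1.0)
        with pytest.raises(ConfigError):
            tv.expected_pair_matrix(comp, "MZ")


class TestPairLoglik:
    def test_single_pair_at_mean_identity_matrix(self):
        pairs = tv.io.make_pair_frame("MZ", ["a"], ["b"], [0.0], [0.0], [1970], [1970])
        comp = tv.VarianceComponents(model="E", var_e=1.0, mean=0.0)
        assert tv.pair_loglik(pairs, comp) == pytest.approx(-math.log(2 * math.pi))

    def test_invariant_to_member_swap(self, small_twin_pairs):
        comp = tv.VarianceComponents(model="AE", var_a=4.0, var_e=1.5, mean=21.0)
        swapped = small_twin_pairs.rename(columns={
            "bmi_a": "bmi_b", "bmi_b": "bmi_a"})
        assert tv.pair_loglik(swapped, comp) == pytest.approx(
            tv.pair_loglik(small_twin_pairs, comp))

    def test_matches_per_pair_density_sum(self):
        pairs = pd.concat([
            tv.simulate_pairs("MZ", 25, AE_SPEC, seed=31, id_prefix="m"),
            tv.simulate_pairs("DZ", 25, AE_SPEC, seed=32, id_prefix="d"),
        ], ignore_index=True)
        comp = tv.VarianceComponents(model="AE", var_a=4.2, var_e=1.3, mean=20.8)
        brute = 0.0
        for row in pairs.itertuples():
            sigma = tv.expected_pair_matrix(comp, row.relation)
            brute += stats.multivariate_normal.logpdf(
                [row.bmi_a, row.bmi_b], mean=[comp.mean, comp.mean], cov=sigma)
        assert tv.pair_loglik(pairs, comp) == pytest.approx(brute)

    def test_singular_expected_matrix_raises_boundary_error(self):
        pairs = tv.io.make_pair_frame("MZ", ["a"], ["b"], [1.0], [1.0], [1970], [1970])
        comp = tv.VarianceComponents(model="AE", var_a=1.0, var_e=0.0)
        with pytest.raises(tv.BoundaryError):
            tv.pair_loglik(pairs, comp)


def test_objective_gradient_matches_numeric(small_twin_pairs):
    obj = _Objective(MODELS["ACE"], group_stats(small_twin_pairs))
    x = np.array([20.5, 1.8, 0.6, 1.1])
    err = optimize.check_grad(lambda z: obj(z)[0], lambda z: obj(z)[1], x)
    assert err <= 1e-4 * abs(obj(x)[0])


class TestFitModel:
    def test_ae_recovery_on_ae_truth(self, twin_ae_pairs):
        fit = tv.fit_model(twin_ae_pairs, "AE", ci=None)
        assert fit.converged
        assert fit.components.std_a == pytest.approx(0.82, abs=0.01)
        assert fit.components.std_a + fit.components.std_e == pytest.approx(1.0)

    def test_boundary_c_prefers_ae_under_lrt(self, twin_ae_pairs):
        # truth has C = 0: the ACE fit should sit near the boundary and the
        # LRT should keep the reduced AE model
        ace_fit = tv.fit_model(twin_ae_pairs, "ACE", ci=None)
        ae_fit = tv.fit_model(twin_ae_pairs, "AE", ci=None)
        comp = tv.compare_models(ace_fit, ae_fit)
        assert comp.preferred == "AE"
        assert ace_fit.components.var_c <= 0.2

    def test_ae_selection_rate_under_ae_truth(self):
        from twinvar.cli import _select_parsimonious
        wins = 0
        reps = 100
        for rep in range(reps):
            pairs = pd.concat([
                tv.simulate_pairs("MZ", 1500, AE_SPEC, seed=1000 + rep, id_prefix="m"),
                tv.simulate_pairs("DZ", 1500, AE_SPEC, seed=5000 + rep, id_prefix="d"),
            ], ignore_index=True)
            fits = {m: tv.fit_model(pairs, m, ci=None, n_starts=2)
                    for m in ("ACE", "ADE", "AE", "E")}
            selected, _ = _select_parsimonious(fits, alpha=0.05)
            wins += selected == "AE"
        assert wins >= 90

    def test_common_environment_detected_when_present(self):
        spec = tv.ComponentSpec(var_a=2.8, var_c=1.7, var_e=1.1, mean=21.0)
        pairs = pd.concat([
            tv.simulate_pairs("MZ", 20_000, spec, seed=41, id_prefix="m"),
            tv.simulate_pairs("DZ", 20_000, spec, seed=42, id_prefix="d"),
        ], ignore_index=True)
        ace_fit = tv.fit_model(pairs, "ACE", ci=None)
        ae_fit = tv.fit_model(pairs, "AE", ci=None)
        comp = tv.compare_models(ace_fit, ae_fit)
        assert comp.preferred == "ACE"
        assert ace_fit.components.var_c == pytest.approx(1.7, abs=0.3)

    def test_c_and_d_simultaneously_refused(self, twin_ae_pairs):
        with pytest.raises(IdentificationError):
            tv.fit_model(twin_ae_pairs, "ACDE")

    def test_single_relation_ace_unidentified(self):
        mz_only = tv.simulate_pairs("MZ", 500, AE_SPEC, seed=43)
        with pytest.raises(IdentificationError):
            tv.fit_model(mz_only, "ACE")

    def test_grid_search_oracle_agrees(self, small_twin_pairs):
        """The ML optimum matches an exhaustive 41^3 grid over (mean, total
        variance, additive share), evaluated with an independently coded
        bivariate-normal likelihood."""
        fit = tv.fit_model(small_twin_pairs, "AE", ci=None)
        sums = {}
        for rel, grp in small_twin_pairs.groupby("relation"):
            a = grp["bmi_a"].to_numpy()
            b = grp["bmi_b"].to_numpy()
            sums[rel] = (len(grp), a.sum(), b.sum(), a @ a, b @ b, a @ b)
        x = np.concatenate([small_twin_pairs["bmi_a"], small_twin_pairs["bmi_b"]])
        mu_grid = np.linspace(x.mean() - 0.5, x.mean() + 0.5, 41)
        t_grid = np.linspace(0.5 * x.var(), 1.5 * x.var(), 41)
        s_grid = np.linspace(0.0, 0.999, 41)
        mu, t, s = np.meshgrid(mu_grid, t_grid, s_grid, indexing="ij")
        w = {"MZ": 1.0, "DZ": 0.5}
        ll = np.zeros_like(mu)
        for rel, (n, s1a, s1b, s2a, s2b, sab) in sums.items():
            v, c = t, w[rel] * s * t
            det = v**2 - c**2
            saa = s2a - 2 * mu * s1a + n * mu**2
            sbb = s2b - 2 * mu * s1b + n * mu**2
            sab_c = sab - mu * (s1a + s1b) + n * mu**2
            q = v * (saa + sbb) - 2 * c * sab_c
            ll += -n * np.log(2 * np.pi) - 0.5 * n * np.log(det) - q / (2 * det)
        i, j, k = np.unravel_index(np.argmax(ll), ll.shape)
        assert fit.components.mean == pytest.approx(mu_grid[i], abs=np.diff(mu_grid)[0])
        assert fit.components.total == pytest.approx(t_grid[j], abs=np.diff(t_grid)[0])
        assert fit.components.std_a == pytest.approx(s_grid[k], abs=np.diff(s_grid)[0])

    def test_likelihood_nesting_monotonicity(self, twin_ae_pairs):
        lls = {m: tv.fit_model(twin_ae_pairs, m, ci=None).loglik
               for m in ("ACE", "AE", "E")}
        assert lls["ACE"] >= lls["AE"] - 1e-6
        assert lls["AE"] >= lls["E"] - 1e-6

    def test_scale_equivariance(self, twin_ae_pairs):
        k = 3.0
        scaled = twin_ae_pairs.copy()
        scaled["bmi_a"] *= k
        scaled["bmi_b"] *= k
        base = tv.fit_model(twin_ae_pairs, "AE", ci=None)
        scal = tv.fit_model(scaled, "AE", ci=None)
        assert scal.components.var_a == pytest.approx(k**2 * base.components.var_a, rel=1e-6)
        assert scal.components.var_e == pytest.approx(k**2 * base.components.var_e, rel=1e-6)
        assert scal.components.std_a == pytest.approx(base.components.std_a, abs=1e-6)

    def test_profile_ci_brackets_estimate(self, twin_ae_pairs):
        fit = tv.fit_model(twin_ae_pairs, "AE", ci="profile")
        lo, hi = fit.ci["std_a"]
        assert lo < fit.components.std_a < hi
        assert hi - lo < 0.05  # tight at n = 40k pairs

    def test_parameter_recovery_and_ci_coverage(self):
        """Over replicated AE-truth datasets the fitted standardized A is
        unbiased within Monte-Carlo tolerance and profile CIs attain close
        to nominal coverage."""
        truth = 0.8
        spec = tv.ComponentSpec(var_a=truth * 5.0, var_e=(1 - truth) * 5.0, mean=21.0)
        estimates, covered = [], 0
        reps = 100
        for rep in range(reps):
            pairs = pd.concat([
                tv.simulate_pairs("MZ", 10_000, spec, seed=20_000 + rep, id_prefix="m"),
                tv.simulate_pairs("DZ", 10_000, spec, seed=30_000 + rep, id_prefix="d"),
            ], ignore_index=True)
            fit = tv.fit_model(pairs, "AE", ci="profile", n_starts=2)
            estimates.append(fit.components.std_a)
            lo, hi = fit.ci["std_a"]
            covered += lo <= truth <= hi
        assert np.mean(estimates) == pytest.approx(truth, abs=0.01)
        assert 90 <= covered <= 99

    def test_falconer_and_ml_agree_without_dominance(self, twin_ae_pairs):
        fit = tv.fit_model(twin_ae_pairs, "AE", ci=None)
        r = {rel: tv.summarize_pairs(grp, ci=None).correlation
             for rel, grp in twin_ae_pairs.groupby("relation")}
        falc = tv.falconer_estimates(r["MZ"], r["DZ"])
        assert fit.components.std_a == pytest.approx(falc.a2, abs=0.02)


class TestCompareModels:
    @staticmethod
    def stub(model, loglik, n_params):
        comp = tv.VarianceComponents(model=model, var_a=1.0, var_e=1.0)
        return tv.ModelFit(components=comp, loglik=loglik,
                           n_params=n_params, converged=True)

    def test_identical_fits_prefer_reduced(self):
        c = tv.compare_models(self.stub("ACE", -100.0, 4), self.stub("AE", -100.0, 3))
        assert c.chi_square == 0.0 and c.p_value == 1.0 and c.preferred == "AE"

    def test_small_chi_square_keeps_parsimonious_model(self):
        c = tv.compare_models(self.stub("ACE", -100.0, 4),
                              self.stub("AE", -100.0 - 0.385 / 2, 3))
        assert c.chi_square == pytest.approx(0.385)
        assert c.df == 1
        assert c.p_value == pytest.approx(0.535, abs=5e-4)
        assert c.preferred == "AE"
        assert c.p_value_mixture == pytest.approx(0.535 / 2, abs=5e-4)

    def test_chi_square_critical_value(self):
        c = tv.compare_models(self.stub("ACE", -100.0, 4),
                              self.stub("AE", -100.0 - 3.84 / 2, 3))
        assert c.p_value == pytest.approx(0.050, abs=5e-4)

    def test_non_nested_pair_rejected(self):
        with pytest.raises(ConfigError):
            tv.compare_models(self.stub("AE", -100.0, 3), self.stub("CE", -101.0, 3))


class TestFalconer:
    def test_printed_twin_correlations(self):
        est = tv.falconer_estimates(0.83, 0.43)
        assert est.a2 == pytest.approx(0.80)
        assert est.c2 == pytest.approx(0.03)
        assert est.e2 == pytest.approx(0.17)

    def test_equal_correlations_give_zero_additive_share(self):
        assert tv.falconer_estimates(0.5, 0.5).a2 == 0.0

    def test_out_of_range_correlation_rejected(self):
        with pytest.raises(ConfigError):
            tv.falconer_estimates(1.2, 0.3)

    @given(st.floats(-1, 1), st.floats(-1, 1))
    def test_components_always_sum_to_one(self, r_mz, r_dz):
        est = tv.falconer_estimates(r_mz, r_dz)
        assert est.a2 + est.c2 + est.e2 == pytest.approx(1.0)


class TestEqualMeansVariances:
    def test_identical_symmetric_groups_give_zero_chi_square(self):
        # double-entering makes member means and variances exactly equal, so
        # with identical data in both groups the constrained model attains
        # the saturated likelihood
        raw = tv.simulate_pairs("MZ", 500, AE_SPEC, seed=51)
        swapped = raw.rename(columns={"bmi_a": "bmi_b", "bmi_b": "bmi_a"})
        pairs = pd.concat([raw, swapped], ignore_index=True)
        res = tv.test_equal_means_variances(pairs, pairs.copy())
        assert res.chi_square == pytest.approx(0.0, abs=0.05)
        assert res.df == 6

    def test_mean_shift_detected(self):
        spec = AE_SPEC
        shifted = tv.ComponentSpec(var_a=spec.var_a, var_e=spec.var_e,
                                   mean=spec.mean + 2.0)
        rejections = 0
        for rep in range(10):
            mz = tv.simulate_pairs("MZ", 2000, spec, seed=600 + rep)
            dz = tv.simulate_pairs("DZ", 2000, shifted, seed=700 + rep)
            res = tv.test_equal_means_variances(mz, dz)
            rejections += res.p_value < 0.05
        assert rejections == 10

    def test_degenerate_variance_rejected(self):
        flat = tv.io.make_pair_frame("MZ", ["a", "c"], ["b", "d"],
                                     [21.0, 21.0], [21.0, 21.0],
                                     [1970, 1970], [1970, 1970])
        with pytest.raises(tv.DataError):
            tv.test_equal_means_variances(flat, flat)
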