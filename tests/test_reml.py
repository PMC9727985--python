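"""REML engine: dense-oracle equality, closed forms, and invariances."""

import warnings

import numpy as np
import pytest

from grtmix import (
    DesignConfig,
    FixedEffects,
    VarianceComponents,
    simulate_rc,
    simulate_rm,
)
from grtmix.models import AnalyticModelName, ModelSpec, RandomTerm, make_spec
from grtmix.reml import (
    DesignError,
    build_matrices,
    fixed_effects_design,
    group_mean_reduce,
    marginal_covariance,
    reml_fit,
)
from grtmix.inference import kr_adjust

from _oracles import (
    dense_covariance,
    dense_gls_beta,
    dense_reml_loglik,
    oneway_anova_components,
)


def small_data(struct, mechanism, seed, g=3, m=4, t=3):
    d = DesignConfig(groups_per_condition=g, members_per_group=m, n_periods=t, structure=struct)
    if mechanism == "rm":
        vc = VarianceComponents(1, 1, 2 if struct == "cohort" else 0, 0, 3,
                                mechanism="rm", structure=struct)
        return simulate_rm(d, FixedEffects.null(), vc, seed), d
    vc = VarianceComponents(1, 0.8, 4 if struct == "cohort" else 0,
                            0.5 if struct == "cohort" else 0, 3,
                            mechanism="rc", structure=struct)
    return simulate_rc(d, FixedEffects.null(), vc, seed), d


ORACLE_CASES = [
    ("rm_vc", True, "cross-sectional", "rm"),
    ("rm_vc", False, "cross-sectional", "rm"),
    ("rc", True, "cross-sectional", "rc"),
    ("saturated", True, "cross-sectional", "rm"),
    ("rm_un", True, "cross-sectional", "rm"),
    ("rm_vc", True, "cohort", "rm"),
    ("rm_un", True, "cohort", "rm"),
    ("rm_un", False, "cohort", "rm"),
    ("rc", True, "cohort", "rc"),
    ("rc", False, "cohort", "rc"),
    ("saturated", True, "cohort", "rc"),
]


class TestDenseOracle:
    @pytest.mark.parametrize("fam,tg,struct,mech", ORACLE_CASES)
    def test_loglik_matches_dense_mvn_oracle(self, fam, tg, struct, mech):
        """Engine REML loglik equals a brute-force dense computation at theta-hat."""
        ds, d = small_data(struct, mech, seed=[3, hash((fam, tg, struct)) % 1000])
        spec = make_spec(AnalyticModelName(fam, tg, struct), n_periods=3,
                         force_individual=True)
        fit = reml_fit(ds, spec)
        assert fit.converged, fit.message
        ll = dense_reml_loglik(ds.frame, spec.time_coding, spec.terms,
                               fit.theta_names, fit.theta, spec.has_residual)
        assert fit.reml_loglik == pytest.approx(ll, abs=1e-6)

    @pytest.mark.parametrize("fam,tg,struct,mech", ORACLE_CASES[:4])
    def test_marginal_covariance_matches_pairwise_rules(self, fam, tg, struct, mech):
        ds, d = small_data(struct, mech, seed=11)
        spec = make_spec(AnalyticModelName(fam, tg, struct), n_periods=3,
                         force_individual=True)
        dm = build_matrices(d, spec)
        theta = 0.5 + np.arange(dm.k) / 10.0
        Vblock = marginal_covariance(spec, d, theta)
        # oracle covariance for the rows of the first group
        f = ds.frame
        first = f[f.group_id == f.group_id.iloc[0]]
        if struct == "cohort":
            first = first.sort_values(["member_id", "period"])
        else:
            # member-major layout pairs each pseudo-member slot across periods
            first = first.sort_values(["period", "member_id"])
            order = np.arange(len(first)).reshape(3, d.members_per_group).T.reshape(-1)
            first = first.iloc[order]
        Vo = dense_covariance(first, spec.terms, dm.params and [p.name for p in dm.params],
                              theta, spec.has_residual)
        assert np.allclose(Vblock, Vo, atol=1e-12)

    @pytest.mark.parametrize("fam,tg,struct,mech", ORACLE_CASES[::3])
    def test_gls_beta_recovered_independently(self, fam, tg, struct, mech):
        ds, _ = small_data(struct, mech, seed=29)
        spec = make_spec(AnalyticModelName(fam, tg, struct), n_periods=3,
                         force_individual=True)
        fit = reml_fit(ds, spec)
        assert fit.converged
        beta = dense_gls_beta(ds.frame, spec.time_coding, spec.terms,
                              fit.theta_names, fit.theta, spec.has_residual)
        assert np.allclose(fit.beta, beta, atol=1e-8)

    @pytest.mark.parametrize("fam,tg,struct,mech", ORACLE_CASES[::2])
    def test_optimum_dominates_perturbed_points(self, fam, tg, struct, mech):
        ds, _ = small_data(struct, mech, seed=31, g=4)
        spec = make_spec(AnalyticModelName(fam, tg, struct), n_periods=3,
                         force_individual=True)
        fit = reml_fit(ds, spec)
        assert fit.converged
        rng = np.random.default_rng(0)
        scale = np.maximum(np.abs(fit.theta), 0.05)
        hits = 0
        for _ in range(25):
            pert = fit.theta + rng.normal(0, 0.15, fit.theta.shape) * scale
            ll = dense_reml_loglik(ds.frame, spec.time_coding, spec.terms,
                                   fit.theta_names, pert, spec.has_residual)
            if np.isfinite(ll):
                hits += 1
                assert fit.reml_loglik >= ll - 1e-9
        assert hits >= 5


class TestClosedForms:
    def test_one_way_anova_estimators(self):
        """Single-period balanced design: REML equals the MSB/MSW closed forms."""
        d = DesignConfig(groups_per_condition=6, members_per_group=8, n_periods=1)
        vc = VarianceComponents(2, 0, 0, 0, 5, mechanism="rm")
        ds = simulate_rm(d, FixedEffects.null(), vc, 37)
        spec = ModelSpec(name="oneway", time_coding="categorical",
                         structure="cross-sectional",
                         terms=(RandomTerm("group", "intercept"),), has_residual=True)
        fit = reml_fit(ds, spec)
        assert fit.converged
        s2g, s2e, _ = oneway_anova_components(ds.frame, d.members_per_group)
        got = fit.theta_series()
        assert got["sigma2_g"] == pytest.approx(s2g, rel=1e-8)
        assert got["sigma2_e"] == pytest.approx(s2e, rel=1e-8)

    def test_residual_only_model_is_ols(self):
        ds, d = small_data("cross-sectional", "rm", seed=41)
        spec = ModelSpec(name="ols", time_coding="categorical",
                         structure="cross-sectional", terms=(), has_residual=True)
        fit = reml_fit(ds, spec)
        assert fit.converged
        from _oracles import dense_design

        X = dense_design(ds.frame, "categorical")
        y = ds.frame["y"].to_numpy()
        beta, rss, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        s2 = resid @ resid / (len(y) - X.shape[1])
        assert fit.theta_series()["sigma2_e"] == pytest.approx(s2, rel=1e-10)
        assert np.allclose(fit.beta, beta, atol=1e-10)

    def test_statsmodels_random_intercept_cross_check(self):
        import statsmodels.api as sm
        from _oracles import dense_design

        ds, d = small_data("cross-sectional", "rm", seed=43, g=6, m=5)
        spec = make_spec(AnalyticModelName("rm_vc", False, "cross-sectional"), n_periods=3)
        fit = reml_fit(ds, spec)
        X = dense_design(ds.frame, "categorical")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mf = sm.MixedLM(ds.frame["y"].to_numpy(), X,
                            groups=ds.frame["group_id"].to_numpy()).fit(reml=True)
        assert fit.reml_loglik == pytest.approx(float(mf.llf), abs=1e-5)
        assert fit.theta_series()["sigma2_g"] == pytest.approx(
            float(np.asarray(mf.cov_re)[0, 0]), abs=1e-3)
        assert fit.theta_series()["sigma2_e"] == pytest.approx(float(mf.scale), abs=1e-3)


class TestInvariances:
    def test_shift_invariance(self):
        ds, _ = small_data("cohort", "rm", seed=47)
        spec = make_spec(AnalyticModelName("rm_vc", True, "cohort"), n_periods=3)
        fit1 = reml_fit(ds, spec)
        shifted = ds.frame.copy()
        shifted["y"] += 100.0
        from grtmix import TrialDataset

        fit2 = reml_fit(TrialDataset.from_frame(shifted), spec)
        assert np.allclose(fit1.theta, fit2.theta, atol=1e-8)
        assert fit2.beta[0] == pytest.approx(fit1.beta[0] + 100.0, abs=1e-7)
        assert np.allclose(fit1.beta[1:], fit2.beta[1:], atol=1e-7)

    def test_nobound_produces_negative_estimates_under_null_component(self):
        """With sigma2_tg = 0 in truth, unconstrained estimates straddle zero."""
        d = DesignConfig(groups_per_condition=6, members_per_group=6, n_periods=3)
        vc = VarianceComponents(1, 0, 0, 0, 4, mechanism="rm")
        spec = make_spec(AnalyticModelName("rm_vc", True, "cross-sectional"), n_periods=3)
        dm = build_matrices(d, spec)
        est = []
        for r in range(40):
            ds = simulate_rm(d, FixedEffects.null(), vc, [53, r])
            fit = dm.fit_dataset(ds)
            if fit.converged:
                est.append(fit.theta_series()["sigma2_tg"])
        est = np.asarray(est)
        assert (est < 0).any() and (est > 0).any()
        flagged = dm.fit_dataset(simulate_rm(d, FixedEffects.null(), vc,
                                             [53, int(np.argmin(est))]))
        assert flagged.boundary_note == bool((flagged.theta[flagged.variance_flags] < 0).any())

    def test_degenerate_constant_outcome_fails_gracefully(self):
        d = DesignConfig(groups_per_condition=3, members_per_group=4, n_periods=3)
        vc = VarianceComponents(0, 0, 0, 0, 0, mechanism="rm")
        ds = simulate_rm(d, FixedEffects.null(), vc, 1)
        fit = reml_fit(ds, make_spec(AnalyticModelName("rm_vc", True, "cross-sectional"),
                                     n_periods=3))
        assert not fit.converged
        assert fit.message


class TestGroupMeanReduction:
    def test_constant_outcomes_reduce_to_constant(self):
        d = DesignConfig(groups_per_condition=2, members_per_group=3, n_periods=2)
        ds = simulate_rm(d, FixedEffects(mu=7.0), VarianceComponents(0, 0, 0, 0, 0), 1)
        red = group_mean_reduce(ds)
        assert np.allclose(red.frame["y"], 7.0)
        assert len(red) == d.n_groups_total * d.n_periods

    @pytest.mark.parametrize("fam", ["saturated", "rm_un"])
    def test_mean_level_equals_individual_level_p_values(self, fam):
        """The group-mean formulation reproduces individual-level KR p-values."""
        d = DesignConfig(groups_per_condition=6, members_per_group=10, n_periods=4)
        vc = VarianceComponents(1, 1, 0, 0, 18, mechanism="rm")
        name = AnalyticModelName(fam, True, "cross-sectional")
        for r in range(3):
            ds = simulate_rm(d, FixedEffects.null(), vc, [59, r])
            f_mean = reml_fit(ds, make_spec(name, n_periods=4))
            f_ind = reml_fit(ds, make_spec(name, n_periods=4, force_individual=True))
            assert f_mean.converged and f_ind.converged
            t_mean, t_ind = kr_adjust(f_mean), kr_adjust(f_ind)
            assert t_mean.p_value == pytest.approx(t_ind.p_value, abs=1e-8)
            assert t_mean.ddf == pytest.approx(t_ind.ddf, abs=1e-6)


class TestBuildMatrices:
    def test_fixed_effect_counts(self):
        d = DesignConfig(groups_per_condition=4, members_per_group=5, n_periods=5)
        Xs, names, within, inter = fixed_effects_design(d, "categorical")
        assert len(names) == 1 + 1 + 4 + 4
        assert len(inter) == 4
        Xs, names, within, inter = fixed_effects_design(d, "linear")
        assert len(names) == 4 and len(inter) == 1

    def test_rank_deficient_design_reports_aliased_columns(self):
        # a single period makes the linear time column identically zero
        d = DesignConfig(groups_per_condition=3, members_per_group=4, n_periods=1)
        with pytest.raises(DesignError, match="time"):
            fixed_effects_design(d, "linear")
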