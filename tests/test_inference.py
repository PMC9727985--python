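"""Small-sample tests: KR against exact cases and pbkrtest, BW bookkeeping."""

import json
import subprocess

import numpy as np
import pytest
from scipy import integrate, stats

from grtmix import (
    DesignConfig,
    FixedEffects,
    VarianceComponents,
    simulate_rm,
    write_trial_csv,
)
from grtmix.inference import bw_df, kr_adjust
from grtmix.inference import TestUnavailable as Unavailable
from grtmix.inference import test_interaction as interaction_test
from grtmix.models import AnalyticModelName, ModelSpec, RandomTerm, make_spec
from grtmix.reml import build_matrices, reml_fit

from _oracles import oneway_anova_f


def rm_data(seed, g=4, m=6, t=3, s2=(1, 1, 0, 0, 4), struct="cross-sectional"):
    d = DesignConfig(groups_per_condition=g, members_per_group=m, n_periods=t, structure=struct)
    vc = VarianceComponents(*s2, mechanism="rm", structure=struct)
    return simulate_rm(d, FixedEffects.null(), vc, seed), d


class TestKnownExactCases:
    def test_ols_limit(self):
        """Residual-only model: the KR adjustment vanishes, ddf = n - rank(X)."""
        ds, d = rm_data(seed=61)
        spec = ModelSpec(name="ols", time_coding="categorical",
                         structure="cross-sectional", terms=(), has_residual=True)
        fit = reml_fit(ds, spec)
        t = kr_adjust(fit)
        assert t.ddf == pytest.approx(fit.n_obs - fit.rank_x, abs=1e-8)
        assert np.allclose(fit.beta_cov_adjusted, fit.beta_cov, rtol=1e-10)

    def test_one_period_grt_reproduces_exact_nested_anova(self):
        """Balanced one-period GRT with random intercepts: KR F-test for the
        condition effect equals the exact nested ANOVA F with ddf = c*g - 2."""
        d = DesignConfig(groups_per_condition=7, members_per_group=9, n_periods=1)
        vc = VarianceComponents(1.5, 0, 0, 0, 4, mechanism="rm")
        ds = simulate_rm(d, FixedEffects.null(), vc, 67)
        spec = ModelSpec(name="oneway", time_coding="categorical",
                         structure="cross-sectional",
                         terms=(RandomTerm("group", "intercept"),), has_residual=True)
        fit = reml_fit(ds, spec)
        L = np.zeros((1, 2))
        L[0, 1] = 1.0  # condition effect
        t = kr_adjust(fit, contrast=L)
        f_exact, ddf_exact = oneway_anova_f(ds.frame)
        assert t.ddf == pytest.approx(ddf_exact, abs=1e-6)
        assert t.f_stat == pytest.approx(f_exact, rel=1e-6)


class TestAgainstPbkrtest:
    def test_kr_matches_r_oracle(self, tmp_path):
        """F, ddf and p agree with the independent pbkrtest implementation."""
        ds, d = rm_data(seed=42)
        csv = tmp_path / "d.csv"
        write_trial_csv(ds, csv)
        spec = make_spec(AnalyticModelName("rm_vc", True, "cross-sectional"), n_periods=3)
        fit = reml_fit(ds, spec)
        t = kr_adjust(fit)
        rscript = f"""
        suppressMessages({{library(lme4); library(pbkrtest)}})
        d <- read.csv("{csv}")
        d$period <- factor(d$period); d$condition <- factor(d$condition)
        full <- lmer(y ~ condition*period + (1|group_id) + (1|group_id:period), data=d, REML=TRUE)
        red  <- lmer(y ~ condition+period + (1|group_id) + (1|group_id:period), data=d, REML=TRUE)
        kr <- KRmodcomp(full, red)$stats
        cat(sprintf('{{"F": %.10f, "ddf": %.10f, "p": %.10f, "ll": %.10f}}',
                    kr$Fstat, kr$ddf, kr$p.value, as.numeric(logLik(full))))
        """
        out = subprocess.run(["Rscript", "-e", rscript], capture_output=True, text=True,
                             timeout=300)
        assert out.returncode == 0, out.stderr
        ref = json.loads(out.stdout.strip().splitlines()[-1])
        assert fit.reml_loglik == pytest.approx(ref["ll"], abs=1e-4)
        assert t.f_stat == pytest.approx(ref["F"], rel=1e-4)
        assert t.ddf == pytest.approx(ref["ddf"], abs=1e-3)
        assert t.p_value == pytest.approx(ref["p"], abs=1e-5)


class TestBetweenWithin:
    def test_df_bookkeeping(self):
        ds, d = rm_data(seed=71, g=10, m=40, t=5)
        spec = make_spec(AnalyticModelName("rm_vc", True, "cross-sectional"), n_periods=5)
        fit = reml_fit(ds, spec)
        t = bw_df(fit)
        # interaction varies within groups: n - G - within columns
        assert t.ndf == 4
        assert t.ddf == fit.n_obs - 20 - 8
        L = np.zeros((1, len(fit.beta_names)))
        L[0, 1] = 1.0  # condition: a between-group effect
        tb = bw_df(fit, contrast=L)
        assert tb.ddf == 2 * 10 - 2

    def test_linear_coding_ndf(self):
        d = DesignConfig(groups_per_condition=4, members_per_group=5, n_periods=3)
        vc = VarianceComponents(1, 0.5, 0, 0, 3, mechanism="rc")
        from grtmix import simulate_rc

        ds = simulate_rc(d, FixedEffects.null(), vc, 73)
        fit = reml_fit(ds, make_spec(AnalyticModelName("rc", True, "cross-sectional"),
                                     n_periods=3))
        assert bw_df(fit).ndf == 1
        assert kr_adjust(fit).ndf == 1

    def test_unconverged_fit_raises_test_unavailable(self):
        d = DesignConfig(groups_per_condition=3, members_per_group=4, n_periods=3)
        ds = simulate_rm(d, FixedEffects.null(), VarianceComponents(0, 0, 0, 0, 0), 1)
        fit = reml_fit(ds, make_spec(AnalyticModelName("rm_vc", True, "cross-sectional"),
                                     n_periods=3))
        with pytest.raises(Unavailable):
            interaction_test(fit, "KR")
        with pytest.raises(Unavailable):
            bw_df(fit)


class TestProperties:
    def test_p_value_is_upper_tail_of_f(self):
        """p equals the integrated F density on random (F, ndf, ddf) triples."""
        rng = np.random.default_rng(5)
        for _ in range(60):
            q = int(rng.integers(1, 6))
            ddf = float(rng.uniform(2.5, 60))
            f = float(rng.uniform(0.05, 6))
            dens = lambda x: stats.f.pdf(x, q, ddf)
            tail, _ = integrate.quad(dens, f, np.inf)
            assert stats.f.sf(f, q, ddf) == pytest.approx(tail, abs=1e-7)

    def test_kr_ddf_decreases_with_fewer_groups(self):
        spec_name = AnalyticModelName("rm_vc", True, "cross-sectional")
        for r in range(3):
            ddfs = {}
            for g in (10, 20):
                ds, d = rm_data(seed=[79, r], g=g, m=10, t=5, s2=(1, 1, 0, 0, 18))
                fit = reml_fit(ds, make_spec(spec_name, n_periods=5))
                ddfs[g] = kr_adjust(fit).ddf
            assert ddfs[10] < ddfs[20]

    def test_kr_never_exceeds_ols_limit(self):
        for r in range(4):
            ds, d = rm_data(seed=[83, r])
            fit = reml_fit(ds, make_spec(AnalyticModelName("rm_vc", True, "cross-sectional"),
                                         n_periods=3))
            t = kr_adjust(fit)
            assert t.ddf <= fit.n_obs - fit.rank_x + 1e-9

    def test_kr_and_bw_agree_for_many_groups(self):
        """With 200 groups per condition the small-sample correction is negligible."""
        ds, d = rm_data(seed=89, g=200, m=5, t=3, s2=(1, 1, 0, 0, 8))
        fit = reml_fit(ds, make_spec(AnalyticModelName("rm_vc", True, "cross-sectional"),
                                     n_periods=3))
        pk = kr_adjust(fit).p_value
        pb = bw_df(fit).p_value
        assert pk == pytest.approx(pb, abs=0.01)

    def test_kr1_equals_kr2_for_linear_structures(self):
        ds, _ = rm_data(seed=97)
        fit = reml_fit(ds, make_spec(AnalyticModelName("rm_vc", True, "cross-sectional"),
                                     n_periods=3))
        t1, t2 = kr_adjust(fit, method="kr1"), kr_adjust(fit, method="kr2")
        assert t1.p_value == t2.p_value and t1.ddf == t2.ddf
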