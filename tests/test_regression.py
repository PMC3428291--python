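"""Net-affect regression: OLS fit, nested F, interaction pruning."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from drmkit.cohort import CohortConfig, generate_study
from drmkit.core import DRMError
from drmkit.pipeline import score_study
from drmkit.regression import (
    DesignSpec,
    build_design_matrix,
    default_interactions,
    fit_linear_model,
    nested_f_test,
    prune_to_final_model,
)

from oracles import rss_f_oracle


def synthetic_frame(rng, n=400, beta=None, noise=0.0):
    data = pd.DataFrame({
        "education01": rng.integers(0, 2, n),
        "setting01": rng.integers(0, 2, n),
        "income01": rng.integers(0, 2, n),
        "sex": rng.integers(0, 2, n),
        "age": rng.integers(18, 90, n).astype(float),
    })
    beta = beta or {}
    y = np.full(n, beta.get("const", 0.5))
    for term, b in beta.items():
        if term == "const":
            continue
        if ":" in term:
            a, c = term.split(":")
            y = y + b * data[a] * data[c]
        else:
            y = y + b * data[term]
    data["net"] = y + noise * rng.normal(size=n)
    return data


def cohort_frame(n, seed, **cfg_kw):
    cfg = CohortConfig(n_respondents=n, seed=seed, dropout_rate=0.0, **cfg_kw)
    sim = generate_study(cfg, waves=("test",))
    scores = score_study(sim.study).query("wave == 'test'")[["respondent_id", "net"]]
    return scores.merge(sim.study.respondents, on="respondent_id")


class TestFit:
    def test_noiseless_recovery_is_exact(self, rng):
        beta = {"const": 0.4, "education01": 0.3, "setting01": -0.2, "income01": 0.25,
                "sex": 0.1, "age": -0.002, "education01:sex": -0.15}
        data = synthetic_frame(rng, beta=beta)
        fit = fit_linear_model(DesignSpec(), data)
        for term, b in beta.items():
            assert fit.params[term] == pytest.approx(b, abs=1e-10)
        for term in fit.terms:
            if term not in beta:
                assert fit.params[term] == pytest.approx(0.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0)

    def test_residual_orthogonality(self, rng):
        data = synthetic_frame(rng, beta={"education01": 0.3}, noise=0.5)
        fit = fit_linear_model(DesignSpec(), data)
        assert np.abs(fit.exog.T @ fit.resid).max() < 1e-8

    def test_rank_deficient_names_aliased_term(self, rng):
        data = synthetic_frame(rng, noise=0.5)
        data["income01"] = data["education01"]  # perfectly aliased
        with pytest.raises(DRMError, match="income01"):
            fit_linear_model(DesignSpec(), data)

    def test_recode_equivariance(self, rng):
        """Flipping a 0/1 coding flips the slope and leaves fit unchanged."""
        data = synthetic_frame(rng, beta={"education01": 0.3, "sex": 0.2}, noise=0.4)
        design = DesignSpec(interactions=())
        fit = fit_linear_model(design, data)
        flipped = data.assign(education01=1 - data["education01"])
        fit2 = fit_linear_model(design, flipped)
        assert fit2.params["education01"] == pytest.approx(-fit.params["education01"])
        assert fit2.rss == pytest.approx(fit.rss)
        assert fit2.params["const"] == pytest.approx(
            fit.params["const"] + fit.params["education01"]
        )

    def test_agrees_with_statsmodels_f(self, rng):
        data = synthetic_frame(rng, beta={"income01": 0.3}, noise=0.6)
        fit = fit_linear_model(DesignSpec(), data)
        X, y = build_design_matrix(DesignSpec(), data)
        ref = sm.OLS(y, X).fit()
        assert fit.f_statistic == pytest.approx(float(ref.fvalue))
        assert fit.adj_r_squared == pytest.approx(float(ref.rsquared_adj))


class TestNestedF:
    def test_identical_models(self, rng):
        data = synthetic_frame(rng, beta={"sex": 0.2}, noise=0.4)
        fit = fit_linear_model(DesignSpec(), data)
        res = nested_f_test(fit, fit)
        assert res.f == 0.0 and res.p == 1.0

    def test_matches_hand_rss_formula(self, rng):
        data = synthetic_frame(rng, n=80, beta={"sex": 0.2, "income01:sex": 0.3}, noise=0.5)
        design = DesignSpec()
        full = fit_linear_model(design, data)
        reduced = fit_linear_model(design.reduced(), data)
        res = nested_f_test(full, reduced)
        X_full, y = build_design_matrix(design, data)
        X_red, _ = build_design_matrix(design.reduced(), data)
        f_o, df1_o, df2_o = rss_f_oracle(y, X_full, X_red)
        assert res.f == pytest.approx(f_o, rel=1e-9)
        assert (res.df1, res.df2) == (df1_o, df2_o)

    def test_matches_anova_lm(self, rng):
        from statsmodels.stats.anova import anova_lm
        data = synthetic_frame(rng, n=120, beta={"sex": 0.2}, noise=0.5)
        design = DesignSpec()
        X_full, y = build_design_matrix(design, data)
        X_red, _ = build_design_matrix(design.reduced(), data)
        table = anova_lm(sm.OLS(y, X_red).fit(), sm.OLS(y, X_full).fit())
        res = nested_f_test(fit_linear_model(design, data),
                            fit_linear_model(design.reduced(), data))
        assert res.f == pytest.approx(float(table["F"].iloc[1]))
        assert res.p == pytest.approx(float(table["Pr(>F)"].iloc[1]))

    def test_non_nested_rejected(self, rng):
        data = synthetic_frame(rng, noise=0.5)
        a = fit_linear_model(DesignSpec(interactions=(("education01", "sex"),)), data)
        b = fit_linear_model(DesignSpec(interactions=(("income01", "sex"),)), data)
        with pytest.raises(DRMError, match="nested"):
            nested_f_test(a, b)

    def test_permutation_calibration(self, rng):
        """Overall F p-values are uniform when the response is permuted."""
        data = cohort_frame(300, seed=77)
        pvals = []
        for _ in range(150):
            shuffled = data.assign(net=rng.permutation(data["net"].to_numpy()))
            pvals.append(fit_linear_model(DesignSpec(), shuffled).f_pvalue)
        pvals = np.array(pvals)
        assert 0.42 <= pvals.mean() <= 0.58
        assert (pvals < 0.1).mean() == pytest.approx(0.1, abs=0.08)


class TestPruning:
    def test_none_significant_leaves_main_effects(self, rng):
        data = synthetic_frame(rng, n=300, beta={"sex": 0.3}, noise=1.0)
        fit = fit_linear_model(DesignSpec(), data)
        final = prune_to_final_model(fit)
        # main effects and covariates always retained
        assert set(final.main_effects) == {"education01", "setting01", "income01"}
        assert set(final.covariates) == {"sex", "age"}
        retained = {f"{a}:{b}" for a, b in final.interactions}
        significant = {f"{a}:{b}" for a, b in default_interactions()
                       if fit.pvalues[f"{a}:{b}"] < 0.05}
        assert retained == significant

    def test_all_significant_keeps_initial(self, rng):
        beta = {f"{a}:{b}": 1.0 for a, b in default_interactions()}
        beta.update(sex=0.2)
        data = synthetic_frame(rng, n=500, beta=beta, noise=0.05)
        fit = fit_linear_model(DesignSpec(), data)
        final = prune_to_final_model(fit)
        assert set(final.interactions) == set(default_interactions())

    def test_true_interactions_retained(self):
        """Generator defaults carry education x sex and income x sex
        effects; a single pruning pass keeps them nearly always."""
        reps, both = 100, 0
        for r in range(reps):
            data = cohort_frame(2000, seed=30_000 + r)
            fit = fit_linear_model(DesignSpec(), data)
            kept = {f"{a}:{b}" for a, b in prune_to_final_model(fit).interactions}
            both += {"education01:sex", "income01:sex"} <= kept
        assert both / reps >= 0.90


def test_single_cohort_estimates_near_large_n_truth():
    """One n=4000 fit lands within 4 sampling SDs of the large-n plim."""
    truth = fit_linear_model(DesignSpec(), cohort_frame(120_000, seed=991)).params
    fit = fit_linear_model(DesignSpec(), cohort_frame(4000, seed=17))
    z = (fit.params - truth) / fit.bse
    assert np.abs(z).max() < 4.0
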