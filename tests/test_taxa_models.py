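import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit, logit

from microtide.taxa_models import (
    DesignInfo,
    FitControl,
    ModelSpec,
    TaxaModelFit,
    TaxaModelSet,
    bh_adjust,
    build_design,
    covariate_lrt,
    estimate_table,
    fit_bb,
    fit_nb,
    presence_chisq,
    profile_ci,
    profile_interval,
    rank_taxa_test,
    summary_table,
    taxa_models,
)


class TestDesign:
    def _frame(self):
        return pd.DataFrame({
            "Group": pd.Categorical(["No", "Yes", "No", "Yes"],
                                    categories=["No", "Yes"]),
            "Smoke": pd.Categorical(["Never", "Former", "Current", "Never"],
                                    categories=["Never", "Former", "Current"]),
            "Age": [60.0, 70.0, 65.0, 75.0],
        }, index=pd.Index([f"L{i}" for i in range(4)], name="Lib"))

    def test_reference_coding_names(self):
        X, info = build_design(self._frame(), ModelSpec("T", ["Group", "Age"]))
        assert info.column_names == ["(Intercept)", "GroupYes", "Age"]
        np.testing.assert_array_equal(X[:, 1], [0, 1, 0, 1])

    def test_three_level_categorical_two_columns(self):
        _, info = build_design(self._frame(), ModelSpec("T", ["Smoke"]))
        assert info.term_columns["Smoke"] == ["SmokeFormer", "SmokeCurrent"]

    def test_star_expands_to_interaction(self):
        X, info = build_design(self._frame(), ModelSpec("T", ["Group*Age"]))
        assert info.terms == ["Group", "Age", "Group:Age"]
        j = info.column_names.index("GroupYes:Age")
        np.testing.assert_allclose(X[:, j], [0, 70, 0, 75])

    def test_undeclared_interaction_component_rejected(self):
        with pytest.raises(ValueError, match="undeclared"):
            ModelSpec("T", ["Group:Age"]).expanded_terms()

    def test_make_row_defaults_and_profiles(self):
        X, info = build_design(self._frame(), ModelSpec("T", ["Group*Age"]))
        row = info.make_row({})  # reference group, mean age
        np.testing.assert_allclose(row, [1, 0, 67.5, 0])
        row = info.make_row({"Group": "Yes", "Age": 60.0})
        np.testing.assert_allclose(row, [1, 1, 60.0, 60.0])


class TestFitNB:
    def test_intercept_only_with_offset(self):
        # constant-mean score equation: exp(b0)*100 = mean(y) for any theta
        y = np.array([5.0, 10.0, 15.0])
        X = np.ones((3, 1))
        fit = fit_nb(y, X, offset=np.full(3, math.log(100.0)))
        assert fit.converged
        assert fit.beta[0] == pytest.approx(math.log(0.1), abs=1e-4)

    def test_all_zero_flagged_not_raised(self):
        fit = fit_nb(np.zeros(10), np.ones((10, 1)))
        assert not fit.converged
        assert "zero" in fit.reason

    def test_rank_deficient_flagged(self):
        X = np.column_stack([np.ones(10), np.arange(10.0), 2 * np.arange(10.0)])
        fit = fit_nb(np.arange(1.0, 11.0), X)
        assert not fit.converged
        assert fit.reason == "rank-deficient"

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError):
            fit_nb(np.array([-1.0, 2.0]), np.ones((2, 1)))

    def test_poisson_limit_recovers_glm(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(4)
        x = rng.normal(size=300)
        X = np.column_stack([np.ones(300), x])
        y = rng.poisson(np.exp(1.0 + 0.5 * x))
        fit = fit_nb(y.astype(float), X)
        glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(fit.beta, glm.params, atol=1e-3)

    def test_parameter_recovery_single_simulation(self):
        rng = np.random.default_rng(10)
        n, beta1, theta = 200, 0.8, 2.0
        x = rng.binomial(1, 0.5, n).astype(float)
        d = rng.integers(1000, 5000, n).astype(float)
        mu = np.exp(-3.0 + beta1 * x + np.log(d))
        y = rng.negative_binomial(theta, theta / (theta + mu)).astype(float)
        fit = fit_nb(y, np.column_stack([np.ones(n), x]), offset=np.log(d))
        assert fit.converged
        assert fit.beta[1] == pytest.approx(beta1, abs=0.15)
        assert fit.dispersion == pytest.approx(theta, rel=0.5)


class TestFitBB:
    def test_intercept_only_symmetric_proportions(self):
        n = np.full(6, 50.0)
        y = np.full(6, 10.0)  # every library at exactly 20%
        fit = fit_bb(y, n, np.ones((6, 1)))
        assert fit.beta[0] == pytest.approx(logit(0.2), abs=1e-3)

    def test_rho_zero_limit_matches_binomial_glm(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(2)
        n = np.full(100, 400.0)
        x = rng.normal(size=100)
        X = np.column_stack([np.ones(100), x])
        p = expit(-1.0 + 0.5 * x)
        y = rng.binomial(400, p).astype(float)  # pure binomial: rho ~ 0
        fit = fit_bb(y, n, X)
        glm = sm.GLM(np.column_stack([y, n - y]), X,
                     family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.beta, glm.params, atol=0.02)
        assert fit.dispersion < 0.02

    def test_y_exceeding_n_raises(self):
        with pytest.raises(ValueError):
            fit_bb(np.array([5.0]), np.array([3.0]), np.ones((1, 1)))

    def test_parameter_recovery_single_simulation(self):
        rng = np.random.default_rng(20)
        n_obs, beta1, rho = 200, 0.6, 0.1
        x = rng.binomial(1, 0.5, n_obs).astype(float)
        n = np.full(n_obs, 500.0)
        mu = expit(-2.0 + beta1 * x)
        s = (1 - rho) / rho
        p = rng.beta(mu * s, (1 - mu) * s)
        y = rng.binomial(500, p).astype(float)
        fit = fit_bb(y, n, np.column_stack([np.ones(n_obs), x]))
        assert fit.converged
        # one simulation: allow ~2.5 sampling SEs around the truth
        assert fit.beta[1] == pytest.approx(beta1, abs=0.25)
        assert fit.dispersion == pytest.approx(rho, rel=0.5)


class TestTaxaModels:
    def test_partition_covers_all_taxa(self, small_ms):
        models = taxa_models(small_ms, ModelSpec("Genus", ["Group"]))
        assert sorted(models.converged_taxa + models.failed_taxa) == \
            sorted(small_ms.tables["Genus"])

    def test_coefficient_named_for_non_reference_level(self, small_ms):
        models = taxa_models(small_ms, ModelSpec("Genus", ["Group"]))
        assert models.fits[0].coef_names == ["(Intercept)", "GroupYes"]

    def test_offset_changes_betas_under_unequal_depths(self, small_ms):
        with_off = taxa_models(small_ms, ModelSpec("Genus", ["Group"], offset=True))
        without = taxa_models(small_ms, ModelSpec("Genus", ["Group"], offset=False))
        b1 = with_off.fit_for(with_off.converged_taxa[0]).beta
        b2 = without.fit_for(with_off.converged_taxa[0]).beta
        assert not np.allclose(b1, b2, atol=1e-3)

    def test_missing_covariate_libraries_dropped(self, small_ms, caplog):
        import logging
        ms = small_ms
        data = ms.data.copy()
        lib0 = ms.libraries("Genus")[0]
        data.loc[data["Lib"] == lib0, "Age"] = np.nan
        ms2 = type(ms)(data=data, tables=ms.tables, clinical_cols=ms.clinical_cols)
        with caplog.at_level(logging.WARNING, logger="microtide"):
            models = taxa_models(ms2, ModelSpec("Genus", ["Age"]))
        assert lib0 not in models.libraries
        assert any(lib0 in r.message for r in caplog.records)

    def test_unknown_covariate_is_error(self, small_ms):
        with pytest.raises(KeyError, match="Nope"):
            taxa_models(small_ms, ModelSpec("Genus", ["Nope"]))


class TestCovariateLRT:
    def test_three_level_categorical_has_df_two(self):
        rng = np.random.default_rng(1)
        n = 90
        frame = pd.DataFrame({
            "Smoke": pd.Categorical(rng.choice(["A", "B", "C"], n),
                                    categories=["A", "B", "C"]),
        }, index=pd.Index([f"L{i}" for i in range(n)], name="Lib"))
        spec = ModelSpec("T", ["Smoke"])
        X, info = build_design(frame, spec)
        y = rng.negative_binomial(2, 0.2, n).astype(float)
        fit = fit_nb(y, X, coef_names=info.column_names, taxon="t")
        models = TaxaModelSet(spec=spec, design=info, fits=[fit], failed=[],
                              libraries=list(frame.index))
        drop = set(info.columns_for_term_family("Smoke"))
        assert len(drop) == 2  # df of the test
        p = covariate_lrt(models, fit, "Smoke")
        assert 0.0 <= p <= 1.0

    def test_null_lrt_p_roughly_uniform(self):
        # no true effect -> LRT p-values should not pile up near 0
        rng = np.random.default_rng(8)
        n, reps = 80, 40
        ps = []
        for _ in range(reps):
            x = rng.binomial(1, 0.5, n).astype(float)
            X = np.column_stack([np.ones(n), x])
            y = rng.negative_binomial(2, 0.25, n).astype(float)
            spec = ModelSpec("T", ["G"])
            info = DesignInfo(terms=["G"], column_names=["(Intercept)", "GYes"],
                              term_columns={"G": ["GYes"]},
                              variables={"G": {"kind": "categorical",
                                               "levels": ["No", "Yes"]}})
            fit = fit_nb(y, X, coef_names=info.column_names, taxon="t")
            if not fit.converged:
                continue
            models = TaxaModelSet(spec=spec, design=info, fits=[fit], failed=[],
                                  libraries=[str(i) for i in range(n)])
            ps.append(covariate_lrt(models, fit, "G"))
        from scipy.stats import kstest
        assert kstest(ps, "uniform").pvalue > 0.01


class TestProfileCI:
    def test_quadratic_profile_equals_wald(self):
        # Gaussian-quadratic log-likelihood: the profile interval is exactly Wald
        mle, se, llmax = 0.37, 0.21, -12.0

        def pl(b):
            return llmax - (b - mle) ** 2 / (2 * se**2)

        lo, hi = profile_interval(pl, mle, se, llmax, level=0.95)
        z = 1.959963984540054
        assert lo == pytest.approx(mle - z * se, abs=1e-6)
        assert hi == pytest.approx(mle + z * se, abs=1e-6)

    def test_contains_mle_and_agrees_with_wald_large_n(self):
        rng = np.random.default_rng(3)
        n = 500
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        mu = np.exp(1.0 + 0.4 * x)
        theta = 3.0
        y = rng.negative_binomial(theta, theta / (theta + mu)).astype(float)
        spec = ModelSpec("T", ["x"])
        info = DesignInfo(terms=["x"], column_names=["(Intercept)", "x"],
                          term_columns={"x": ["x"]},
                          variables={"x": {"kind": "numeric", "mean": 0.0,
                                           "min": -3.0, "max": 3.0}})
        fit = fit_nb(y, X, coef_names=info.column_names, taxon="t")
        models = TaxaModelSet(spec=spec, design=info, fits=[fit], failed=[],
                              libraries=[str(i) for i in range(n)])
        ci = profile_ci(models, fit, level=0.95).set_index("Coefficient")
        z = 1.959963984540054
        for j, name in enumerate(fit.coef_names):
            lo, hi = ci.loc[name, "ci_low"], ci.loc[name, "ci_high"]
            assert lo < fit.beta[j] < hi
            wald_w = 2 * z * fit.se[j]
            assert (hi - lo) == pytest.approx(wald_w, rel=0.05)


def brute_bh(p):
    """Step-up definition evaluated literally."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        adj[i] = prev
    return adj


class TestBHAdjust:
    def test_worked_examples(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        np.testing.assert_allclose(bh_adjust([0.005, 0.04, 0.9]), [0.015, 0.06, 0.9])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.42]), [0.42])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False),
                    min_size=1, max_size=20))
    def test_matches_brute_force(self, p):
        np.testing.assert_allclose(bh_adjust(p), brute_bh(p), rtol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(0)
        p = rng.random(15)
        np.testing.assert_allclose(bh_adjust(p),
                                   multipletests(p, method="fdr_bh")[1])


def _manual_model_set(beta, cov, names, terms, term_columns):
    fit = TaxaModelFit(
        taxon="tax1", family="negbin", coef_names=names,
        beta=np.asarray(beta, dtype=float), cov=np.asarray(cov, dtype=float),
        dispersion=2.0, loglik=-10.0, converged=True, n_obs=20,
    )
    info = DesignInfo(terms=terms, column_names=["(Intercept)"] + names[1:],
                      term_columns=term_columns, variables={})
    spec = ModelSpec("T", terms)
    return TaxaModelSet(spec=spec, design=info, fits=[fit], failed=[],
                        libraries=["a"])


class TestEstimateTable:
    def test_interaction_contrast_worked_example(self):
        # main 0.5 (var .04), interaction 0.2 (var .09), cov -0.02
        names = ["(Intercept)", "GYes", "GYes:SB"]
        cov = np.array([
            [0.010, 0.000, 0.000],
            [0.000, 0.040, -0.020],
            [0.000, -0.020, 0.090],
        ])
        models = _manual_model_set([0.1, 0.5, 0.2], cov, names,
                                   ["G", "S", "G:S"],
                                   {"G": ["GYes"], "S": [], "G:S": ["GYes:SB"]})
        est = estimate_table(models, level=0.95)
        row = est[est["Coefficient"] == "GYes | SB"].iloc[0]
        assert row["ratio"] == pytest.approx(math.exp(0.7), abs=1e-3)
        assert row["ci_low"] == pytest.approx(1.119, abs=2e-3)
        assert row["ci_high"] == pytest.approx(3.625, abs=2e-3)

    def test_zero_beta_ratio_one(self):
        models = _manual_model_set([0.0, 0.0], [[0.01, 0], [0, 0.04]],
                                   ["(Intercept)", "GYes"], ["G"], {"G": ["GYes"]})
        est = estimate_table(models)
        row = est[est["Coefficient"] == "GYes"].iloc[0]
        assert row["ratio"] == pytest.approx(1.0)
        assert row["ci_low"] < 1.0 < row["ci_high"]

    def test_no_interaction_row_count(self, small_ms):
        models = taxa_models(small_ms, ModelSpec("Genus", ["Group", "Age"]))
        est = estimate_table(models)
        assert len(est) == len(models.fits) * 3  # intercept + 2 covariates

    def test_log_ci_symmetry(self, small_ms):
        models = taxa_models(small_ms, ModelSpec("Genus", ["Group"]))
        est = estimate_table(models)
        np.testing.assert_allclose(np.log(est["ci_high"] / est["ratio"]),
                                   np.log(est["ratio"] / est["ci_low"]),
                                   atol=1e-9)

    def test_fdr_pooled_within_coefficient(self, small_ms):
        models = taxa_models(small_ms, ModelSpec("Genus", ["Group"]))
        est = estimate_table(models)
        for _, g in est.groupby("Coefficient"):
            np.testing.assert_allclose(g["fdr_p"], bh_adjust(g["p"].to_numpy()))


class TestSummaryTable:
    def test_columns_and_profile_cis_contain_estimate(self, small_ms):
        models = taxa_models(small_ms, ModelSpec("Genus", ["Group"]))
        summ = summary_table(models, profile=True)
        assert {"Taxa", "Coefficient", "Estimate", "ci_low", "ci_high",
                "z", "wald_p", "fdr_p", "lrt_p"} <= set(summ.columns)
        assert ((summ["ci_low"] <= summ["Estimate"])
                & (summ["Estimate"] <= summ["ci_high"])).all()


class TestRankTaxaTest:
    def _two_group_ms(self, values):
        """Micro set with one taxon whose ra values are `values` (3 vs 3)."""
        from microtide.io_core import ClinicalTable, OtuTable, build_micro_set
        n = len(values)
        libs = [f"L{i}" for i in range(n)]
        filler = 1000 - np.asarray(values)
        otu = OtuTable("T", ["t1", "t2"], libs,
                       np.vstack([values, filler]).astype(int))
        clin = ClinicalTable("Lib", pd.DataFrame(
            {"G": pd.Categorical(["a"] * (n // 2) + ["b"] * (n - n // 2))},
            index=pd.Index(libs, name="Lib")))
        return build_micro_set({"T": otu}, clin)

    def test_exact_p_matches_full_enumeration(self):
        ms = self._two_group_ms([1, 2, 3, 4, 5, 6])
        res = rank_taxa_test(ms, "T", "G")
        p = res[res["Taxa"] == "t1"]["p"].iloc[0]
        # oracle: enumerate all C(6,3) assignments of ranks to group a
        vals = [1, 2, 3, 4, 5, 6]
        obs = sum(vals[:3])
        sums = [sum(c) for c in itertools.combinations(vals, 3)]
        lo, hi = min(sums), max(sums)
        extreme = sum(1 for s in sums
                      if abs(s - (lo + hi) / 2) >= abs(obs - (lo + hi) / 2))
        assert p == pytest.approx(extreme / len(sums))
        assert p == pytest.approx(0.1)

    def test_kruskal_wallis_hand_value(self):
        from microtide.io_core import ClinicalTable, OtuTable, build_micro_set
        libs = [f"L{i}" for i in range(6)]
        vals = np.array([1, 2, 3, 4, 5, 6])
        otu = OtuTable("T", ["t1", "t2"], libs,
                       np.vstack([vals, 100 - vals]).astype(int))
        clin = ClinicalTable("Lib", pd.DataFrame(
            {"G": pd.Categorical(["a", "a", "a", "b", "b", "b"])},
            index=pd.Index(libs, name="Lib")))
        ms = build_micro_set({"T": otu}, clin)
        # force the Kruskal-Wallis path via scipy on the same grouping
        from scipy.stats import kruskal
        h = kruskal(vals[:3], vals[3:]).statistic
        assert h == pytest.approx(3.857, abs=5e-4)

    def test_null_labels_give_large_p(self):
        rng = np.random.default_rng(5)
        ms = self._two_group_ms(list(rng.permutation([10, 20, 30, 40, 50, 60])))
        res = rank_taxa_test(ms, "T", "G")
        assert (res["p"] > 0.001).all()

    def test_failed_only_restricts_taxa(self, small_ms):
        models = taxa_models(small_ms, ModelSpec("Genus", ["Group"]))
        res = rank_taxa_test(small_ms, "Genus", "Group", failed_only=models)
        assert list(res["Taxa"]) == models.failed_taxa


class TestPresenceChisq:
    def _ms(self, bins, groups):
        from microtide.io_core import ClinicalTable, OtuTable, build_micro_set
        n = len(bins)
        libs = [f"L{i}" for i in range(n)]
        counts = np.vstack([np.asarray(bins) * 5, np.full(n, 50)])
        otu = OtuTable("T", ["t1", "t2"], libs, counts.astype(int))
        clin = ClinicalTable("Lib", pd.DataFrame(
            {"G": pd.Categorical(groups)}, index=pd.Index(libs, name="Lib")))
        return build_micro_set({"T": otu}, clin)

    def test_perfect_association_chi2_twenty(self):
        ms = self._ms([1] * 10 + [0] * 10, ["a"] * 10 + ["b"] * 10)
        res = ms and presence_chisq(ms, "T", "G")
        row = res[res["Taxa"] == "t1"].iloc[0]
        assert row["statistic"] == pytest.approx(20.0)
        assert row["df"] == 1

    def test_independent_gives_near_zero(self):
        ms = self._ms([1, 0, 1, 0, 1, 0, 1, 0], ["a", "a", "b", "b"] * 2)
        res = presence_chisq(ms, "T", "G")
        assert res[res["Taxa"] == "t1"]["statistic"].iloc[0] == pytest.approx(0.0)

    def test_degenerate_all_present_flagged(self):
        ms = self._ms([1] * 8, ["a"] * 4 + ["b"] * 4)
        res = presence_chisq(ms, "T", "G")
        row = res[res["Taxa"] == "t2"].iloc[0]  # t2 present everywhere
        assert row["degenerate"]
        assert np.isnan(row["statistic"])
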