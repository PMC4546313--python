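import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import bloodsig.model as bm
from bloodsig import (ExpressionMatrix, GeneSetCollection, PhenotypeTable,
                      ValidationError, fit_platform_logistic, four_gene_score,
                      loocv_select, predict_score, select_representative,
                      train_naive_bayes)
from bloodsig.annotation import FunctionalCore
from bloodsig.model import (FOUR_GENE_INTERCEPT, FOUR_GENE_WEIGHTS,
                            GaussianNBRisk, NaiveBayesModel)
from bloodsig.stability import StableModule


def _core(genes):
    parent = StableModule("up", list(genes), "M1", "M1", 1e-9, 1)
    return FunctionalCore(parent, list(genes), "PW", "canonical_pathway", 1e-9)


def _expr(values, genes, samples=None):
    samples = samples or [f"S{i}" for i in range(np.shape(values)[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples),
                            "microarray_log2")


def _labels(samples, n_high):
    return PhenotypeTable(pd.DataFrame(
        {"risk_label": ["high"] * n_high + ["low"] * (len(samples) - n_high)},
        index=pd.Index(samples, name="sample_id")))


class TestSelectRepresentative:
    def _de(self, genes, ps):
        de = pd.DataFrame({"p_value": ps}, index=genes)
        de["rank"] = de["p_value"].rank(method="first").astype(int)
        return de

    def test_smallest_p_above_median_wins(self, rng):
        genes = ["a", "b", "c"] + [f"bg{i}" for i in range(20)]
        vals = np.vstack([np.full((3, 8), 9.0), rng.normal(5, 1, (20, 8))])
        expr = _expr(vals, genes)
        de = self._de(genes, [1e-8, 1e-5, 1e-3] + [0.5] * 20)
        rep = select_representative(_core(["a", "b", "c"]), de, expr)
        assert rep.gene_id == "a"
        assert rep.passed_expression_filter

    def test_low_expression_gene_skipped(self, rng):
        genes = ["a", "b"] + [f"bg{i}" for i in range(20)]
        vals = np.vstack([np.full((1, 8), 1.0),       # a: low abundance
                          np.full((1, 8), 9.0),       # b: high abundance
                          rng.normal(5, 1, (20, 8))])
        expr = _expr(vals, genes)
        de = self._de(genes, [1e-8, 1e-5] + [0.5] * 20)
        rep = select_representative(_core(["a", "b"]), de, expr)
        assert rep.gene_id == "b"
        assert rep.passed_expression_filter

    def test_fallback_when_no_core_gene_is_abundant(self, rng):
        genes = ["a", "b"] + [f"bg{i}" for i in range(20)]
        vals = np.vstack([np.full((2, 8), 1.0), rng.normal(5, 1, (20, 8))])
        expr = _expr(vals, genes)
        de = self._de(genes, [1e-8, 1e-5] + [0.5] * 20)
        with pytest.warns(UserWarning, match="expression filter"):
            rep = select_representative(_core(["a", "b"]), de, expr)
        assert rep.gene_id == "a"
        assert not rep.passed_expression_filter

    def test_empty_core_rejected(self, small_expr):
        de = self._de(small_expr.gene_ids, [0.5] * 10)
        with pytest.raises(ValidationError):
            select_representative(_core([]), de, small_expr)


def brute_force_posterior(x, model: NaiveBayesModel):
    """Direct Bayes arithmetic: product of Gaussian densities times priors."""
    from scipy.stats import norm
    lh = model.prior_high
    ll = 1 - model.prior_high
    for g in model.genes:
        lh *= norm.pdf(x[g], model.mean_high[g], np.sqrt(model.var_high[g]))
        ll *= norm.pdf(x[g], model.mean_low[g], np.sqrt(model.var_low[g]))
    return lh / (lh + ll)


class TestNaiveBayes:
    def test_uninformative_features_return_prior(self, rng):
        vals = rng.normal(0, 1, (2, 40))
        expr = _expr(vals, ["g1", "g2"])
        labels = _labels(expr.sample_ids, 10)  # prior_high = 0.25
        model = train_naive_bayes(expr, ["g1", "g2"], labels)
        scores = [predict_score(model, expr.values[s])
                  for s in expr.sample_ids]
        assert np.mean(scores) == pytest.approx(model.prior_high, abs=0.12)

    def test_symmetric_single_gene_posterior_half(self):
        model = NaiveBayesModel(
            genes=["g"], mean_high=pd.Series({"g": 2.0}),
            mean_low=pd.Series({"g": 0.0}), var_high=pd.Series({"g": 1.0}),
            var_low=pd.Series({"g": 1.0}), prior_high=0.5)
        assert predict_score(model, {"g": 1.0}) == pytest.approx(0.5, abs=1e-12)

    def test_matches_brute_force_bayes_oracle(self, rng):
        for _ in range(5):
            model = NaiveBayesModel(
                genes=["a", "b"],
                mean_high=pd.Series({"a": rng.normal(), "b": rng.normal()}),
                mean_low=pd.Series({"a": rng.normal(), "b": rng.normal()}),
                var_high=pd.Series({"a": rng.uniform(0.5, 2),
                                    "b": rng.uniform(0.5, 2)}),
                var_low=pd.Series({"a": rng.uniform(0.5, 2),
                                   "b": rng.uniform(0.5, 2)}),
                prior_high=rng.uniform(0.2, 0.8))
            x = {"a": rng.normal(), "b": rng.normal()}
            assert predict_score(model, x) == pytest.approx(
                brute_force_posterior(x, model), abs=1e-12)

    def test_extreme_input_stays_finite(self):
        model = NaiveBayesModel(
            genes=["g"], mean_high=pd.Series({"g": 1.0}),
            mean_low=pd.Series({"g": -1.0}), var_high=pd.Series({"g": 0.5}),
            var_low=pd.Series({"g": 1.5}), prior_high=0.5)
        for x in (1e6, -1e6):
            s = predict_score(model, {"g": x})
            assert 0 <= s <= 1 and np.isfinite(s)

    def test_missing_gene_value_rejected(self):
        model = NaiveBayesModel(
            genes=["g"], mean_high=pd.Series({"g": 1.0}),
            mean_low=pd.Series({"g": 0.0}), var_high=pd.Series({"g": 1.0}),
            var_low=pd.Series({"g": 1.0}), prior_high=0.5)
        with pytest.raises(ValidationError, match="missing"):
            predict_score(model, {"other": 1.0})

    def test_singleton_class_rejected(self, rng):
        X = rng.normal(0, 1, (5, 2))
        with pytest.raises(ValidationError):
            GaussianNBRisk().fit(X, np.array([1, 0, 0, 0, 0]))

    def test_unbiased_variance_with_floor(self):
        X = np.array([[0.0], [1.0], [5.0], [5.0]])
        est = GaussianNBRisk().fit(X, np.array([0, 0, 1, 1]))
        assert est.var_[0, 0] == pytest.approx(0.5)   # ddof=1
        assert est.var_[1, 0] == pytest.approx(1e-9)  # floored


class TestLoocvSelect:
    def _survival(self, samples, times, events, n_high):
        return PhenotypeTable(pd.DataFrame(
            {"risk_label": ["high"] * n_high +
                           ["low"] * (len(samples) - n_high),
             "survival_time": times, "event": events},
            index=pd.Index(samples, name="sample_id")))

    def _separating_cohort(self, rng, n=40):
        samples = [f"S{i}" for i in range(n)]
        half = n // 2
        # pair 1 separates perfectly; pair 2 is pure noise
        up1 = np.r_[rng.normal(4, 0.3, half), rng.normal(0, 0.3, half)]
        dn1 = np.r_[rng.normal(0, 0.3, half), rng.normal(4, 0.3, half)]
        up2 = rng.normal(0, 1, n)
        dn2 = rng.normal(0, 1, n)
        expr = _expr(np.vstack([up1, up2, dn1, dn2]),
                     ["u1", "u2", "d1", "d2"], samples)
        times = np.r_[rng.exponential(6, half), rng.exponential(40, half)]
        pheno = self._survival(samples, times, np.ones(n), half)
        return expr, pheno

    def test_perfect_pair_selects_k1(self, rng):
        expr, pheno = self._separating_cohort(rng)
        k, model, perf = loocv_select(expr, pheno, pheno, ["u1", "u2"],
                                      ["d1", "d2"])
        assert k == 1
        assert model.genes == ["u1", "d1"]
        assert perf.loc[1, "logrank_p"] <= perf.loc[2, "logrank_p"]

    def test_all_null_still_returns_model_with_flag(self, rng):
        samples = [f"S{i}" for i in range(30)]
        expr = _expr(rng.normal(0, 1, (4, 30)), ["u1", "u2", "d1", "d2"],
                     samples)
        pheno = self._survival(samples, rng.exponential(20, 30),
                               np.ones(30), 15)
        with pytest.warns(UserWarning, match="not.*significant|significant"):
            k, model, perf = loocv_select(expr, pheno, pheno, ["u1", "u2"],
                                          ["d1", "d2"])
        assert model is not None
        assert not perf.loc[k, "significant"]

    def test_held_out_label_never_influences_its_own_fold(self, rng):
        expr, pheno = self._separating_cohort(rng)
        _, _, perf = loocv_select(expr, pheno, pheno, ["u1", "u2"],
                                  ["d1", "d2"])
        flipped = pheno.table.copy()
        target = flipped.index[0]
        flipped.loc[target, "risk_label"] = "low"
        _, _, perf2 = loocv_select(expr, PhenotypeTable(flipped), pheno,
                                   ["u1", "u2"], ["d1", "d2"])
        for k in (1, 2):
            s1 = perf.attrs["loo_scores"][k][target]
            s2 = perf2.attrs["loo_scores"][k][target]
            assert s1 == pytest.approx(s2, abs=1e-12)

    def test_mismatched_lists_rejected(self, rng):
        expr, pheno = self._separating_cohort(rng)
        with pytest.raises(ValidationError):
            loocv_select(expr, pheno, pheno, ["u1"], ["d1", "d2"])


class TestFourGeneScore:
    def test_boundary_input_scores_exactly_half(self):
        mcm2 = FOUR_GENE_INTERCEPT / -FOUR_GENE_WEIGHTS["MCM2"]
        assert four_gene_score(mcm2, 0.0, 0.0, 0.0) == pytest.approx(0.5,
                                                                     abs=1e-12)

    def test_all_zero_input_evaluates_printed_formula(self):
        assert four_gene_score(0, 0, 0, 0) == pytest.approx(
            np.exp(-27.28) / (1 + np.exp(-27.28)), rel=1e-12)

    def test_unit_changes_move_logit_by_printed_coefficients(self):
        # base point chosen near the decision boundary so the logit is
        # numerically recoverable (s = 0.84)
        base = dict(mcm2=-5.0, pros1=-2.0, cd22=2.0, tmem66=1.0)
        s0 = logit(four_gene_score(**base))
        for arg, coef in [("mcm2", -3.43), ("pros1", -0.68),
                          ("cd22", 3.06), ("tmem66", 3.49)]:
            bumped = dict(base)
            bumped[arg] += 1.0
            assert logit(four_gene_score(**bumped)) - s0 == pytest.approx(
                coef, abs=1e-9)

    def test_monotonicity_sweep(self):
        grid = np.linspace(-3, 3, 7)
        up = [four_gene_score(0, 0, 8 + d, 0) for d in grid]
        assert np.all(np.diff(up) > 0)       # increasing in CD22
        down = [four_gene_score(8 + d, 0, 0, 0) for d in grid]
        assert np.all(np.diff(down) < 0)     # decreasing in MCM2

    def test_overflow_safe(self):
        assert four_gene_score(-1e4, 0, 1e4, 1e4) == pytest.approx(1.0)
        assert four_gene_score(1e4, 1e4, -1e4, -1e4) == pytest.approx(0.0)

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError):
            four_gene_score(np.nan, 0, 0, 0)


class TestPlatformLogistic:
    def _survival_from_class(self, samples, y):
        # deaths before 12 months for the high class, survivors past 24 for low
        times = np.where(y == 1, 6.0, 36.0)
        events = np.where(y == 1, 1, 0)
        return PhenotypeTable(pd.DataFrame(
            {"survival_time": times, "event": events},
            index=pd.Index(samples, name="sample_id")))

    def test_recovers_known_coefficients(self):
        n = 400
        gen = np.random.default_rng(0)
        beta = np.array([0.5, -1.0, 0.8, 0.0, 1.2])  # intercept + 4 genes
        X = gen.normal(0, 1, (n, 4))
        y = gen.binomial(1, expit(beta[0] + X @ beta[1:]))
        samples = [f"S{i}" for i in range(n)]
        genes = ["MCM2", "PROS1", "CD22", "TMEM66"]
        expr = ExpressionMatrix(pd.DataFrame(X.T, index=genes,
                                             columns=samples), "qpcr_deltact")
        model = fit_platform_logistic(expr, self._survival_from_class(samples, y),
                                      genes)
        import statsmodels.api as sm
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        fitted = np.r_[model.intercept, [model.weights[g] for g in genes]]
        # exact ML agreement with the independent fitter ...
        assert np.allclose(fitted, ref.params, atol=1e-6)
        # ... and truth recovered: every coefficient within its 99% CI,
        # most within 2 s.e.; the null gene's CI covers 0
        z = np.abs(fitted - beta) / ref.bse
        assert np.all(z <= 2.58)
        assert (z <= 2).sum() >= 4
        assert abs(model.weights["CD22"] - 0.0) <= 2.58 * ref.bse[3]

    def test_perfect_separation_falls_back_to_ridge(self, rng):
        n = 30
        x = np.r_[rng.uniform(2, 3, 15), rng.uniform(-3, -2, 15)]
        y = (x > 0).astype(int)
        samples = [f"S{i}" for i in range(n)]
        expr = ExpressionMatrix(
            pd.DataFrame(x[None, :], index=["G"], columns=samples),
            "qpcr_deltact")
        with pytest.warns(UserWarning, match="ridge"):
            model = fit_platform_logistic(
                expr, self._survival_from_class(samples, y), ["G"])
        assert "ridge_fallback" in model.flags
        assert np.isfinite(model.weights["G"])

    def test_inverted_extreme_windows_rejected(self, rng, small_expr):
        pheno = self._survival_from_class(small_expr.sample_ids,
                                          np.r_[np.ones(6), np.zeros(6)])
        with pytest.raises(ValidationError, match="t_low"):
            fit_platform_logistic(small_expr, pheno, small_expr.gene_ids[:2],
                                  t_low=30, t_high=20)

    def test_empty_extreme_group_rejected(self, small_expr):
        pheno = PhenotypeTable(pd.DataFrame(
            {"survival_time": [15.0] * 12, "event": [1] * 12},
            index=pd.Index(small_expr.sample_ids, name="sample_id")))
        with pytest.raises(ValidationError, match="extreme"):
            fit_platform_logistic(small_expr, pheno, small_expr.gene_ids[:2])
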