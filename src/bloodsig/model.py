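"""Prognostic model construction and scoring.

From each functional core one *representative gene* is chosen: the most
differentially expressed core gene whose mean expression exceeds the
transcriptome median (avoiding barely-expressed genes).  Representatives
from up- and down-regulated modules are paired into nested candidate sets
(top-k up + top-k down); a Gaussian naïve-Bayes classifier is trained for
each k and the model size is chosen by leave-one-out cross-validation,
scoring each candidate by the log-rank separation of the LOO-predicted
risk groups (posterior dichotomized at 0.5).

A fixed four-gene logistic score for the qPCR platform is also provided:

    s = −27.28 − 3.43·MCM2 − 0.68·PROS1 + 3.06·CD22 + 3.49·TMEM66
    score = exp(s) / (1 + exp(s)),  high risk iff score ≥ 0.5

where gene values are delta-Ct (18S-normalized) measurements.  The same
model shape can be refit on any cohort's survival extremes via
:func:`fit_platform_logistic`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp
from sklearn.base import BaseEstimator, ClassifierMixin

from .annotation import FunctionalCore
from .exceptions import ValidationError
from .io import QPCR, ExpressionMatrix, PhenotypeTable
from .survival import cox_ph, logrank_test

VAR_FLOOR = 1e-9

#: Printed four-gene qPCR logistic model (delta-Ct inputs).
FOUR_GENE_INTERCEPT = -27.28
FOUR_GENE_WEIGHTS = {"MCM2": -3.43, "PROS1": -0.68, "CD22": 3.06,
                     "TMEM66": 3.49}


@dataclass
class RepresentativeGene:
    gene_id: str
    parent_core: FunctionalCore
    de_p: float
    de_rank: int
    passed_expression_filter: bool


@dataclass
class NaiveBayesModel:
    """Gaussian naïve-Bayes risk model over an ordered, up/down-paired gene list."""

    genes: list[str]
    mean_high: pd.Series
    mean_low: pd.Series
    var_high: pd.Series
    var_low: pd.Series
    prior_high: float
    cutoff: float = 0.5

    def __post_init__(self):
        if (self.var_high <= 0).any() or (self.var_low <= 0).any():
            raise ValidationError("class variances must be positive")
        if not (0 < self.prior_high < 1):
            raise ValidationError("class priors must be strictly between 0 and 1")


@dataclass
class FourGeneScoreModel:
    """Logistic risk score over four delta-Ct measurements."""

    intercept: float = FOUR_GENE_INTERCEPT
    weights: dict = field(default_factory=lambda: dict(FOUR_GENE_WEIGHTS))
    cutoff: float = 0.5
    platform: str = QPCR
    flags: list = field(default_factory=list)

    def score(self, values: dict | pd.Series) -> float:
        s = self.intercept
        for gene, w in self.weights.items():
            v = float(values[gene])
            if not np.isfinite(v):
                raise ValidationError(f"non-finite value for {gene}")
            s += w * v
        return float(expit(s))

    def score_matrix(self, expr: ExpressionMatrix) -> pd.Series:
        return pd.Series(
            {s: self.score(expr.values[s]) for s in expr.sample_ids})


def select_representative(core: FunctionalCore, de: pd.DataFrame,
                          expr: ExpressionMatrix) -> RepresentativeGene:
    """Pick the representative gene of one functional core.

    Among core genes whose mean training expression exceeds the median of
    all genes' means, take the one with smallest DE p (ties by DE rank).
    If no core gene passes the abundance filter, fall back to the smallest-p
    core gene with ``passed_expression_filter=False`` and a warning.
    """
    if not core.core_genes:
        raise ValidationError("functional core is empty")
    gene_means = expr.values.mean(axis=1)
    threshold = float(gene_means.median())
    candidates = [g for g in core.core_genes if g in de.index]
    if not candidates:
        raise ValidationError("no core gene present in the DE table")
    sub = de.loc[candidates].sort_values("rank")
    passing = sub.index[gene_means.loc[sub.index] > threshold]
    if len(passing) > 0:
        gene = passing[0]
        passed = True
    else:
        gene = sub.index[0]
        passed = False
        warnings.warn(f"no core gene of {core.source_set_name!r} passes the "
                      "expression filter; using the smallest-p gene anyway")
    return RepresentativeGene(gene, core, float(de.loc[gene, "p_value"]),
                              int(de.loc[gene, "rank"]), passed)


class GaussianNBRisk(BaseEstimator, ClassifierMixin):
    """Gaussian naïve Bayes with unbiased class variances (sklearn-style).

    fit(X, y): X samples × genes, y in {0, 1} (1 = high risk).  Unbiased
    per-class variances floored at 1e-9; priors = class frequencies.
    Fitted attributes: theta_ (2 × p class means), var_, class_prior_.
    """

    def __init__(self, var_floor: float = VAR_FLOOR):
        self.var_floor = var_floor

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValidationError("exactly two classes required")
        counts = np.array([(y == c).sum() for c in self.classes_])
        if (counts < 2).any():
            raise ValidationError("each class needs >= 2 samples")
        self.theta_ = np.vstack([X[y == c].mean(axis=0) for c in self.classes_])
        self.var_ = np.vstack([np.maximum(X[y == c].var(axis=0, ddof=1),
                                          self.var_floor)
                               for c in self.classes_])
        self.class_prior_ = counts / counts.sum()
        return self

    def _joint_log_likelihood(self, X):
        X = np.asarray(X, dtype=float)
        jll = np.empty((X.shape[0], 2))
        for i in range(2):
            ll = -0.5 * np.log(2 * np.pi * self.var_[i]) \
                 - 0.5 * (X - self.theta_[i]) ** 2 / self.var_[i]
            jll[:, i] = ll.sum(axis=1) + np.log(self.class_prior_[i])
        return jll

    def predict_proba(self, X):
        jll = self._joint_log_likelihood(X)
        log_norm = logsumexp(jll, axis=1, keepdims=True)
        return np.exp(jll - log_norm)

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


def train_naive_bayes(expr: ExpressionMatrix, genes: list[str],
                      labels: PhenotypeTable,
                      cutoff: float = 0.5) -> NaiveBayesModel:
    """Fit the Gaussian NB risk model on labelled training samples."""
    groups = labels.risk_groups()
    groups = groups[groups.index.isin(expr.sample_ids)]
    X = expr.subset_genes(list(genes)).values[groups.index].to_numpy().T
    y = (groups == "high").astype(int).to_numpy()
    est = GaussianNBRisk().fit(X, y)
    lo, hi = (0, 1) if est.classes_[0] == 0 else (1, 0)
    return NaiveBayesModel(
        genes=list(genes),
        mean_high=pd.Series(est.theta_[hi], index=genes),
        mean_low=pd.Series(est.theta_[lo], index=genes),
        var_high=pd.Series(est.var_[hi], index=genes),
        var_low=pd.Series(est.var_[lo], index=genes),
        prior_high=float(est.class_prior_[hi]),
        cutoff=cutoff,
    )


def predict_score(model: NaiveBayesModel, sample_values) -> float:
    """Posterior probability of the high-risk class, computed in log space."""
    try:
        x = np.array([float(sample_values[g]) for g in model.genes])
    except KeyError as exc:
        raise ValidationError(f"missing value for model gene {exc}") from None
    if not np.isfinite(x).all():
        raise ValidationError("non-finite expression value")

    def _log_lik(mean, var):
        m = mean.to_numpy()
        v = var.to_numpy()
        return float((-0.5 * np.log(2 * np.pi * v)
                      - 0.5 * (x - m) ** 2 / v).sum())

    lh = _log_lik(model.mean_high, model.var_high) + np.log(model.prior_high)
    ll = _log_lik(model.mean_low, model.var_low) + np.log(1 - model.prior_high)
    return float(np.exp(lh - logsumexp([lh, ll])))


def score_samples(model: NaiveBayesModel, expr: ExpressionMatrix) -> pd.Series:
    """Posterior high-risk score for every sample column."""
    return pd.Series({s: predict_score(model, expr.values[s])
                      for s in expr.sample_ids})


def loocv_select(expr: ExpressionMatrix, labels: PhenotypeTable,
                 survival: PhenotypeTable,
                 up_reps: list[RepresentativeGene] | list[str],
                 down_reps: list[RepresentativeGene] | list[str],
                 cutoff: float = 0.5):
    """Choose the number of gene pairs by leave-one-out cross-validation.

    For k = 1..K the candidate set is the top-k up plus top-k down
    representatives (module-rank order).  Each training sample is scored by
    an NB model fit on the remaining samples; LOO scores are dichotomized
    at ``cutoff`` and candidates compared by the log-rank p of the two
    predicted groups on training survival (ties: larger group hazard ratio,
    then smaller k).  The winning gene set is refit on all samples.

    Returns (k, final NaiveBayesModel, cv_performance DataFrame indexed by k
    with columns logrank_p, hazard_ratio, significant, plus per-sample LOO
    scores in attrs["loo_scores"]).
    """
    up = [r.gene_id if isinstance(r, RepresentativeGene) else r for r in up_reps]
    down = [r.gene_id if isinstance(r, RepresentativeGene) else r
            for r in down_reps]
    if len(up) != len(down) or not up:
        raise ValidationError("need equal, non-empty up/down representative lists")
    K = len(up)
    groups = labels.risk_groups()
    groups = groups[groups.index.isin(expr.sample_ids)]
    samples = list(groups.index)
    surv = survival.survival().loc[samples]
    t = surv["survival_time"].to_numpy()
    e = surv["event"].to_numpy()
    rows = []
    loo_scores: dict[int, pd.Series] = {}
    for k in range(1, K + 1):
        genes = up[:k] + down[:k]
        X = expr.subset_genes(genes).values[samples].to_numpy().T
        y = (groups == "high").astype(int).to_numpy()
        scores = np.empty(len(samples))
        skipped = False
        for i in range(len(samples)):
            mask = np.ones(len(samples), dtype=bool)
            mask[i] = False
            yi = y[mask]
            if min((yi == 0).sum(), (yi == 1).sum()) < 2:
                warnings.warn(f"LOO fold with a near-singleton class; "
                              f"skipping k={k}")
                skipped = True
                break
            est = GaussianNBRisk().fit(X[mask], yi)
            hi = int(np.where(est.classes_ == 1)[0][0])
            scores[i] = est.predict_proba(X[i:i + 1])[0, hi]
        if skipped:
            continue
        high = scores >= cutoff
        if high.all() or (~high).all():
            rows.append((k, 1.0, np.nan, False))
            loo_scores[k] = pd.Series(scores, index=samples)
            continue
        _, p = logrank_test(t, e, high.astype(int))
        hr = float(cox_ph(t, e, pd.DataFrame({"high": high.astype(float)}))
                   .hazard_ratios.iloc[0])
        rows.append((k, p, hr, p < 0.05))
        loo_scores[k] = pd.Series(scores, index=samples)
    if not rows:
        raise ValidationError("every candidate model size was skipped")
    perf = pd.DataFrame(rows, columns=["k", "logrank_p", "hazard_ratio",
                                       "significant"]).set_index("k")
    hr_key = perf["hazard_ratio"].fillna(-np.inf)
    order = sorted(perf.index, key=lambda k: (perf.loc[k, "logrank_p"],
                                              -hr_key.loc[k], k))
    best_k = int(order[0])
    final = train_naive_bayes(expr, up[:best_k] + down[:best_k], labels,
                              cutoff=cutoff)
    if not bool(perf.loc[best_k, "significant"]):
        warnings.warn("selected model's cross-validated separation is not "
                      "significant (log-rank p >= 0.05)")
    perf.attrs["loo_scores"] = loo_scores
    return best_k, final, perf


def four_gene_score(mcm2: float, pros1: float, cd22: float,
                    tmem66: float) -> float:
    """The fixed four-gene qPCR risk score on delta-Ct inputs."""
    model = FourGeneScoreModel()
    return model.score({"MCM2": mcm2, "PROS1": pros1, "CD22": cd22,
                        "TMEM66": tmem66})


def _newton_logistic(X: np.ndarray, y: np.ndarray, ridge: float = 0.0,
                     tol: float = 1e-8, max_iter: int = 100):
    """IRLS/Newton maximum-likelihood logistic fit; returns (beta, converged)."""
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = np.maximum(mu * (1 - mu), 1e-12)
        grad = X.T @ (y - mu) - ridge * beta
        hess = (X.T * w) @ X + (ridge + 1e-12) * np.eye(p)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            return beta, False
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            return beta, True
    return beta, False


def fit_platform_logistic(expr: ExpressionMatrix, survival: PhenotypeTable,
                          genes: list[str], t_low: float = 12.0,
                          t_high: float = 24.0) -> FourGeneScoreModel:
    """Refit the four-gene-shaped logistic model on one platform's extremes.

    High-risk = death observed before ``t_low`` months; low-risk = survival
    (event or censoring) beyond ``t_high`` months; everyone else excluded.
    Maximum-likelihood Newton fit; perfect separation (non-convergence or
    exploding coefficients) falls back to a small ridge penalty (1e-4) with
    a flag.
    """
    if t_low > t_high:
        raise ValidationError("t_low must not exceed t_high")
    surv = survival.survival()
    surv = surv.loc[[s for s in surv.index if s in expr.sample_ids]]
    high = surv.index[(surv["event"] == 1) & (surv["survival_time"] < t_low)]
    low = surv.index[surv["survival_time"] > t_high]
    if len(high) == 0 or len(low) == 0:
        raise ValidationError(
            f"empty extreme group (high={len(high)}, low={len(low)})")
    samples = list(high) + list(low)
    y = np.array([1] * len(high) + [0] * len(low), dtype=float)
    Xg = expr.subset_genes(list(genes)).values[samples].to_numpy().T
    X = np.column_stack([np.ones(len(samples)), Xg])
    beta, converged = _newton_logistic(X, y)
    flags: list[str] = []
    if not converged or np.max(np.abs(beta)) > 1e3:
        warnings.warn("logistic fit did not converge (likely separation); "
                      "refitting with ridge penalty 1e-4")
        beta, _ = _newton_logistic(X, y, ridge=1e-4)
        flags.append("ridge_fallback")
    return FourGeneScoreModel(
        intercept=float(beta[0]),
        weights={g: float(b) for g, b in zip(genes, beta[1:])},
        cutoff=0.5,
        platform=expr.platform,
        flags=flags,
    )
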