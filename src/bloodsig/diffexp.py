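"""Two-group differential expression with empirical-Bayes moderated t-statistics.

The first pipeline stage contrasts high- vs low-risk training samples gene by
gene.  Per-gene variances are shrunken towards a common prior estimated from
the whole transcriptome (the classic limma-style hierarchical model restricted
to a two-class design):

    s̃_g² = (d0·s0² + d_g·s_g²) / (d0 + d_g)
    t_g  = logFC_g / (s̃_g · sqrt(1/n1 + 1/n2)),   t_g ~ t(d0 + d_g) under H0

with the prior (d0, s0²) obtained by closed-form moment matching on the log
sample variances (digamma/trigamma inversion).  Multiplicity is controlled by
Benjamini–Hochberg step-up adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError
from .io import ExpressionMatrix, PhenotypeTable

#: Cap representing an effectively infinite prior degrees of freedom.
D0_CAP = 1e6


@dataclass
class EmpiricalBayesPrior:
    """Prior for the gene-variance hierarchy: d0 degrees of freedom, s0² scale."""

    d0: float
    s0_sq: float

    def __post_init__(self):
        if not (self.d0 > 0):
            raise ValidationError("prior d0 must be > 0")
        if not (self.s0_sq > 0):
            raise ValidationError("prior s0_sq must be > 0")


def _trigamma_inverse(x: float) -> float:
    """Solve psi'(y) = x for y > 0 by Newton iteration on 1/psi'."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) / y < 1e-10:
            break
    return float(y)


def estimate_prior(sample_vars: np.ndarray, d_g: float) -> EmpiricalBayesPrior:
    """Moment-matching estimate of (d0, s0²) from per-gene sample variances.

    Works on e_g = log s_g² − psi(d_g/2) + log(d_g/2), which is unbiased for
    log σ_g² gene-wise; the excess of var(e) over trigamma(d_g/2) identifies
    d0.  When the log variances are under-dispersed (var(e) ≤ trigamma, e.g.
    all variances equal) the prior is taken as effectively infinite with s0²
    equal to the geometric mean of the sample variances, so that shrinkage to
    the common value is exact.
    """
    v = np.asarray(sample_vars, dtype=float)
    v = v[v > 0]
    if v.size == 0:
        raise ValidationError("no positive sample variances to estimate prior")
    z = np.log(v)
    e = z - special.digamma(d_g / 2.0) + np.log(d_g / 2.0)
    if v.size == 1:
        return EmpiricalBayesPrior(D0_CAP, float(np.exp(np.mean(z))))
    mean_e = float(np.mean(e))
    var_e = float(np.var(e, ddof=1))
    excess = var_e - special.polygamma(1, d_g / 2.0)
    if excess <= 0:
        return EmpiricalBayesPrior(D0_CAP, float(np.exp(np.mean(z))))
    d0 = 2.0 * _trigamma_inverse(excess)
    d0 = min(d0, D0_CAP)
    s0_sq = float(np.exp(mean_e + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return EmpiricalBayesPrior(d0, s0_sq)


def moderated_t_test(expr: ExpressionMatrix, labels: PhenotypeTable,
                     prior: EmpiricalBayesPrior | None = None) -> pd.DataFrame:
    """Moderated-t differential expression, high- vs low-risk group.

    Parameters
    ----------
    expr : ExpressionMatrix
        Training expression; every labelled sample must be a column.
    labels : PhenotypeTable
        Supplies the high/low risk labels.  Samples without a label are
        ignored; each group needs >= 2 samples.
    prior : EmpiricalBayesPrior, optional
        Force a prior (e.g. ``EmpiricalBayesPrior(D0_CAP, s0_sq)`` for the
        d0 → ∞ limit) instead of estimating it from the data.

    Returns
    -------
    pandas.DataFrame indexed by gene with columns log_fc, mean_high,
    mean_low, pooled_sd, moderated_t, p_value, fdr, direction, rank.
    Ranks order by ascending p, ties broken by |log_fc| descending then
    gene id, so they are a permutation of 1..n_genes.
    """
    groups = labels.risk_groups()
    groups = groups[groups.index.isin(expr.sample_ids)]
    high = groups.index[groups == "high"].tolist()
    low = groups.index[groups == "low"].tolist()
    n1, n2 = len(high), len(low)
    if n1 < 2 or n2 < 2:
        raise ValidationError(
            f"each group needs >=2 samples (high={n1}, low={n2})")
    xh = expr.values[high].to_numpy(dtype=float)
    xl = expr.values[low].to_numpy(dtype=float)
    mean_high = xh.mean(axis=1)
    mean_low = xl.mean(axis=1)
    log_fc = mean_high - mean_low
    d_g = n1 + n2 - 2
    ss = ((xh - mean_high[:, None]) ** 2).sum(axis=1) + \
         ((xl - mean_low[:, None]) ** 2).sum(axis=1)
    s2 = ss / d_g
    zero_var = s2 <= 0
    if zero_var.any():
        warnings.warn(f"{int(zero_var.sum())} gene(s) with zero variance in "
                      "both groups; assigned p = 1")
    if prior is None:
        prior = estimate_prior(s2, d_g)
    d0 = min(prior.d0, D0_CAP)
    s2_tilde = (d0 * prior.s0_sq + d_g * s2) / (d0 + d_g)
    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log_fc / se, 0.0)
    df_total = min(d0 + d_g, D0_CAP)
    p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    p = np.where(zero_var & (log_fc == 0), 1.0, p)
    fdr = benjamini_hochberg(p)
    res = pd.DataFrame({
        "log_fc": log_fc,
        "mean_high": mean_high,
        "mean_low": mean_low,
        "pooled_sd": np.sqrt(s2),
        "moderated_t": t,
        "p_value": p,
        "fdr": fdr,
        "direction": np.where(log_fc > 0, "up", "down"),
    }, index=expr.values.index)
    order = np.lexsort((res.index.astype(str),
                        -np.abs(res["log_fc"].to_numpy()),
                        res["p_value"].to_numpy()))
    ranks = np.empty(len(res), dtype=int)
    ranks[order] = np.arange(1, len(res) + 1)
    res["rank"] = ranks
    res.attrs["prior_d0"] = d0
    res.attrs["prior_s0_sq"] = prior.s0_sq
    res.attrs["n_high"] = n1
    res.attrs["n_low"] = n2
    return res


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj


def select_candidates(de: pd.DataFrame, fdr_cutoff: float = 0.05
                      ) -> tuple[list[str], list[str]]:
    """Split FDR-significant genes into up/down lists ordered by ascending p.

    Genes with fdr < cutoff qualify; ordering follows the deterministic rank
    column of the DE table.
    """
    if not (0 < fdr_cutoff < 1):
        raise ValidationError("fdr_cutoff must be in (0, 1)")
    sig = de[de["fdr"] < fdr_cutoff].sort_values("rank")
    up = sig.index[sig["direction"] == "up"].tolist()
    down = sig.index[sig["direction"] == "down"].tolist()
    return up, down
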