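"""Survival-analysis machinery: Kaplan–Meier, log-rank, Cox PH, concordance.

Cox proportional-hazards fits are delegated to lifelines (Efron tie
handling, Newton convergence), while the log-rank statistic, the Cox
score-test-at-zero and the Kaplan–Meier product-limit estimator are
implemented directly so they can be cross-checked against brute-force
oracles and reused cheaply inside cross-validation loops.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.utils import concordance_index as _lifelines_cindex
from scipy import stats

from .exceptions import ValidationError
from .io import PhenotypeTable


@dataclass
class KaplanMeierCurve:
    """Right-continuous product-limit survival estimate; callable at any t."""

    times: np.ndarray      # distinct event times, ascending
    survival: np.ndarray   # S(t) just after each event time
    at_risk: np.ndarray    # number at risk just before each event time

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if self.times.size == 0:  # no events: S ≡ 1
            ones = np.ones_like(t)
            return float(ones) if ones.ndim == 0 else ones
        idx = np.searchsorted(self.times, t, side="right") - 1
        s = np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, None)])
        return float(s) if s.ndim == 0 else s


@dataclass
class SurvivalFit:
    """Cox fit summary: per-covariate effects plus global fit statistics."""

    coefficients: pd.Series
    hazard_ratios: pd.Series
    standard_errors: pd.Series
    wald_p: pd.Series
    lrt_p: float
    concordance: float
    logrank_p: float | None = None
    flags: list[str] = field(default_factory=list)


def _check_surv(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    if times.size == 0:
        raise ValidationError("empty survival input")
    if times.shape != events.shape:
        raise ValidationError("times and events must align")
    if (times < 0).any():
        raise ValidationError("negative survival times")
    if not np.isin(events, [0, 1]).all():
        raise ValidationError("events must be 0/1")
    return times, events.astype(int)


def kaplan_meier(times, events) -> KaplanMeierCurve:
    """Product-limit estimator; S(0) = 1, drops only at observed events."""
    times, events = _check_surv(times, events)
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    event_times = np.unique(t[e == 1])
    surv, risk = [], []
    s = 1.0
    for et in event_times:
        n_at_risk = int((t >= et).sum())
        d = int(((t == et) & (e == 1)).sum())
        s *= 1.0 - d / n_at_risk
        surv.append(s)
        risk.append(n_at_risk)
    return KaplanMeierCurve(event_times.astype(float), np.asarray(surv),
                            np.asarray(risk, dtype=int))


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square on 1 dof, p-value).

    Observed-vs-expected group-1 events summed over distinct event times
    with the hypergeometric variance at each time.
    """
    times, events = _check_surv(times, events)
    g = np.asarray(groups)
    labels = np.unique(g)
    if labels.size != 2:
        raise ValidationError(f"need exactly 2 groups, got {labels.size}")
    in1 = g == labels[1]
    o_minus_e = 0.0
    var = 0.0
    for et in np.unique(times[events == 1]):
        at_risk = times >= et
        n = int(at_risk.sum())
        n1 = int((at_risk & in1).sum())
        d = int(((times == et) & (events == 1)).sum())
        d1 = int(((times == et) & (events == 1) & in1).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var <= 0:
        return 0.0, 1.0
    chi2 = o_minus_e ** 2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def cox_score_test_at_zero(times, events, x) -> float:
    """Efron partial-likelihood score chi-square for a single covariate at β=0.

    With a binary covariate and no tied event times this coincides with the
    log-rank chi-square; kept as an in-repo oracle for that equivalence.
    """
    times, events = _check_surv(times, events)
    x = np.asarray(x, dtype=float)
    u = 0.0
    info = 0.0
    for et in np.unique(times[events == 1]):
        at_risk = times >= et
        tied = (times == et) & (events == 1)
        d = int(tied.sum())
        sum_x_risk = float(x[at_risk].sum())
        sum_x2_risk = float((x[at_risk] ** 2).sum())
        n_risk = int(at_risk.sum())
        sum_x_tied = float(x[tied].sum())
        sum_x2_tied = float((x[tied] ** 2).sum())
        u += sum_x_tied
        for l in range(d):
            f = l / d
            denom = n_risk - f * d
            mean = (sum_x_risk - f * sum_x_tied) / denom
            meansq = (sum_x2_risk - f * sum_x2_tied) / denom
            u -= mean
            info += meansq - mean ** 2
    if info <= 0:
        return 0.0
    return float(u ** 2 / info)


def cox_ph(times, events, covariates, ties: str = "efron",
           robust: bool = False) -> SurvivalFit:
    """Cox proportional-hazards regression (Efron ties, lifelines backend).

    ``covariates`` is a DataFrame / 2-D array (samples × covariates).  A
    constant covariate is rejected; non-convergence triggers a ridge
    fallback (small L2 penalty) with a flag.
    """
    if ties != "efron":
        raise ValidationError("only efron tie handling is supported")
    times, events = _check_surv(times, events)
    if events.sum() < 1:
        raise ValidationError("need at least one event")
    cov = pd.DataFrame(covariates)
    cov.columns = [str(c) for c in cov.columns]
    arr = cov.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValidationError("covariates must be finite")
    const = [c for c in cov.columns if np.ptp(cov[c].to_numpy()) == 0]
    if const:
        raise ValidationError(f"constant covariate(s): {const}")
    df = cov.reset_index(drop=True).copy()
    df["_time"] = times
    df["_event"] = events
    flags: list[str] = []
    fitter = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(df, duration_col="_time", event_col="_event")
    except Exception:
        flags.append("ridge_fallback")
        fitter = CoxPHFitter(penalizer=1e-4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(df, duration_col="_time", event_col="_event")
    summ = fitter.summary
    return SurvivalFit(
        coefficients=summ["coef"].copy(),
        hazard_ratios=np.exp(summ["coef"]).rename("hazard_ratio"),
        standard_errors=summ["se(coef)"].copy(),
        wald_p=summ["p"].copy(),
        lrt_p=float(fitter.log_likelihood_ratio_test().p_value),
        concordance=float(fitter.concordance_index_),
        flags=flags,
    )


def concordance_index(times, events, scores) -> float:
    """C-index of a risk score: higher score should mean shorter survival.

    Fraction of comparable pairs ordered correctly; score ties count 0.5.
    """
    times, events = _check_surv(times, events)
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ValidationError("scores must be finite")
    if events.sum() == 0:
        raise ValidationError("no usable pairs (no events)")
    # lifelines convention: higher prediction = longer survival → negate risk
    return float(_lifelines_cindex(times, -scores, events))


def evaluate_score(scores, survival: PhenotypeTable, cutoff: float = 0.5,
                   co_scores: dict | None = None) -> dict:
    """Bundle the standard score evaluations against overall survival.

    Returns a dict with: univariate Cox on the continuous score (HR per
    unit, LRT p, concordance), dichotomized analysis at ``cutoff`` (log-rank
    chi2/p, group HR, KM curves), and a bivariate Cox per co-score.
    Degenerate dichotomizations and collinear co-scores are flagged instead
    of tested.
    """
    surv = survival.survival()
    scores = pd.Series(scores)
    scores = scores.loc[surv.index]
    t = surv["survival_time"].to_numpy()
    e = surv["event"].to_numpy()
    s = scores.to_numpy(dtype=float)
    report: dict = {"flags": []}
    uni = cox_ph(t, e, pd.DataFrame({"score": s}))
    report["univariate"] = uni
    high = s >= cutoff
    if high.all() or (~high).all():
        report["flags"].append("degenerate_dichotomization")
        report["dichotomized"] = None
    else:
        chi2, p = logrank_test(t, e, high.astype(int))
        grp = cox_ph(t, e, pd.DataFrame({"high": high.astype(float)}))
        report["dichotomized"] = {
            "logrank_chi2": chi2, "logrank_p": p,
            "hazard_ratio": float(grp.hazard_ratios.iloc[0]),
            "km_high": kaplan_meier(t[high], e[high]),
            "km_low": kaplan_meier(t[~high], e[~high]),
            "n_high": int(high.sum()), "n_low": int((~high).sum()),
        }
    if co_scores:
        report["bivariate"] = {}
        for name, co in co_scores.items():
            co = pd.Series(co).loc[surv.index].to_numpy(dtype=float)
            if np.ptp(co) == 0 or abs(np.corrcoef(s, co)[0, 1]) > 1 - 1e-10:
                report["bivariate"][name] = "collinear"
                report["flags"].append(f"collinear:{name}")
                continue
            fit = cox_ph(t, e, pd.DataFrame({"score": s, name: co}))
            report["bivariate"][name] = fit
    return report
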