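"""Outcome statistics: diagnostic accuracy, group tests, survival analysis.

Covers the analysis stage of the pipeline: 2x2 diagnostic metrics and odds
ratio for predicting 3-month non-progression, Mann-Whitney / chi-square /
Fisher group comparisons, Spearman correlation, Kaplan-Meier fits with
log-rank comparisons, the median-outward optimal-cutoff log-rank search,
Cox proportional-hazards and logistic regression, and ROC/Youden cutoffs.

Model fitting is delegated to the standard stack (lifelines, statsmodels,
scipy, scikit-learn); the study-specific pieces — the diagnostic surface on
the MR/nPD table and the constrained cutoff search — are implemented here.
All p values are two-tailed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import median_survival_times
from scipy import stats as sps


# ---------------------------------------------------------------------------
# 2x2 tables


@dataclass(frozen=True)
class TwoByTwo:
    """Classification counts: test positive = metabolic responder (MR),
    condition positive = non-progression at 3 months (nPD)."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        cells = (self.tp, self.fn, self.fp, self.tn)
        if any(c < 0 for c in cells):
            raise ValueError("cell counts must be non-negative")
        if sum(cells) == 0:
            raise ValueError("table must contain at least one observation")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @classmethod
    def from_labels(cls, test_positive: Sequence[bool],
                    condition_positive: Sequence[bool]) -> "TwoByTwo":
        t = np.asarray(test_positive, bool)
        c = np.asarray(condition_positive, bool)
        if t.shape != c.shape:
            raise ValueError("label vectors differ in length")
        return cls(
            tp=int(np.sum(t & c)), fn=int(np.sum(~t & c)),
            fp=int(np.sum(t & ~c)), tn=int(np.sum(~t & ~c)),
        )


def _ratio_pct(num: int, den: int) -> Optional[float]:
    return None if den == 0 else 100.0 * num / den


def confusion_metrics(t: TwoByTwo) -> dict[str, Optional[float]]:
    """Sensitivity, specificity, PPV, NPV and accuracy, in percent.

    A metric with an empty denominator is reported as ``None`` (undefined),
    never as 0.
    """
    return {
        "sensitivity": _ratio_pct(t.tp, t.tp + t.fn),
        "specificity": _ratio_pct(t.tn, t.tn + t.fp),
        "ppv": _ratio_pct(t.tp, t.tp + t.fp),
        "npv": _ratio_pct(t.tn, t.tn + t.fn),
        "accuracy": _ratio_pct(t.tp + t.tn, t.total),
    }


def odds_ratio(t: TwoByTwo, haldane: bool = False,
               alpha: float = 0.05) -> dict[str, float]:
    """Crude odds ratio with the Woolf (log-normal) confidence interval.

    OR = (tp*tn)/(fn*fp); CI = exp(ln OR +/- z * sqrt(sum of reciprocal
    cells)).  A zero cell raises unless ``haldane`` adds 0.5 to every cell.
    """
    a, b, c, d = float(t.tp), float(t.fn), float(t.fp), float(t.tn)
    if min(a, b, c, d) == 0:
        if not haldane:
            raise ValueError("zero cell; enable the Haldane correction")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = sps.norm.ppf(1 - alpha / 2)
    return {
        "or": or_,
        "ci_low": math.exp(math.log(or_) - z * se),
        "ci_high": math.exp(math.log(or_) + z * se),
    }


def disease_control_rate(recist_groups: Sequence) -> float:
    """Percentage of non-PD patients among all assessed."""
    groups = [str(getattr(g, "value", g)) for g in recist_groups]
    if not groups:
        raise ValueError("empty label list")
    bad = set(groups) - {"nPD", "PD"}
    if bad:
        raise ValueError(f"unknown dichotomized labels: {sorted(bad)}")
    return 100.0 * groups.count("nPD") / len(groups)


# ---------------------------------------------------------------------------
# group comparisons and correlation


def mann_whitney(group_a: Sequence[float], group_b: Sequence[float]
                 ) -> dict[str, float]:
    """Two-tailed Mann-Whitney U test.

    Exact null distribution when both groups have n <= 10 and there are no
    ties; tie-corrected normal approximation otherwise.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size <= 10 and b.size <= 10 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {"U": float(res.statistic), "p": float(res.pvalue), "method": method}


def chi_square(t: TwoByTwo) -> dict[str, float]:
    """Pearson chi-square on a 2x2 table, falling back to Fisher's exact
    test whenever any expected cell count is below 5."""
    table = np.array([[t.tp, t.fn], [t.fp, t.tn]], float)
    expected = sps.contingency.expected_freq(table)
    if np.any(expected < 5):
        _, p = sps.fisher_exact(table, alternative="two-sided")
        return {"statistic": math.nan, "p": float(p), "method": "fisher"}
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return {"statistic": float(chi2), "p": float(p), "method": "chi2"}


def spearman(x: Sequence[float], y: Sequence[float]) -> dict[str, float]:
    """Spearman rank correlation with two-tailed p."""
    rho, p = sps.spearmanr(x, y)
    return {"rho": float(rho), "p": float(p)}


# ---------------------------------------------------------------------------
# survival


@dataclass
class SurvivalFit:
    """Kaplan-Meier fit with median survival and its confidence interval."""

    kmf: KaplanMeierFitter
    median_months: float  # inf when the curve never reaches 0.5
    median_ci: tuple[float, float]
    label: str = ""
    n: int = 0
    events: int = 0

    def survival_at(self, t: float) -> float:
        return float(self.kmf.predict(t))


def km_fit(times: Sequence[float], events: Sequence[bool],
           label: str = "", alpha: float = 0.05) -> SurvivalFit:
    """Product-limit survival estimate.

    The median is the first time the survival curve drops to <= 0.5; its
    confidence interval comes from the crossing times of the pointwise
    survival bands (the Brookmeyer-Crowley construction).
    """
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    if np.any(times < 0):
        raise ValueError("survival times must be non-negative")
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(times, events, label=label or "KM")
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    return SurvivalFit(
        kmf=kmf,
        median_months=float(kmf.median_survival_time_),
        median_ci=(lo, hi),
        label=label,
        n=int(times.size),
        events=int(events.sum()),
    )


def log_rank(times_a, events_a, times_b, events_b) -> dict[str, float]:
    """Two-group log-rank test (two-tailed)."""
    res = logrank_test(times_a, times_b, event_observed_A=events_a,
                       event_observed_B=events_b)
    return {"statistic": float(res.test_statistic), "p": float(res.p_value)}


@dataclass(frozen=True)
class CutoffResult:
    """Outcome of the median-outward optimal-cutoff log-rank search."""

    cutoff: float
    p: float
    statistic: float
    n_low: int
    n_high: int
    median_low: float
    median_high: float
    trace: tuple[dict, ...] = field(repr=False)


def _median_outward_order(distinct: np.ndarray, median: float) -> list[int]:
    """Visit distinct values starting nearest the median, then alternately
    stepping to the next value above and below."""
    start = int(np.argmin(np.abs(distinct - median)))
    order = [start]
    up, down = start + 1, start - 1
    while up < distinct.size or down >= 0:
        if up < distinct.size:
            order.append(up)
            up += 1
        if down >= 0:
            order.append(down)
            down -= 1
    return order


def optimal_cutoff(values: Sequence[float],
                   times: Sequence[float],
                   events: Sequence[bool],
                   min_group_fraction: float = 0.15) -> CutoffResult:
    """Maximally selected log-rank cutoff with a median-outward search.

    Candidate cutoffs are the distinct observed values c, splitting patients
    into {value < c} vs {value >= c}.  Starting from the distinct value
    nearest the sample median the search alternately steps outward,
    evaluating the log-rank p for every candidate whose two groups both
    contain at least ``min_group_fraction`` of the cohort; the minimum-p
    eligible candidate wins (ties go to the candidate visited earlier, i.e.
    closer to the median).  The full trace is retained.
    """
    v = np.asarray(values, float)
    t = np.asarray(times, float)
    e = np.asarray(events, bool)
    if v.size != t.size or v.size != e.size:
        raise ValueError("values, times and events differ in length")
    distinct = np.unique(v)
    if distinct.size < 2:
        raise ValueError("need at least 2 distinct values to search for a cutoff")
    floor = min_group_fraction * v.size
    med = float(np.median(v))

    trace: list[dict] = []
    best: Optional[dict] = None
    for idx in _median_outward_order(distinct, med):
        c = float(distinct[idx])
        low = v < c
        n_low, n_high = int(low.sum()), int((~low).sum())
        eligible = n_low >= floor and n_high >= floor
        entry = {"cutoff": c, "n_low": n_low, "n_high": n_high,
                 "eligible": eligible, "statistic": math.nan, "p": math.nan}
        if eligible:
            lr = log_rank(t[low], e[low], t[~low], e[~low])
            entry.update(statistic=lr["statistic"], p=lr["p"])
            if best is None or lr["p"] < best["p"]:
                best = dict(entry)
        trace.append(entry)
    if best is None:
        raise ValueError("no candidate cutoff satisfies the group-size floor")

    low = v < best["cutoff"]
    return CutoffResult(
        cutoff=best["cutoff"],
        p=best["p"],
        statistic=best["statistic"],
        n_low=best["n_low"],
        n_high=best["n_high"],
        median_low=km_fit(t[low], e[low]).median_months,
        median_high=km_fit(t[~low], e[~low]).median_months,
        trace=tuple(trace),
    )


def cox_fit(covariates: pd.DataFrame,
            times: Sequence[float],
            events: Sequence[bool]) -> pd.DataFrame:
    """Cox proportional-hazards fit (partial likelihood, Efron ties).

    Returns one row per covariate with the hazard ratio, Wald 95% CI and p.
    Constant covariates and non-convergence raise explicit errors.
    """
    cov = covariates.astype(float)
    for col in cov.columns:
        if cov[col].nunique() < 2:
            raise ValueError(f"covariate {col!r} is constant")
    n_events = int(np.asarray(events, bool).sum())
    if n_events < cov.shape[1] + 1:
        raise ValueError("too few events for the number of covariates")
    df = cov.copy()
    df["_time"] = np.asarray(times, float)
    df["_event"] = np.asarray(events, bool).astype(int)
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="_time", event_col="_event")
    except Exception as exc:  # lifelines raises ConvergenceError/Warning subclasses
        raise RuntimeError(f"Cox model failed to converge: {exc}") from exc
    summ = cph.summary
    out = pd.DataFrame({
        "hr": summ["exp(coef)"],
        "ci_low": summ["exp(coef) lower 95%"],
        "ci_high": summ["exp(coef) upper 95%"],
        "p": summ["p"],
        "coef": summ["coef"],
        "se": summ["se(coef)"],
    })
    out.index.name = "covariate"
    return out


def logistic_fit(covariates: pd.DataFrame,
                 labels: Sequence[bool]) -> pd.DataFrame:
    """Logistic regression returning per-covariate OR, Wald 95% CI and p.

    Perfect separation raises an explicit error rather than returning a
    silently diverged fit.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    cov = covariates.astype(float)
    y = np.asarray(labels, bool).astype(int)
    X = sm.add_constant(cov, has_constant="add")
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        # separation drives coefficients to +/-inf and the Hessian singular
        raise RuntimeError("perfect separation in logistic regression") from exc
    if not fit.mle_retvals.get("converged", True) or np.any(np.abs(fit.params) > 30):
        raise RuntimeError("logistic regression did not converge (possible separation)")
    params = fit.params.drop("const")
    conf = fit.conf_int().drop(index="const")
    out = pd.DataFrame({
        "or": np.exp(params),
        "ci_low": np.exp(conf[0]),
        "ci_high": np.exp(conf[1]),
        "p": fit.pvalues.drop("const"),
        "coef": params,
        "se": fit.bse.drop("const"),
    })
    out.index.name = "covariate"
    return out


def roc_cutoff(scores: Sequence[float], labels: Sequence[bool]
               ) -> dict[str, float]:
    """ROC AUC and the Youden-optimal cutoff (max sensitivity+specificity-1)."""
    from sklearn.metrics import roc_auc_score, roc_curve

    y = np.asarray(labels, bool).astype(int)
    s = np.asarray(scores, float)
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    auc = float(roc_auc_score(y, s))
    fpr, tpr, thr = roc_curve(y, s)
    j = tpr - fpr
    return {"auc": auc, "cutoff": float(thr[int(np.argmax(j))]),
            "youden_j": float(j.max())}
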