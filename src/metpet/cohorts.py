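"""Simulated patient cohorts with known statistical structure.

The generator emulates the study population the outcome statistics are
designed for: advanced EGFR-mutant lung adenocarcinoma patients on
first-line EGFR-TKI therapy, each carrying

* a quantitative EGFR-mutation burden ``dct`` (delta cycle threshold from
  allele-specific PCR; lower = more mutant allele),
* a baseline metabolic tumor burden ``bsum_mtv`` (cm^3, sum over target
  lesions), log-normally distributed and positively coupled to dCt,
* a PERCIST responder flag, a 3-month RECIST label (nPD / PD) drawn from a
  logistic model, and
* PFS / OS event times from a proportional-hazards model on dichotomized
  predictors with independent uniform censoring on [0, horizon].

Defaults encode the study-scale conditions: n = 30, dCt dichotomized at 6
cycles, bsumMTV at 40 cm^3, exponential baseline hazards whose reference
stratum (all risk flags low) has median PFS 19.5 and OS 30.9 months,
administrative censoring horizon 33 months, and hazard ratios 4.85 (high
dCt) and 5.60 (high burden) on PFS and 9.84 (high dCt) on OS.  Because the
hazard model concentrates risk in the flagged strata, the cohort-wide
marginal medians come out shorter than the reference stratum's — the
model's point is known structure for parameter-recovery tests, not marginal
curve matching.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

LN2 = math.log(2.0)


def _default_response_model() -> dict[str, float]:
    # P(nPD | responder) ~ 0.95, P(nPD | non-responder) ~ 0.44
    return {"intercept": -0.22, "percist_responder": 3.22}


def _default_log_hazard() -> dict[str, dict[str, float]]:
    return {
        "pfs": {"dct_high": math.log(4.85), "mtv_high": math.log(5.60)},
        "os": {"dct_high": math.log(9.84)},
    }


def _default_baseline_median() -> dict[str, float]:
    # reference-stratum (all risk flags low) medians, months
    return {"pfs": 19.5, "os": 30.9}


@dataclass(frozen=True)
class CohortSimSpec:
    """Generative parameters for one simulated cohort."""

    n: int = 30
    rng_seed: int = 0
    # dCt: cycles, roughly normal on its native (log-abundance) scale
    dct_mean: float = 6.0
    dct_sd: float = 2.5
    # baseline metabolic burden: log(bsumMTV) = log_mean + burden_link*(dct - dct_mean) + eps
    burden_link: float = 0.25
    mtv_log_mean: float = math.log(40.0)
    mtv_log_sd: float = 1.0
    # responder flag and the logistic model for the 3-month non-PD label
    responder_rate: float = 0.7
    response_model: dict[str, float] = field(default_factory=_default_response_model)
    # dichotomization thresholds used to build hazard covariates
    dct_threshold: float = 6.0
    mtv_threshold_cm3: float = 40.0
    # proportional-hazards structure per endpoint
    log_hazard: dict[str, dict[str, float]] = field(default_factory=_default_log_hazard)
    baseline_median_months: dict[str, float] = field(default_factory=_default_baseline_median)
    weibull_shape: float = 1.0  # 1.0 = exponential
    censoring_horizon_months: float = 33.0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("cohort size must be at least 2")
        if self.censoring_horizon_months <= 0:
            raise ValueError("censoring horizon must be positive")
        if self.dct_sd < 0 or self.mtv_log_sd < 0:
            raise ValueError("spread parameters must be non-negative")
        if not 0.0 <= self.responder_rate <= 1.0:
            raise ValueError("responder rate must lie in [0, 1]")
        if self.weibull_shape <= 0:
            raise ValueError("Weibull shape must be positive")


def _draw_times(rng: np.random.Generator, linpred: np.ndarray,
                median: float, shape: float) -> np.ndarray:
    """Event times under a Weibull PH model; shape 1 reduces to exponential.

    The baseline hazard scale is set so that the linpred = 0 stratum has the
    requested median: S(t) = exp(-lambda0 * t**shape * exp(xb)).
    """
    lam0 = LN2 / median**shape
    u = rng.uniform(size=linpred.shape)
    return (-np.log(u) / (lam0 * np.exp(linpred))) ** (1.0 / shape)


def make_cohort(spec: CohortSimSpec) -> tuple[pd.DataFrame, dict]:
    """Simulate a cohort table and return it with the true parameters.

    The table has one row per patient with clinical covariates, imaging
    summaries, the 3-month RECIST dichotomy, and censored PFS/OS times.
    Deterministic given ``spec.rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n

    age = np.clip(rng.normal(70.0, 10.0, n), 40, 91).round(0)
    sex = np.where(rng.uniform(size=n) < 0.6, "female", "male")
    smoking = np.where(rng.uniform(size=n) < 0.4, "ever", "never")
    cea = np.exp(rng.normal(2.0, 1.5, n))  # ng/mL, long right tail
    classical_mutation = rng.uniform(size=n) < 0.8

    dct = rng.normal(spec.dct_mean, spec.dct_sd, n)
    eps = rng.normal(0.0, spec.mtv_log_sd, n)
    bsum_mtv = np.exp(spec.mtv_log_mean + spec.burden_link * (dct - spec.dct_mean) + eps)
    bsum_tlg = bsum_mtv * np.exp(rng.normal(math.log(6.0), 0.4, n))  # TLG ~ mean SUL x MTV

    responder = rng.uniform(size=n) < spec.responder_rate

    df = pd.DataFrame({
        "id": [f"P{i + 1:03d}" for i in range(n)],
        "age": age,
        "sex": sex,
        "smoking": smoking,
        "cea": cea,
        "classical_mutation": classical_mutation,
        "dct": dct,
        "bsum_mtv": bsum_mtv,
        "bsum_tlg": bsum_tlg,
        "percist_responder": responder,
    })
    df["dct_high"] = df["dct"] >= spec.dct_threshold
    df["mtv_high"] = df["bsum_mtv"] >= spec.mtv_threshold_cm3

    # 3-month non-PD label from the logistic response model
    logit = np.full(n, spec.response_model.get("intercept", 0.0))
    for name, beta in spec.response_model.items():
        if name == "intercept":
            continue
        if name not in df.columns:
            raise ValueError(f"response model refers to unknown column {name!r}")
        logit = logit + beta * df[name].to_numpy(dtype=float)
    p_npd = 1.0 / (1.0 + np.exp(-logit))
    npd = rng.uniform(size=n) < p_npd
    df["recist_3mo"] = np.where(npd, "nPD", "PD")

    # survival endpoints
    for endpoint in ("pfs", "os"):
        betas = spec.log_hazard.get(endpoint, {})
        linpred = np.zeros(n)
        for name, beta in betas.items():
            if name not in df.columns:
                raise ValueError(f"{endpoint} hazard refers to unknown column {name!r}")
            linpred = linpred + beta * df[name].to_numpy(dtype=float)
        t_event = _draw_times(rng, linpred,
                              spec.baseline_median_months[endpoint],
                              spec.weibull_shape)
        t_cens = rng.uniform(0.0, spec.censoring_horizon_months, n)
        df[f"{endpoint}_months"] = np.minimum(t_event, t_cens)
        df[f"{endpoint}_event"] = t_event <= t_cens

    truth = {
        "dct_threshold": spec.dct_threshold,
        "mtv_threshold_cm3": spec.mtv_threshold_cm3,
        "burden_link": spec.burden_link,
        "log_hazard": {k: dict(v) for k, v in spec.log_hazard.items()},
        "baseline_median_months": dict(spec.baseline_median_months),
        "response_model": dict(spec.response_model),
        "weibull_shape": spec.weibull_shape,
        "censoring_horizon_months": spec.censoring_horizon_months,
    }
    return df, truth
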