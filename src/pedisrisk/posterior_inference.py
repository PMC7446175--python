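"""Inference from posterior draws: HDIs, coefficient and odds-ratio summaries,
null-exclusion decisions, tail probabilities, posterior AUC distributions,
model comparison, and per-patient risk prediction.

Everything here consumes a :class:`~pedisrisk.bayes_logistic.PosteriorDraws`
(or raw sample arrays) — it is agnostic to how the draws were sampled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bayes_logistic import PosteriorDraws, build_design, design_row, inverse_logit
from .pedis_data import Cohort, ValidationError

__all__ = [
    "HdiInterval",
    "CoefficientSummary",
    "AucPosterior",
    "ModelComparison",
    "RiskPrediction",
    "hdi",
    "coefficient_summary",
    "summary_table",
    "null_exclusion",
    "tail_probability",
    "auc",
    "posterior_auc",
    "compare_models",
    "predict_risk",
]


@dataclass(frozen=True)
class HdiInterval:
    """Highest density interval: the narrowest window holding ``mass`` of the
    samples; every value inside has higher density than any value outside
    (under unimodality)."""

    lower: float
    upper: float
    mass: float = 0.95

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValidationError("HDI lower bound above upper bound")

    def width(self) -> float:
        return self.upper - self.lower


def hdi(samples, mass: float = 0.95) -> HdiInterval:
    """Sample-based HDI by exhaustive sorted-window search.

    Sort the samples, take window length m = ceil(mass·n) and return the
    narrowest window [x_(i), x_(i+m-1)]; width ties resolve to the smallest i.
    Assumes a unimodal posterior (the usual case for regression coefficients).
    """
    x = np.sort(np.asarray(samples, dtype=float))
    if x.size < 2:
        raise ValidationError("hdi requires at least 2 samples")
    if np.any(np.isnan(x)):
        raise ValidationError("hdi input contains NaN")
    if not 0 < mass < 1:
        raise ValidationError(f"mass must be in (0, 1), got {mass}")
    m = int(math.ceil(mass * x.size))
    widths = x[m - 1 :] - x[: x.size - m + 1]
    i = int(np.argmin(widths))  # argmin returns the first minimum: smallest i
    return HdiInterval(float(x[i]), float(x[i + m - 1]), mass)


def null_exclusion(interval: HdiInterval, null_value: float = 0.0) -> bool:
    """True iff the HDI excludes the null value; a null on the boundary counts
    as covered (no association claimed)."""
    return null_value < interval.lower or null_value > interval.upper


def tail_probability(samples, threshold: float = 0.0) -> float:
    """Fraction of draws strictly below the threshold."""
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValidationError("tail_probability requires non-empty draws")
    return float(np.mean(x < threshold))


@dataclass(frozen=True)
class CoefficientSummary:
    """Posterior summary of one coefficient on both the log-odds and OR scales.

    ``odds_ratio`` is exactly exp(median_beta); the OR interval is the
    endpoint-exponentiated beta HDI (a convention, since HDIs are not
    transform-invariant). ``associated`` is the null-exclusion decision on the
    beta scale.
    """

    name: str
    median_beta: float
    beta_hdi: HdiInterval
    odds_ratio: float
    or_hdi: HdiInterval
    prob_below_null: float
    associated: bool


def coefficient_summary(draws: PosteriorDraws, name: str, mass: float = 0.95) -> CoefficientSummary:
    samples = draws.column(name)
    median = float(np.median(samples))
    beta_hdi = hdi(samples, mass)
    return CoefficientSummary(
        name=name,
        median_beta=median,
        beta_hdi=beta_hdi,
        odds_ratio=math.exp(median),
        or_hdi=HdiInterval(math.exp(beta_hdi.lower), math.exp(beta_hdi.upper), mass),
        prob_below_null=tail_probability(samples, 0.0),
        associated=null_exclusion(beta_hdi, 0.0),
    )


def summary_table(draws: PosteriorDraws, mass: float = 0.95) -> pd.DataFrame:
    """One row per predictor: beta median and HDI, OR and OR HDI,
    P(beta < 0), and the association verdict."""
    rows = []
    for name in draws.names:
        s = coefficient_summary(draws, name, mass)
        rows.append(
            dict(predictor=s.name, beta_median=s.median_beta,
                 beta_hdi_low=s.beta_hdi.lower, beta_hdi_high=s.beta_hdi.upper,
                 odds_ratio=s.odds_ratio,
                 or_hdi_low=s.or_hdi.lower, or_hdi_high=s.or_hdi.upper,
                 prob_below_null=s.prob_below_null, associated=s.associated)
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


def auc(scores, labels) -> float:
    """Rank-based (Mann–Whitney) area under the ROC curve.

    Equals the probability that a random positive outscores a random negative,
    counting tied score pairs as 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("auc requires both outcome classes")
    ranks = stats.rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class AucPosterior:
    """One apparent AUC per posterior draw, summarised by median and HDI."""

    auc_draws: np.ndarray
    median: float
    hdi: HdiInterval

    def __post_init__(self) -> None:
        if np.any((self.auc_draws < 0) | (self.auc_draws > 1)):
            raise ValidationError("AUC draws must lie in [0, 1]")


def posterior_auc(draws: PosteriorDraws, cohort: Cohort, thin: int = 1,
                  mass: float = 0.95) -> AucPosterior:
    """Posterior distribution of the apparent (in-sample) AUC.

    For each retained coefficient draw, predicted probabilities for every
    fit-eligible patient are scored against the observed outcomes by
    Mann–Whitney AUC. ``thin`` evaluates every k-th draw for speed. The result
    is invariant to any strictly increasing transform of the per-patient
    scores within a draw (ranks only).
    """
    if thin < 1:
        raise ValidationError("thin must be >= 1")
    X, y, _ = build_design(cohort, draws.model_spec)
    if len(np.unique(y)) < 2:
        raise ValidationError("cohort must contain both outcome classes")
    B = draws.draws[::thin]
    eta = X @ B.T  # (n_patients, n_draws); monotone in probability
    pos = y == 1
    n_pos = int(pos.sum())
    n_neg = int(y.size - n_pos)
    ranks = stats.rankdata(eta, axis=0)
    aucs = (ranks[pos].sum(axis=0) - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    aucs = np.asarray(aucs, dtype=float)
    if aucs.size >= 2:
        interval = hdi(aucs, mass)
    else:
        interval = HdiInterval(float(aucs[0]), float(aucs[0]), mass)
    return AucPosterior(aucs, float(np.median(aucs)), interval)


@dataclass(frozen=True)
class ModelComparison:
    """Difference between two posterior AUC distributions.

    ``delta_auc`` = median(B) − median(A); ``cohens_d`` is the standardized
    mean difference with the pooled-SD convention
    sqrt((sd_A² + sd_B²)/2). Antisymmetric under swapping the models.
    """

    delta_auc: float
    cohens_d: float


def compare_models(auc_a: AucPosterior, auc_b: AucPosterior) -> ModelComparison:
    a, b = auc_a.auc_draws, auc_b.auc_draws
    sd_a = float(a.std(ddof=1))
    sd_b = float(b.std(ddof=1))
    pooled = math.sqrt((sd_a**2 + sd_b**2) / 2)
    if pooled == 0:
        if float(b.mean() - a.mean()) == 0.0:
            return ModelComparison(float(auc_b.median - auc_a.median), 0.0)
        raise ValidationError("Cohen's d undefined: zero pooled SD with unequal means")
    return ModelComparison(
        delta_auc=float(auc_b.median - auc_a.median),
        cohens_d=float((b.mean() - a.mean()) / pooled),
    )


@dataclass
class RiskPrediction:
    """Posterior predictive amputation risk for one covariate profile."""

    profile: dict
    risk_draws: np.ndarray
    median_risk: float
    hdi: HdiInterval


def predict_risk(draws: PosteriorDraws, profile: dict, mass: float = 0.95) -> RiskPrediction:
    """Per-draw predicted probability for a validated covariate profile.

    The profile must state all predictors explicitly, including age (years)
    and gender — the coding (age z-scoring, male=1) is taken from the model
    spec of the fit, so predictions and fit are guaranteed consistent.
    """
    x = design_row(profile, draws.model_spec)
    risks = inverse_logit(draws.draws @ x)
    risks = np.atleast_1d(risks)
    if risks.size >= 2:
        interval = hdi(risks, mass)
    else:
        interval = HdiInterval(float(risks[0]), float(risks[0]), mass)
    return RiskPrediction(dict(profile), risks, float(np.median(risks)), interval)
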