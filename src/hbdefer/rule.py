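"""The historical-mean eligibility rule for a single visit.

A repeat donor is deferred for one of two reasons:

* **reason A** — the bound on their historical mean Hb falls below the legal
  deferral threshold. With alpha_mean = 0 the bound is the mean itself; with a
  negative (positive) alpha_mean it is the lower (upper) limit of the
  two-sided |alpha_mean|x100% confidence interval
  ``hist_mean ± z_{(1+|alpha|)/2} * sigma / sqrt(n)``.
* **reason B** — the mean is acceptable but the visit's single measurement is
  a low outlier: ``hb < hist_mean - z_{alpha_outlier} * sigma * a`` with
  ``a = sqrt(1 + 1/n)`` when the prediction-interval adjustment is enabled
  and 1 otherwise.

This mimics a control chart: the historical mean plays the in-control level
and the outlier cutoff the lower control limit. The rule needs at least
``min_prior_measurements`` prior measurements (default 2), so a donor's first
two visits are never assessed.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .model import (
    DonorHistory,
    PolicyConfig,
    Sex,
    VariabilityEstimate,
    VisitAssessment,
)

__all__ = [
    "normal_quantile",
    "mean_bound",
    "outlier_cutoff",
    "assess_visit",
    "assess_donor",
]


def normal_quantile(p: float) -> float:
    """Standard-normal quantile: the z with Phi(z) = p, for p in (0, 1)."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"probability must lie strictly in (0, 1), got {p}")
    return float(norm.ppf(p))


def mean_bound(
    hist_mean: float, n_prior: int, sigma: float, alpha_mean: float
) -> float:
    """Bound on the historical mean compared to the deferral threshold.

    Returns ``hist_mean`` when alpha_mean is 0, otherwise
    ``hist_mean + sign(alpha_mean) * z * sigma / sqrt(n_prior)`` with
    ``z = Phi^-1((1 + |alpha_mean|) / 2)`` — the lower (negative alpha) or
    upper (positive alpha) limit of the two-sided confidence interval.
    """
    if not -1.0 < alpha_mean < 1.0:
        raise ValueError(f"alpha_mean must lie strictly in (-1, 1), got {alpha_mean}")
    if n_prior < 1:
        raise ValueError("mean_bound requires at least one prior measurement")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if alpha_mean == 0.0:
        return float(hist_mean)
    z = normal_quantile((1.0 + abs(alpha_mean)) / 2.0)
    return float(hist_mean + math.copysign(z, alpha_mean) * sigma / math.sqrt(n_prior))


def outlier_cutoff(
    hist_mean: float,
    sigma: float,
    alpha_outlier: float,
    n_prior: int | None = None,
    prediction_adjustment: bool = False,
) -> float:
    """Hb level below which a single measurement counts as a low outlier.

    ``cutoff = hist_mean - z_{alpha_outlier} * sigma * a`` where
    ``a = sqrt(1 + 1/n_prior)`` if the prediction-interval adjustment is on
    (accounting for the sampling error of the historical mean itself) and
    1 otherwise.
    """
    if not 0.5 < alpha_outlier < 1.0:
        raise ValueError(
            f"alpha_outlier must lie strictly in (0.5, 1), got {alpha_outlier}"
        )
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    a = 1.0
    if prediction_adjustment:
        if n_prior is None or n_prior < 1:
            raise ValueError("prediction adjustment requires n_prior >= 1")
        a = math.sqrt(1.0 + 1.0 / n_prior)
    return float(hist_mean - normal_quantile(alpha_outlier) * sigma * a)


def assess_visit(
    prior_hbs: Sequence[float],
    hb: float,
    sex: Sex,
    sigma: float,
    config: PolicyConfig,
    donor_id: str = "",
    visit_date=None,
) -> VisitAssessment:
    """Assess one visit given the donor's prior measurements.

    The historical mean is formed from ``prior_hbs`` only — the current
    measurement never enters its own reference level. Decision order:
    not_assessed if too few priors; else defer_A if the mean bound is below
    the threshold; else defer_B if the measurement is a low outlier; else
    eligible. The current single-measurement policy defers iff hb is strictly
    below the threshold (equality donates).
    """
    threshold = config.threshold(sex)
    current = "defer" if hb < threshold else "donate"
    n_prior = len(prior_hbs)

    if n_prior < config.min_prior_measurements:
        return VisitAssessment(
            donor_id=donor_id,
            visit_date=visit_date,
            sex=sex,
            hb=float(hb),
            n_prior=n_prior,
            hist_mean=math.nan,
            ci_bound=math.nan,
            outlier_cutoff=math.nan,
            current_decision=current,
            alt_decision="not_assessed",
            reason="NA",
        )

    hist_mean = float(np.mean(np.asarray(prior_hbs, dtype=float)))
    bound = mean_bound(hist_mean, n_prior, sigma, config.alpha_mean)
    cutoff = outlier_cutoff(
        hist_mean,
        sigma,
        config.alpha_outlier,
        n_prior=n_prior,
        prediction_adjustment=config.prediction_adjustment,
    )

    if bound < threshold:
        alt, reason = "defer_A", "A"
    elif hb < cutoff and (
        not config.outlier_requires_below_threshold or hb < threshold
    ):
        alt, reason = "defer_B", "B"
    else:
        alt, reason = "eligible", ""

    return VisitAssessment(
        donor_id=donor_id,
        visit_date=visit_date,
        sex=sex,
        hb=float(hb),
        n_prior=n_prior,
        hist_mean=hist_mean,
        ci_bound=bound,
        outlier_cutoff=cutoff,
        current_decision=current,
        alt_decision=alt,
        reason=reason,
    )


def _prior_values(
    hbs: np.ndarray, k: int, threshold: float, config: PolicyConfig
) -> np.ndarray:
    prior = hbs[:k]
    if config.history_scope == "donations_only":
        prior = prior[prior >= threshold]
    if config.max_history is not None:
        prior = prior[-config.max_history :]
    return prior


def assess_donor(
    history: DonorHistory,
    estimates: VariabilityEstimate,
    config: PolicyConfig,
) -> list[VisitAssessment]:
    """Assess every visit of one donor chronologically.

    The assessment is static: alternative decisions never alter which
    measurements enter later histories. Under
    ``history_scope='donations_only'`` the reference history is restricted to
    visits where a donation took place under the current policy (hb at or
    above the threshold); ``max_history`` caps the history to the most recent
    measurements.
    """
    sex = history.sex
    sigma = estimates.sigma(sex)
    threshold = config.threshold(sex)
    hbs = history.hbs()
    out: list[VisitAssessment] = []
    for k, visit in enumerate(history.visits):
        prior = _prior_values(hbs, k, threshold, config)
        out.append(
            assess_visit(
                prior,
                visit.hb,
                sex,
                sigma,
                config,
                donor_id=history.donor_id,
                visit_date=visit.visit_date,
            )
        )
    return out
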