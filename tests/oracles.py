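"""Independent brute-force oracles used to check the implementation.

Deliberately primitive: the normal quantile is inverted by bisection on an
erf-based CDF, means are taken with :mod:`statistics`, and the deferral rule
is re-evaluated from scratch at every visit. Nothing here shares code with
the package.
"""

from __future__ import annotations

import math
import statistics


def normal_cdf(z: float) -> float:
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


def normal_quantile_bisect(p: float, tol: float = 1e-12) -> float:
    lo, hi = -10.0, 10.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if normal_cdf(mid) < p:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def naive_assess(
    prior_hbs,
    hb: float,
    threshold: float,
    sigma: float,
    alpha_mean: float = 0.0,
    alpha_outlier: float = 0.999,
    min_prior: int = 2,
    prediction_adjustment: bool = False,
    outlier_requires_below_threshold: bool = False,
):
    """From-scratch single-visit decision; returns (alt_decision, hist_mean,
    bound, cutoff) with NaNs when not assessed."""
    n = len(prior_hbs)
    if n < min_prior:
        return "not_assessed", math.nan, math.nan, math.nan
    hist_mean = statistics.mean(prior_hbs)
    if alpha_mean == 0.0:
        bound = hist_mean
    else:
        z = normal_quantile_bisect((1.0 + abs(alpha_mean)) / 2.0)
        bound = hist_mean + (z if alpha_mean > 0 else -z) * sigma / math.sqrt(n)
    a = math.sqrt(1.0 + 1.0 / n) if prediction_adjustment else 1.0
    cutoff = hist_mean - normal_quantile_bisect(alpha_outlier) * sigma * a
    if bound < threshold:
        decision = "defer_A"
    elif hb < cutoff and (not outlier_requires_below_threshold or hb < threshold):
        decision = "defer_B"
    else:
        decision = "eligible"
    return decision, hist_mean, bound, cutoff


def naive_assess_donor(
    hbs,
    threshold: float,
    sigma: float,
    history_scope: str = "all_visits",
    max_history: int | None = None,
    **rule_kwargs,
):
    """Visit-by-visit re-evaluation of a whole career."""
    out = []
    for k in range(len(hbs)):
        prior = list(hbs[:k])
        if history_scope == "donations_only":
            prior = [x for x in prior if x >= threshold]
        if max_history is not None:
            prior = prior[-max_history:]
        out.append(naive_assess(prior, hbs[k], threshold, sigma, **rule_kwargs))
    return out
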