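"""Retrospective policy re-assessment over a full visit dataset.

Every visit with enough prior measurements is relabelled under the
historical-mean algorithm while keeping the current single-measurement
decision, yielding four counts over assessed visits: current deferrals
``d_cur``, alternative deferrals ``d_alt``, newly deferred visits (currently
donating, alternatively deferred) and newly eligible visits (currently
deferred, alternatively eligible). These satisfy the accounting identity
``d_alt - d_cur = newly_deferred - newly_eligible`` exactly.

Percentage conventions: deferral rates and the newly-deferred share are per
assessed visit; the net change in donations is per current-policy donation
(assessed visits minus current deferrals), so
``pct_change_donations = (rate_cur - rate_alt) / (1 - rate_cur/100)``.

The relabelling is static — alternative decisions never feed back into later
histories — and ignores deferral periods and minimum donation intervals, as a
retrospective counterfactual must.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import histories_to_frame
from .model import (
    DonorHistory,
    EvaluationReport,
    PolicyConfig,
    Sex,
    VariabilityEstimate,
)
from .rule import normal_quantile

__all__ = [
    "evaluate_policy",
    "assess_frame",
    "compute_report_metrics",
    "change_in_donations_from_rates",
    "sweep_parameters",
    "filter_recent_other_donations",
]


def _history_stats(df: pd.DataFrame, config: PolicyConfig) -> pd.DataFrame:
    """Per-visit count and sum of the prior reference measurements.

    Vectorised for the common case; the ``max_history`` cap falls back to a
    per-donor pass.
    """
    out = df.copy()
    thr = np.where(out["sex"].to_numpy() == Sex.MALE.value,
                   config.threshold_male, config.threshold_female)
    out["threshold"] = thr

    if config.max_history is None:
        grp = out.groupby("donor_id", sort=False)
        if config.history_scope == "donations_only":
            eligible = (out["hb"].to_numpy() >= thr).astype(float)
            contrib = out["hb"].to_numpy() * eligible
            out["_elig"] = eligible
            out["_contrib"] = contrib
            g = out.groupby("donor_id", sort=False)
            out["n_prior"] = (g["_elig"].cumsum() - out["_elig"]).astype(int)
            out["prior_sum"] = g["_contrib"].cumsum() - out["_contrib"]
            out = out.drop(columns=["_elig", "_contrib"])
        else:
            out["n_prior"] = grp.cumcount()
            out["prior_sum"] = grp["hb"].cumsum() - out["hb"]
    else:
        n_prior = np.empty(len(out), dtype=int)
        prior_sum = np.empty(len(out), dtype=float)
        pos = 0
        for _, sub in out.groupby("donor_id", sort=False):
            hbs = sub["hb"].to_numpy()
            t = sub["threshold"].to_numpy()
            for k in range(len(hbs)):
                prior = hbs[:k]
                if config.history_scope == "donations_only":
                    prior = prior[prior >= t[:k]]
                prior = prior[-config.max_history:]
                n_prior[pos] = prior.size
                prior_sum[pos] = prior.sum()
                pos += 1
        out["n_prior"] = n_prior
        out["prior_sum"] = prior_sum
    return out


def _sigma_per_row(
    df: pd.DataFrame, estimates: VariabilityEstimate
) -> np.ndarray:
    sex_codes = df["sex"].to_numpy()
    sigma = np.full(len(df), np.nan)
    for sex in (Sex.MALE, Sex.FEMALE):
        mask = sex_codes == sex.value
        if mask.any():
            sigma[mask] = estimates.sigma(sex)  # raises if unusable
    return sigma


def _decide(
    stats: pd.DataFrame,
    sigma: np.ndarray,
    config: PolicyConfig,
    alpha_mean: float | None = None,
    alpha_outlier: float | None = None,
) -> pd.DataFrame:
    """Apply the deferral rules to precomputed history statistics."""
    a_mean = config.alpha_mean if alpha_mean is None else alpha_mean
    a_out = config.alpha_outlier if alpha_outlier is None else alpha_outlier
    if not -1.0 < a_mean < 1.0:
        raise ValueError(f"alpha_mean out of (-1, 1): {a_mean}")
    if not 0.5 < a_out < 1.0:
        raise ValueError(f"alpha_outlier out of (0.5, 1): {a_out}")

    df = stats.copy()
    hb = df["hb"].to_numpy(dtype=float)
    thr = df["threshold"].to_numpy(dtype=float)
    n_prior = df["n_prior"].to_numpy(dtype=float)
    assessed = n_prior >= config.min_prior_measurements

    with np.errstate(invalid="ignore", divide="ignore"):
        hist_mean = np.where(n_prior > 0, df["prior_sum"].to_numpy() / n_prior, np.nan)
        if a_mean == 0.0:
            bound = hist_mean
        else:
            z = normal_quantile((1.0 + abs(a_mean)) / 2.0)
            bound = hist_mean + math.copysign(z, a_mean) * sigma / np.sqrt(n_prior)
        adj = (
            np.sqrt(1.0 + 1.0 / n_prior)
            if config.prediction_adjustment
            else np.ones_like(n_prior)
        )
        cutoff = hist_mean - normal_quantile(a_out) * sigma * adj

    low_outlier = hb < cutoff
    if config.outlier_requires_below_threshold:
        low_outlier &= hb < thr
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # NaN comparisons on unassessed rows
        alt = np.select(
            [~assessed, bound < thr, low_outlier],
            ["not_assessed", "defer_A", "defer_B"],
            default="eligible",
        )
    reason = np.select(
        [alt == "not_assessed", alt == "defer_A", alt == "defer_B"],
        ["NA", "A", "B"],
        default="",
    )

    df["n_prior"] = df["n_prior"].astype(int)
    df["hist_mean"] = np.where(assessed, hist_mean, np.nan)
    df["ci_bound"] = np.where(assessed, bound, np.nan)
    df["outlier_cutoff"] = np.where(assessed, cutoff, np.nan)
    df["current_decision"] = np.where(hb < thr, "defer", "donate")
    df["alt_decision"] = alt
    df["reason"] = reason
    return df


def assess_frame(
    histories: Iterable[DonorHistory] | pd.DataFrame,
    estimates: VariabilityEstimate,
    config: PolicyConfig,
) -> pd.DataFrame:
    """Assess every visit of every donor; vectorised counterpart of
    :func:`hbdefer.rule.assess_donor`."""
    df = (
        histories
        if isinstance(histories, pd.DataFrame)
        else histories_to_frame(histories)
    )
    stats = _history_stats(df, config)
    sigma = _sigma_per_row(stats, estimates)
    return _decide(stats, sigma, config)


def compute_report_metrics(
    d_cur: int,
    d_alt: int,
    newly_deferred: int,
    newly_eligible: int,
    n_visits_assessed: int,
) -> dict:
    """Percentage metrics from the four assessment counts.

    Enforces the accounting identity ``d_alt - d_cur = newly_deferred -
    newly_eligible``; a violation signals an upstream bug. Ratios with a zero
    denominator are reported as None rather than a number. No rounding is
    applied here — rounding belongs to presentation only.
    """
    if n_visits_assessed <= 0:
        raise ValueError("no assessed visits")
    for name, v in [
        ("d_cur", d_cur),
        ("d_alt", d_alt),
        ("newly_deferred", newly_deferred),
        ("newly_eligible", newly_eligible),
    ]:
        if v < 0:
            raise ValueError(f"negative count {name}={v}")
    if d_alt - d_cur != newly_deferred - newly_eligible:
        raise ValueError(
            "accounting identity violated: "
            f"d_alt - d_cur = {d_alt - d_cur} but "
            f"newly_deferred - newly_eligible = {newly_deferred - newly_eligible}"
        )
    rate_cur = 100.0 * d_cur / n_visits_assessed
    rate_alt = 100.0 * d_alt / n_visits_assessed
    pct_change_deferrals = (
        100.0 * (d_alt - d_cur) / d_cur if d_cur > 0 else None
    )
    n_donations_cur = n_visits_assessed - d_cur
    pct_change_donations = (
        100.0 * (newly_eligible - newly_deferred) / n_donations_cur
        if n_donations_cur > 0
        else None
    )
    return {
        "rate_cur": rate_cur,
        "rate_alt": rate_alt,
        "pct_change_deferrals": pct_change_deferrals,
        "pct_newly_deferred": 100.0 * newly_deferred / n_visits_assessed,
        "pct_change_donations": pct_change_donations,
    }


def change_in_donations_from_rates(rate_cur: float, rate_alt: float) -> float:
    """Net change in donations (%) implied by the two deferral rates:
    ``(rate_cur - rate_alt) / (1 - rate_cur/100)``."""
    return (rate_cur - rate_alt) / (1.0 - rate_cur / 100.0)


def _tally(assessed: pd.DataFrame, n_donors: int) -> EvaluationReport:
    cur_defer = assessed["current_decision"].to_numpy() == "defer"
    alt = assessed["alt_decision"].to_numpy()
    alt_defer = (alt == "defer_A") | (alt == "defer_B")
    newly_deferred = int((~cur_defer & alt_defer).sum())
    newly_eligible = int((cur_defer & (alt == "eligible")).sum())
    d_cur = int(cur_defer.sum())
    d_alt = int(alt_defer.sum())
    n = len(assessed)
    metrics = compute_report_metrics(d_cur, d_alt, newly_deferred, newly_eligible, n)

    means: dict[str, float] = {}
    # sort so the mean is independent of donor processing order
    newly_eligible_rows = assessed[cur_defer & (alt == "eligible")].sort_values(
        ["donor_id", "date"], kind="stable"
    )
    for sex in (Sex.MALE, Sex.FEMALE):
        sub = newly_eligible_rows[newly_eligible_rows["sex"] == sex.value]
        means[sex.value] = float(sub["hist_mean"].mean()) if len(sub) else math.nan

    return EvaluationReport(
        n_donors=n_donors,
        n_visits_assessed=n,
        d_cur=d_cur,
        d_alt=d_alt,
        newly_deferred=newly_deferred,
        newly_eligible=newly_eligible,
        mean_hist_mean_newly_eligible_male=means[Sex.MALE.value],
        mean_hist_mean_newly_eligible_female=means[Sex.FEMALE.value],
        **metrics,
    )


def evaluate_policy(
    histories: Sequence[DonorHistory],
    estimates: VariabilityEstimate,
    config: PolicyConfig,
) -> tuple[EvaluationReport, pd.DataFrame]:
    """Re-assess a full dataset and summarise it as an evaluation report.

    Visits that cannot be assessed (fewer prior measurements than required,
    i.e. each donor's first visits) are excluded from every count and
    denominator. Returns the report and the full per-visit assessment table.
    """
    assessments = assess_frame(histories, estimates, config)
    assessed = assessments[assessments["alt_decision"] != "not_assessed"]
    if assessed.empty:
        raise ValueError(
            "no assessable visits: every donor has fewer than "
            f"{config.min_prior_measurements + 1} visits"
        )
    n_donors = assessments["donor_id"].nunique()
    return _tally(assessed, n_donors), assessments


DEFAULT_ALPHA_MEAN_GRID = tuple(np.linspace(-0.999, 0.999, 21))
DEFAULT_ALPHA_OUTLIER_SET = (0.99, 0.999, 0.9999)


def sweep_parameters(
    histories: Sequence[DonorHistory],
    estimates: VariabilityEstimate,
    base_config: PolicyConfig,
    alpha_mean_grid: Sequence[float] | None = None,
    alpha_outlier_set: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Evaluate the policy over a grid of (alpha_mean, alpha_outlier) pairs.

    History statistics are computed once (they do not depend on the alphas);
    only the decision step is repeated per pair. Returns one row per pair
    with the report fields as columns.
    """
    a_means = (
        list(DEFAULT_ALPHA_MEAN_GRID) if alpha_mean_grid is None else list(alpha_mean_grid)
    )
    a_outs = (
        list(DEFAULT_ALPHA_OUTLIER_SET)
        if alpha_outlier_set is None
        else list(alpha_outlier_set)
    )
    if not a_means or not a_outs:
        raise ValueError("parameter grids must be non-empty")

    df = histories_to_frame(histories)
    stats = _history_stats(df, base_config)
    sigma = _sigma_per_row(stats, estimates)
    n_donors = df["donor_id"].nunique()

    rows = []
    for a_out in a_outs:
        for a_mean in a_means:
            decided = _decide(stats, sigma, base_config, a_mean, a_out)
            assessed = decided[decided["alt_decision"] != "not_assessed"]
            if assessed.empty:
                raise ValueError("no assessable visits in sweep")
            report = _tally(assessed, n_donors)
            alt = assessed["alt_decision"].to_numpy()
            rows.append(
                {
                    "alpha_mean": a_mean,
                    "alpha_outlier": a_out,
                    **report.to_dict(),
                    "d_alt_A": int((alt == "defer_A").sum()),
                    "d_alt_B": int((alt == "defer_B").sum()),
                }
            )
    return pd.DataFrame(rows)


def filter_recent_other_donations(
    histories: Sequence[DonorHistory],
    exclusion_window_days: int = 365,
) -> tuple[list[DonorHistory], int]:
    """Drop donors with a flagged visit (e.g. a double red cell donation)
    within the trailing exclusion window.

    The window is anchored at the most recent visit date in the dataset. If
    no visit anywhere carries a flag the filter is a no-op with a warning
    (the extract had no flag column). Returns the kept histories and the
    number of donors removed.
    """
    all_histories = list(histories)
    if not any(v.flagged for h in all_histories for v in h.visits):
        warnings.warn(
            "no flagged visits present; record filter is a no-op", stacklevel=2
        )
        return all_histories, 0
    end = max(v.visit_date for h in all_histories for v in h.visits)
    kept = [
        h
        for h in all_histories
        if not any(
            v.flagged and (end - v.visit_date).days <= exclusion_window_days
            for v in h.visits
        )
    ]
    return kept, len(all_histories) - len(kept)
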