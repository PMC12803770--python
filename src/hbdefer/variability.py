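"""Measurement-variability estimation from successive within-donor differences.

If a donor's Hb level is stable, the difference between two subsequent
measurements is pure measurement (plus short-term biological) noise with
variance 2*sigma^2, so the SD of pooled within-donor successive differences
divided by sqrt(2) estimates sigma. Between-donor differences in level cancel
in the differencing, so population spread does not leak in. Post-donation
recovery adds real within-donor change, making this an upper limit for the
measurement SD; no recovery correction is applied.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np

from .model import DonorHistory, Sex, VariabilityEstimate

__all__ = ["consecutive_differences", "estimate_sigma", "estimate_variability"]


def consecutive_differences(
    history: DonorHistory, max_gap_days: int | None = None
) -> np.ndarray:
    """Differences hb[k+1] - hb[k] between subsequent visits of one donor.

    Empty for donors with fewer than two visits. With ``max_gap_days`` set,
    pairs whose visits are separated by more than that many days are dropped.
    """
    hbs = history.hbs()
    if hbs.size < 2:
        return np.empty(0, dtype=float)
    diffs = np.diff(hbs)
    if max_gap_days is not None:
        dates = history.dates()
        gaps = np.array(
            [(b - a).days for a, b in zip(dates, dates[1:])], dtype=float
        )
        diffs = diffs[gaps <= max_gap_days]
    return diffs


def estimate_sigma(
    histories: Iterable[DonorHistory],
    sex: Sex,
    max_gap_days: int | None = None,
) -> tuple[float, int]:
    """Pooled successive-difference estimate of the measurement SD for one sex.

    Returns ``(sigma_hat, n_pairs)`` where sigma_hat is the sample SD
    (n-1 denominator) of all pooled within-donor consecutive differences
    divided by sqrt(2); NaN when fewer than two pairs are available.
    """
    pooled = [
        consecutive_differences(h, max_gap_days=max_gap_days)
        for h in histories
        if h.sex is sex
    ]
    diffs = np.concatenate(pooled) if pooled else np.empty(0)
    n_pairs = int(diffs.size)
    if n_pairs < 2:
        return math.nan, n_pairs
    return float(np.std(diffs, ddof=1) / math.sqrt(2.0)), n_pairs


def estimate_variability(
    histories: Sequence[DonorHistory],
    max_gap_days: int | None = None,
    min_pairs: int = 30,
) -> VariabilityEstimate:
    """Estimate the measurement SD for both sexes from a set of donor careers."""
    sigma_m, n_m = estimate_sigma(histories, Sex.MALE, max_gap_days=max_gap_days)
    sigma_f, n_f = estimate_sigma(histories, Sex.FEMALE, max_gap_days=max_gap_days)
    return VariabilityEstimate(
        sigma_male=sigma_m,
        sigma_female=sigma_f,
        n_pairs_male=n_m,
        n_pairs_female=n_f,
        min_pairs=min_pairs,
    )
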