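"""Domain types for longitudinal donor haemoglobin screening.

Everything downstream works in g/dL. A donor's record is a chronological
sequence of visits (donation attempts), each carrying the haemoglobin (Hb)
concentration measured on site. The eligibility rules compare a visit against
a sex-specific legal deferral threshold and, for the historical-mean
algorithm, against the donor's own prior measurements.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

#: Plausible Hb range in g/dL after unit normalisation; rows outside are
#: rejected as data errors rather than clipped.
HB_PLAUSIBLE_RANGE = (5.0, 25.0)


class Sex(str, Enum):
    MALE = "M"
    FEMALE = "F"


_SEX_ALIASES = {
    "m": Sex.MALE,
    "male": Sex.MALE,
    "f": Sex.FEMALE,
    "female": Sex.FEMALE,
}


def parse_sex(value: str) -> Sex:
    """Parse a sex code (M/F/male/female, case-insensitive)."""
    try:
        return _SEX_ALIASES[str(value).strip().lower()]
    except KeyError:
        raise ValueError(f"unsupported sex code: {value!r}") from None


@dataclass(frozen=True)
class VisitRecord:
    """One donor visit: identifier, sex, date and measured Hb in g/dL.

    ``flagged`` marks visits carrying an optional exclusion marker from the
    source extract (e.g. a recent double red cell donation); it only matters
    to :func:`hbdefer.evaluate.filter_recent_other_donations`.
    """

    donor_id: str
    sex: Sex
    visit_date: dt.date
    hb: float
    flagged: bool = False


@dataclass
class DonorHistory:
    """A donor's chronologically ordered visits (one per calendar date)."""

    donor_id: str
    visits: list[VisitRecord]

    def __post_init__(self) -> None:
        dates = [v.visit_date for v in self.visits]
        if any(b < a for a, b in zip(dates, dates[1:])):
            raise ValueError(f"visits of donor {self.donor_id} are not sorted by date")

    @property
    def sex(self) -> Sex:
        return self.visits[0].sex

    @property
    def n_visits(self) -> int:
        return len(self.visits)

    def hbs(self) -> np.ndarray:
        return np.array([v.hb for v in self.visits], dtype=float)

    def dates(self) -> list[dt.date]:
        return [v.visit_date for v in self.visits]


@dataclass
class PolicyConfig:
    """Deferral-policy parameters.

    alpha_mean in (-1, 1) sets the confidence level of the two-sided interval
    around the historical mean; its sign selects which bound is compared to
    the threshold (negative: lower bound, strict; zero: the mean itself;
    positive: upper bound, lenient). alpha_outlier in (0.5, 1) sets how
    extreme a low single measurement must be, relative to the historical mean
    and the measurement SD, to count as a low outlier.
    """

    threshold_male: float = 13.5
    threshold_female: float = 12.5
    alpha_mean: float = 0.0
    alpha_outlier: float = 0.999
    min_prior_measurements: int = 2
    outlier_requires_below_threshold: bool = False
    prediction_adjustment: bool = False
    history_scope: str = "all_visits"  # or "donations_only"
    same_day_rule: str = "max"  # or "min" / "mean"
    units: str = "g_dL"  # or "g_L"
    max_history: int | None = None  # cap on number of prior measurements used

    def __post_init__(self) -> None:
        if not (-1.0 < self.alpha_mean < 1.0):
            raise ValueError(
                f"alpha_mean must lie strictly between -1 and 1, got {self.alpha_mean}"
            )
        if not (0.5 < self.alpha_outlier < 1.0):
            raise ValueError(
                "alpha_outlier must lie strictly between 0.5 and 1 "
                f"(values <= 0.5 place the low-outlier cutoff above the mean), "
                f"got {self.alpha_outlier}"
            )
        if self.threshold_male <= 0 or self.threshold_female <= 0:
            raise ValueError("deferral thresholds must be positive")
        if self.min_prior_measurements < 2:
            raise ValueError("min_prior_measurements must be >= 2")
        if self.history_scope not in ("all_visits", "donations_only"):
            raise ValueError(f"unknown history_scope: {self.history_scope!r}")
        if self.same_day_rule not in ("max", "min", "mean"):
            raise ValueError(f"unknown same_day_rule: {self.same_day_rule!r}")
        if self.units not in ("g_dL", "g_L"):
            raise ValueError(f"unknown units: {self.units!r}")
        if self.max_history is not None and self.max_history < 1:
            raise ValueError("max_history must be >= 1 when set")

    def threshold(self, sex: Sex) -> float:
        return self.threshold_male if sex is Sex.MALE else self.threshold_female


@dataclass(frozen=True)
class CountryPreset:
    """Per-country deferral thresholds and donation-interval descriptors,
    plus typical donor-population Hb means and measurement SDs used as
    simulator defaults."""

    name: str
    threshold_male: float
    threshold_female: float
    min_interval_days_male: int
    min_interval_days_female: int
    mean_hb_male: float
    mean_hb_female: float
    meas_sd_male: float
    meas_sd_female: float


PRESETS: dict[str, CountryPreset] = {
    p.name: p
    for p in [
        CountryPreset("Australia", 13.0, 12.0, 84, 84, 14.84, 13.37, 0.71, 0.67),
        CountryPreset("Belgium", 13.5, 12.5, 60, 60, 15.19, 13.65, 0.49, 0.52),
        CountryPreset("Finland", 13.0, 12.0, 56, 56, 15.58, 13.89, 0.73, 0.73),
        CountryPreset("France", 13.0, 12.0, 56, 56, 15.13, 13.31, 0.53, 0.62),
        CountryPreset("Netherlands", 13.5, 12.5, 56, 122, 15.06, 13.54, 0.70, 0.67),
        CountryPreset("South Africa", 13.5, 12.5, 56, 56, 15.66, 13.70, 0.84, 0.83),
        CountryPreset("USA", 13.0, 12.5, 56, 56, 15.55, 13.68, 0.85, 0.79),
    ]
}


def get_preset(name: str) -> CountryPreset:
    key = name.strip().lower()
    for preset in PRESETS.values():
        if preset.name.lower() == key:
            return preset
    raise KeyError(
        f"unknown country preset {name!r}; available: {', '.join(PRESETS)}"
    )


@dataclass
class VariabilityEstimate:
    """Per-sex Hb measurement SD (g/dL) with the successive-difference pair
    counts behind each estimate.

    An estimate based on fewer than ``min_pairs`` successive-difference pairs
    is flagged unusable; downstream code then requires an explicit override
    (see :meth:`known`).
    """

    sigma_male: float = math.nan
    sigma_female: float = math.nan
    n_pairs_male: int = 0
    n_pairs_female: int = 0
    min_pairs: int = 30
    override: bool = False

    @classmethod
    def known(
        cls, sigma_male: float | None = None, sigma_female: float | None = None
    ) -> "VariabilityEstimate":
        """Build an estimate from externally supplied (known) SDs."""
        return cls(
            sigma_male=math.nan if sigma_male is None else float(sigma_male),
            sigma_female=math.nan if sigma_female is None else float(sigma_female),
            override=True,
        )

    def usable(self, sex: Sex) -> bool:
        sigma = self.sigma_male if sex is Sex.MALE else self.sigma_female
        if math.isnan(sigma) or sigma < 0:
            return False
        if self.override:
            return True
        n = self.n_pairs_male if sex is Sex.MALE else self.n_pairs_female
        return n >= self.min_pairs

    def sigma(self, sex: Sex) -> float:
        """Return sigma for ``sex``; raise if the estimate is unusable."""
        if not self.usable(sex):
            raise ValueError(
                f"no usable measurement-SD estimate for sex {sex.value}: "
                "estimate it from data with enough successive-difference pairs "
                "or supply an explicit override (VariabilityEstimate.known)"
            )
        return self.sigma_male if sex is Sex.MALE else self.sigma_female


@dataclass
class ValidationReport:
    """Row accounting for a visits file: read = kept + rejected + collapsed."""

    n_rows_read: int = 0
    n_rows_rejected: int = 0
    n_collapsed_same_day: int = 0
    n_visits: int = 0
    reasons: dict[str, int] = field(default_factory=dict)

    def consistent(self) -> bool:
        return (
            self.n_rows_read
            == self.n_visits + self.n_rows_rejected + self.n_collapsed_same_day
        )


@dataclass
class VisitAssessment:
    """Per-visit output of the historical-mean algorithm.

    ``ci_bound`` is the bound actually compared to the threshold (it equals
    ``hist_mean`` when alpha_mean is 0). ``current_decision`` is the single
    measurement policy ('defer' iff hb below threshold); ``alt_decision`` is
    one of eligible / defer_A (historical mean below threshold) / defer_B
    (low outlier) / not_assessed (fewer prior measurements than required).
    ``reason`` is 'A', 'B', 'NA' for not_assessed, or '' for eligible.
    """

    donor_id: str
    visit_date: dt.date | None
    sex: Sex
    hb: float
    n_prior: int
    hist_mean: float
    ci_bound: float
    outlier_cutoff: float
    current_decision: str
    alt_decision: str
    reason: str


#: Sentinel used when a ratio metric has a zero denominator (e.g. no current
#: deferrals); kept as None so it can never be mistaken for a number.
UNDEFINED = None


@dataclass
class EvaluationReport:
    """Table-style summary of a retrospective policy re-assessment.

    Counts are over assessed visits only (visits with at least
    ``min_prior_measurements`` prior measurements). Percentages follow the
    conventions: deferral rates and the newly-deferred share use all assessed
    visits as denominator; the net change in donations uses current-policy
    donations (assessed visits minus current deferrals).
    """

    n_donors: int
    n_visits_assessed: int
    d_cur: int
    d_alt: int
    newly_deferred: int
    newly_eligible: int
    rate_cur: float
    rate_alt: float
    pct_change_deferrals: float | None
    pct_newly_deferred: float
    pct_change_donations: float | None
    mean_hist_mean_newly_eligible_male: float
    mean_hist_mean_newly_eligible_female: float

    def to_dict(self) -> dict:
        return {
            "n_donors": self.n_donors,
            "n_visits_assessed": self.n_visits_assessed,
            "d_cur": self.d_cur,
            "d_alt": self.d_alt,
            "newly_deferred": self.newly_deferred,
            "newly_eligible": self.newly_eligible,
            "rate_cur": self.rate_cur,
            "rate_alt": self.rate_alt,
            "pct_change_deferrals": self.pct_change_deferrals,
            "pct_newly_deferred": self.pct_newly_deferred,
            "pct_change_donations": self.pct_change_donations,
            "mean_hist_mean_newly_eligible_male": self.mean_hist_mean_newly_eligible_male,
            "mean_hist_mean_newly_eligible_female": self.mean_hist_mean_newly_eligible_female,
        }
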