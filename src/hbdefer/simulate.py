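"""Synthetic donor careers with the statistical structure the algorithm assumes.

Each donor i has a stable haematological setpoint mu_i drawn from a
sex-specific population distribution Normal(pop_mean, between_donor_sd); every
measurement is mu_i minus an optional post-donation deficit plus i.i.d.
Gaussian measurement noise Normal(0, meas_sigma). Visit dates start at a
random origin and advance by the sex-specific minimum donation interval plus
a uniform jitter.

The optional recovery model subtracts
``recovery_dip * max(0, 1 - log(1+t)/log(1+recovery_days))`` for t days since
the previous visit — Hb regained linearly in log(time), reaching the setpoint
at ``recovery_days``. It is off by default, matching the assumption under
which the successive-difference SD estimator is unbiased; switching it on
probes the estimator's upper-limit property.

Generation is reproducible: each donor gets an independent random stream
derived from (seed, donor index), so the population is a pure function of its
configuration.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .model import DonorHistory, PolicyConfig, Sex, VisitRecord, get_preset

__all__ = [
    "SexParams",
    "SimConfig",
    "SimulatedPopulation",
    "simulate_population",
    "inject_low_mean_donors",
]


@dataclass(frozen=True)
class SexParams:
    """Generative parameters for one sex (all Hb quantities in g/dL)."""

    mean_hb: float
    between_donor_sd: float = 1.0
    meas_sigma: float = 0.70
    min_interval_days: int = 56


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a synthetic donor population.

    Defaults emulate a Netherlands-like capillary-measurement setting:
    male/female population means 15.06/13.54 g/dL, measurement SD 0.70/0.67
    g/dL, between-donor SD 1.0 g/dL, minimum donation intervals 56/122 days.
    """

    n_donors: int = 1000
    prop_female: float = 0.5
    male: SexParams = field(
        default_factory=lambda: SexParams(15.06, 1.0, 0.70, 56)
    )
    female: SexParams = field(
        default_factory=lambda: SexParams(13.54, 1.0, 0.67, 122)
    )
    visits_per_donor: int | tuple[int, int] = 10
    interval_jitter_days: int = 28
    recovery_enabled: bool = False
    recovery_dip: float = 1.5
    recovery_days: int = 150
    seed: int = 0
    start_date: dt.date = dt.date(2015, 1, 1)
    start_window_days: int = 365

    def __post_init__(self) -> None:
        if self.n_donors < 1:
            raise ValueError("n_donors must be >= 1")
        if not 0.0 <= self.prop_female <= 1.0:
            raise ValueError("prop_female must lie in [0, 1]")
        for p in (self.male, self.female):
            if p.between_donor_sd < 0 or p.meas_sigma < 0:
                raise ValueError("standard deviations must be non-negative")
            if p.min_interval_days < 1:
                raise ValueError("min_interval_days must be >= 1")
        if isinstance(self.visits_per_donor, tuple):
            lo, hi = self.visits_per_donor
            if lo < 1 or hi < lo:
                raise ValueError("visits_per_donor range must satisfy 1 <= lo <= hi")
        elif self.visits_per_donor < 1:
            raise ValueError("visits_per_donor must be >= 1")
        if self.interval_jitter_days < 0:
            raise ValueError("interval_jitter_days must be non-negative")
        if self.recovery_dip < 0:
            raise ValueError("recovery_dip must be non-negative")
        if self.recovery_days < 1:
            raise ValueError("recovery_days must be >= 1")

    def params(self, sex: Sex) -> SexParams:
        return self.male if sex is Sex.MALE else self.female

    @classmethod
    def for_country(cls, name: str, **overrides) -> "SimConfig":
        """Build a configuration from a country preset's thresholds-era
        intervals and typical Hb means/SDs; keyword overrides win."""
        p = get_preset(name)
        defaults = dict(
            male=SexParams(p.mean_hb_male, 1.0, p.meas_sd_male, p.min_interval_days_male),
            female=SexParams(
                p.mean_hb_female, 1.0, p.meas_sd_female, p.min_interval_days_female
            ),
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class SimulatedPopulation:
    """Simulated donor careers plus the ground-truth setpoints behind them."""

    histories: list[DonorHistory]
    true_means: dict[str, float]
    config: SimConfig

    @property
    def n_donors(self) -> int:
        return len(self.histories)


def _recovery_deficit(t_days: float, dip: float, recovery_days: int) -> float:
    frac = math.log1p(t_days) / math.log1p(recovery_days)
    return dip * max(0.0, 1.0 - frac)


def simulate_population(config: SimConfig) -> SimulatedPopulation:
    """Generate a donor population; a pure function of ``config``."""
    n = config.n_donors
    n_female = round(config.prop_female * n)
    histories: list[DonorHistory] = []
    true_means: dict[str, float] = {}
    width = max(6, len(str(n)))

    for i in range(n):
        sex = Sex.FEMALE if i < n_female else Sex.MALE
        params = config.params(sex)
        rng = np.random.default_rng([config.seed, i])
        donor_id = f"D{i:0{width}d}"

        mu = params.mean_hb + params.between_donor_sd * rng.standard_normal()
        if isinstance(config.visits_per_donor, tuple):
            lo, hi = config.visits_per_donor
            m = int(rng.integers(lo, hi + 1))
        else:
            m = config.visits_per_donor

        day = int(rng.integers(0, config.start_window_days + 1))
        dates: list[dt.date] = []
        deficits: list[float] = []
        prev_day: int | None = None
        for _ in range(m):
            if prev_day is not None:
                day = prev_day + params.min_interval_days + int(
                    rng.integers(0, config.interval_jitter_days + 1)
                )
            if config.recovery_enabled and prev_day is not None:
                deficits.append(
                    _recovery_deficit(
                        day - prev_day, config.recovery_dip, config.recovery_days
                    )
                )
            else:
                deficits.append(0.0)
            dates.append(config.start_date + dt.timedelta(days=day))
            prev_day = day

        noise = params.meas_sigma * rng.standard_normal(m)
        hbs = mu - np.asarray(deficits) + noise
        visits = [
            VisitRecord(donor_id, sex, d, float(hb)) for d, hb in zip(dates, hbs)
        ]
        histories.append(DonorHistory(donor_id, visits))
        true_means[donor_id] = float(mu)

    return SimulatedPopulation(histories, true_means, config)


def inject_low_mean_donors(
    population: SimulatedPopulation,
    fraction: float,
    offset: float,
    policy: PolicyConfig,
    seed: int,
) -> tuple[SimulatedPopulation, list[str]]:
    """Shift a random subset of donors' setpoints to threshold - offset.

    Emulates the subpopulation with consistently low Hb that the
    historical-mean rule should newly defer. Shifting the setpoint shifts all
    of a donor's measurements by the same amount (noise and recovery deficits
    are unchanged), so the operation is exact without re-simulation. Returns
    the modified population and the shifted donor IDs for ground-truth
    labelling.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    n = population.n_donors
    k = round(fraction * n)
    rng = np.random.default_rng([seed, 0x10C])
    idx = sorted(rng.choice(n, size=k, replace=False).tolist())

    histories = list(population.histories)
    true_means = dict(population.true_means)
    shifted_ids: list[str] = []
    for i in idx:
        h = histories[i]
        target = policy.threshold(h.sex) - offset
        delta = target - true_means[h.donor_id]
        histories[i] = DonorHistory(
            h.donor_id,
            [replace(v, hb=v.hb + delta) for v in h.visits],
        )
        true_means[h.donor_id] = target
        shifted_ids.append(h.donor_id)

    return SimulatedPopulation(histories, true_means, population.config), shifted_ids
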