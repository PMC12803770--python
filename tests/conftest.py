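import datetime as dt

import pytest

from hbdefer import DonorHistory, PolicyConfig, Sex, VariabilityEstimate, VisitRecord


def make_history(
    donor_id: str,
    hbs,
    sex: Sex = Sex.MALE,
    start: dt.date = dt.date(2020, 1, 1),
    step_days: int = 56,
) -> DonorHistory:
    visits = [
        VisitRecord(donor_id, sex, start + dt.timedelta(days=i * step_days), float(hb))
        for i, hb in enumerate(hbs)
    ]
    return DonorHistory(donor_id, visits)


@pytest.fixture
def toy_policy() -> PolicyConfig:
    # EU thresholds, headline parameters: mean compared directly (alpha_mean 0),
    # 1-in-1000 outlier rule
    return PolicyConfig(alpha_mean=0.0, alpha_outlier=0.999)


@pytest.fixture
def toy_sigma() -> VariabilityEstimate:
    return VariabilityEstimate.known(sigma_male=0.5, sigma_female=0.5)


@pytest.fixture
def toy_histories() -> list[DonorHistory]:
    """Two male careers crossing every decision branch.

    With sigma 0.5, threshold 13.5, alpha_outlier 0.999 (z = 3.0902, so the
    cutoff sits 1.5451 below the mean), the six assessed visits split into:
    X3 newly eligible, X4 eligible/donate, X5 defer_B+current defer,
    Y3 newly deferred (A), Y4 defer_A+current defer, Y5 newly deferred (A).
    """
    return [
        make_history("X", [14.0, 14.5, 13.0, 14.0, 12.0]),
        make_history("Y", [13.2, 13.4, 13.6, 13.0, 13.8]),
    ]
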