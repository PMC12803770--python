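import math

import numpy as np
import pytest

from hbdefer import (
    DonorHistory,
    PolicyConfig,
    SimConfig,
    VariabilityEstimate,
    assess_donor,
    assess_frame,
    change_in_donations_from_rates,
    compute_report_metrics,
    evaluate_policy,
    filter_recent_other_donations,
    simulate_population,
    sweep_parameters,
)
from hbdefer.model import Sex, VisitRecord

from conftest import make_history


class TestToyTally:
    """Six assessed visits enumerated by hand (see the toy_histories docstring)."""

    def test_counts_match_manual_enumeration(self, toy_histories, toy_policy, toy_sigma):
        report, assessments = evaluate_policy(toy_histories, toy_sigma, toy_policy)
        assert report.n_visits_assessed == 6
        assert report.d_cur == 3
        assert report.d_alt == 4
        assert report.newly_deferred == 2
        assert report.newly_eligible == 1

    def test_decisions_match_manual_enumeration(self, toy_histories, toy_policy, toy_sigma):
        _, assessments = evaluate_policy(toy_histories, toy_sigma, toy_policy)
        got = dict(
            zip(
                zip(assessments["donor_id"], assessments["n_prior"]),
                assessments["alt_decision"],
            )
        )
        assert got[("X", 2)] == "eligible"
        assert got[("X", 3)] == "eligible"
        assert got[("X", 4)] == "defer_B"
        assert got[("Y", 2)] == "defer_A"
        assert got[("Y", 3)] == "defer_A"
        assert got[("Y", 4)] == "defer_A"

    def test_percentages_and_newly_eligible_mean(self, toy_histories, toy_policy, toy_sigma):
        report, _ = evaluate_policy(toy_histories, toy_sigma, toy_policy)
        assert report.rate_cur == pytest.approx(50.0)
        assert report.rate_alt == pytest.approx(100 * 4 / 6)
        assert report.pct_change_deferrals == pytest.approx(100 * (4 - 3) / 3)
        assert report.pct_newly_deferred == pytest.approx(100 * 2 / 6)
        assert report.pct_change_donations == pytest.approx(100 * (1 - 2) / (6 - 3))
        assert report.mean_hist_mean_newly_eligible_male == pytest.approx(14.25)
        assert math.isnan(report.mean_hist_mean_newly_eligible_female)


def test_coinciding_policies_yield_zero_changes(toy_policy, toy_sigma):
    histories = [
        make_history("low", [12.0] * 5),  # deferred by both policies everywhere
        make_history("high", [15.0] * 5),  # accepted by both everywhere
    ]
    report, _ = evaluate_policy(histories, toy_sigma, toy_policy)
    assert report.d_cur == report.d_alt == 3
    assert report.pct_change_deferrals == 0.0
    assert report.pct_change_donations == 0.0
    assert report.newly_deferred == report.newly_eligible == 0


class TestReportMetrics:
    def test_published_rate_relationship_netherlands(self):
        # with 10,000 assessed visits the counts reproduce printed rates exactly
        m = compute_report_metrics(522, 249, 0, 273, 10_000)
        assert m["rate_cur"] == pytest.approx(5.22)
        assert m["rate_alt"] == pytest.approx(2.49)
        assert round(m["pct_change_donations"], 2) == 2.88

    def test_published_rate_relationship_australia(self):
        m = compute_report_metrics(142, 43, 0, 99, 10_000)
        assert round(m["pct_change_deferrals"], 1) == -69.7

    def test_equal_counts_give_zero_changes(self):
        m = compute_report_metrics(50, 50, 10, 10, 1000)
        assert m["pct_change_deferrals"] == 0.0
        assert m["pct_change_donations"] == 0.0

    def test_identity_violation_is_an_error(self):
        with pytest.raises(ValueError, match="accounting identity"):
            compute_report_metrics(10, 20, 5, 5, 1000)

    def test_zero_current_deferrals_marks_change_undefined(self):
        m = compute_report_metrics(0, 5, 5, 0, 1000)
        assert m["pct_change_deferrals"] is None

    def test_zero_assessed_visits_is_an_error(self):
        with pytest.raises(ValueError):
            compute_report_metrics(0, 0, 0, 0, 0)

    def test_rate_form_equals_count_form(self):
        m = compute_report_metrics(522, 249, 0, 273, 10_000)
        assert m["pct_change_donations"] == pytest.approx(
            change_in_donations_from_rates(m["rate_cur"], m["rate_alt"]), abs=1e-9
        )


def test_evaluate_errors_when_nothing_is_assessable(toy_policy, toy_sigma):
    histories = [make_history("d", [14.0, 14.0])]
    with pytest.raises(ValueError, match="no assessable"):
        evaluate_policy(histories, toy_sigma, toy_policy)


@pytest.mark.parametrize("seed", range(6))
def test_accounting_identity_on_random_datasets(seed):
    rng = np.random.default_rng(seed)
    cfg = SimConfig(
        n_donors=int(rng.integers(20, 60)),
        visits_per_donor=(3, 8),
        seed=int(rng.integers(0, 2**16)),
    )
    pop = simulate_population(cfg)
    policy = PolicyConfig(
        alpha_mean=float(rng.uniform(-0.99, 0.99)),
        alpha_outlier=float(rng.choice([0.99, 0.999, 0.9999])),
    )
    est = VariabilityEstimate.known(sigma_male=0.7, sigma_female=0.67)
    report, _ = evaluate_policy(pop.histories, est, policy)
    assert report.d_alt - report.d_cur == report.newly_deferred - report.newly_eligible


def test_vectorised_frame_matches_per_donor_assessment(toy_policy):
    pop = simulate_population(SimConfig(n_donors=40, visits_per_donor=(2, 9), seed=21))
    est = VariabilityEstimate.known(sigma_male=0.7, sigma_female=0.67)
    config = PolicyConfig(alpha_mean=-0.5, alpha_outlier=0.999, prediction_adjustment=True)
    frame = assess_frame(pop.histories, est, config)
    flat = [a for h in pop.histories for a in assess_donor(h, est, config)]
    assert len(flat) == len(frame)
    for a, row in zip(flat, frame.itertuples(index=False)):
        assert (a.donor_id, a.alt_decision, a.current_decision) == (
            row.donor_id,
            row.alt_decision,
            row.current_decision,
        )
        if a.alt_decision != "not_assessed":
            assert row.hist_mean == pytest.approx(a.hist_mean, abs=1e-9)
            assert row.ci_bound == pytest.approx(a.ci_bound, abs=1e-9)
            assert row.outlier_cutoff == pytest.approx(a.outlier_cutoff, abs=1e-9)


def test_report_is_invariant_to_donor_order(toy_policy, toy_sigma):
    pop = simulate_population(SimConfig(n_donors=30, seed=13))
    forward, _ = evaluate_policy(pop.histories, toy_sigma, toy_policy)
    backward, _ = evaluate_policy(list(reversed(pop.histories)), toy_sigma, toy_policy)
    assert forward == backward


def test_evaluation_is_static_and_repeatable(toy_policy, toy_sigma, toy_histories):
    first, _ = evaluate_policy(toy_histories, toy_sigma, toy_policy)
    second, _ = evaluate_policy(toy_histories, toy_sigma, toy_policy)
    assert first == second


class TestSweep:
    @pytest.fixture()
    def setting(self):
        pop = simulate_population(SimConfig(n_donors=60, visits_per_donor=8, seed=17))
        est = VariabilityEstimate.known(sigma_male=0.7, sigma_female=0.67)
        return pop.histories, est, PolicyConfig()

    def test_single_pair_equals_direct_evaluation(self, setting):
        histories, est, policy = setting
        table = sweep_parameters(histories, est, policy, [0.0], [0.999])
        report, _ = evaluate_policy(histories, est, policy)
        row = table.iloc[0]
        assert row["d_cur"] == report.d_cur and row["d_alt"] == report.d_alt
        assert row["rate_alt"] == pytest.approx(report.rate_alt)

    def test_grid_shape(self, setting):
        histories, est, policy = setting
        table = sweep_parameters(histories, est, policy, [-0.5, 0.0, 0.5], [0.99, 0.999])
        assert len(table) == 6
        assert set(table["alpha_outlier"]) == {0.99, 0.999}

    def test_reason_b_count_non_increasing_in_alpha_outlier(self, setting):
        histories, est, policy = setting
        table = sweep_parameters(histories, est, policy, [0.0], [0.95, 0.99, 0.999, 0.9999])
        counts = table.sort_values("alpha_outlier")["d_alt_B"].tolist()
        assert counts == sorted(counts, reverse=True)

    def test_reason_a_count_non_increasing_in_alpha_mean(self, setting):
        histories, est, policy = setting
        table = sweep_parameters(histories, est, policy, [-0.9, -0.3, 0.0, 0.3, 0.9], [0.999])
        counts = table.sort_values("alpha_mean")["d_alt_A"].tolist()
        assert counts == sorted(counts, reverse=True)

    def test_empty_grid_rejected(self, setting):
        histories, est, policy = setting
        with pytest.raises(ValueError):
            sweep_parameters(histories, est, policy, [], [0.999])


class TestRecordFilter:
    def test_no_flags_is_identity_with_warning(self, toy_histories):
        with pytest.warns(UserWarning, match="no flagged"):
            kept, removed = filter_recent_other_donations(toy_histories, 365)
        assert removed == 0 and kept == toy_histories

    def test_flagged_donors_within_window_are_removed(self):
        import datetime as dt

        def hist(donor, flag_date=None):
            visits = []
            for i in range(4):
                date = dt.date(2020, 1, 1) + dt.timedelta(days=60 * i)
                visits.append(
                    VisitRecord(donor, Sex.MALE, date, 14.0, flagged=(date == flag_date))
                )
            return DonorHistory(donor, visits)

        histories = [
            hist("clean"),
            # flag 60 days before the dataset's last visit: inside the window
            hist("recent", flag_date=dt.date(2020, 1, 1) + dt.timedelta(days=120)),
            # flag 180 days before: outside the window
            hist("old", flag_date=dt.date(2020, 1, 1)),
        ]
        kept, removed = filter_recent_other_donations(histories, exclusion_window_days=120)
        assert removed == 1
        assert [h.donor_id for h in kept] == ["clean", "old"]

    def test_all_donors_flagged_empties_the_dataset(self):
        import datetime as dt

        visits = [VisitRecord("a", Sex.MALE, dt.date(2020, 1, 1), 14.0, True)]
        kept, removed = filter_recent_other_donations([DonorHistory("a", visits)], 365)
        assert kept == [] and removed == 1
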