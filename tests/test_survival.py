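"""Kaplan-Meier, log-rank, maxstat cutpoint and Cox hazard ratio."""

import numpy as np
import pytest

import oracles
from tamnk import (
    CohortConfig,
    MaxstatStratifier,
    SurvivalRecord,
    ValidationError,
    cox_binary_hr,
    km_estimate,
    logrank_test,
    maxstat_cutpoint,
    simulate_cohort,
    stratified_analysis,
)


def _records(times, events, prefix="s"):
    return [
        SurvivalRecord(f"{prefix}{i}", t, e) for i, (t, e) in enumerate(zip(times, events))
    ]


class TestKaplanMeier:
    def test_worked_example(self):
        """times [1,2,3], events [1,1,0]: S = (1-1/3), (1-1/3)(1-1/2), then flat."""
        km = km_estimate(_records([1, 2, 3], [1, 1, 0]))
        assert np.allclose(km.survival, [2 / 3, 1 / 3, 1 / 3])
        assert list(km.at_risk) == [3, 2, 1]

    def test_all_censored_stays_at_one(self):
        km = km_estimate(_records([1, 5, 9], [0, 0, 0]))
        assert np.allclose(km.survival, 1.0)

    def test_single_event_drops_to_zero(self):
        km = km_estimate(_records([5], [1]))
        assert km.survival_at(5) == 0.0

    def test_monotone_and_no_censoring_tail(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(5, 40)
        km = km_estimate(_records(times, np.ones(40, int)))
        assert (np.diff(km.survival) <= 1e-12).all()
        # without censoring S at the last event time is (n - events)/n = 0
        assert km.survival[-1] == pytest.approx(0.0)


class TestLogRank:
    def test_identical_groups_give_zero(self):
        group = _records([1, 3, 5, 7], [1, 0, 1, 1])
        chi2, p = logrank_test(group, _records([1, 3, 5, 7], [1, 0, 1, 1], "b"))
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        """A: events at 1,2; B: events at 10,11. Per-event 2x2 tables give
        O-E = 7/6 and V = 17/36, so chi-square = 49/17."""
        chi2, p = logrank_test(_records([1, 2], [1, 1]), _records([10, 11], [1, 1], "b"))
        assert chi2 == pytest.approx(49 / 17)
        assert 0.0 <= p <= 1.0

    def test_label_swap_invariance(self):
        a = _records([1, 4, 6], [1, 1, 0])
        b = _records([2, 3, 9], [0, 1, 1], "b")
        assert logrank_test(a, b)[0] == pytest.approx(logrank_test(b, a)[0])

    def test_zero_events_reports_null(self):
        chi2, p = logrank_test(_records([1, 2], [0, 0]), _records([3], [0], "b"))
        assert (chi2, p) == (0.0, 1.0)


class TestMaxstat:
    def _planted(self, seed=42):
        rng = np.random.default_rng(seed)
        _, recs, grp = simulate_cohort(
            CohortConfig(n_patients=200, true_hr_low_vs_high=3.0, seed=seed)
        )
        grp = np.asarray(grp)
        scores = np.where(grp == "low", rng.normal(-2, 0.5, 200), rng.normal(2, 0.5, 200))
        return recs, scores, grp

    def test_planted_separation_recovered(self):
        recs, scores, grp = self._planted()
        res = maxstat_cutpoint(recs, scores, n_perm=500, seed=1)
        assigned_low = scores <= res.cutpoint
        agreement = (assigned_low == (grp == "low")).mean()
        assert agreement >= 0.95
        assert res.perm_p < 0.05

    def test_statistics_match_naive_scan(self):
        """Vectorized candidate statistics equal an independent loop-based
        scan to 1e-12, and the same cutpoint is chosen."""
        recs, scores, _ = self._planted(seed=13)
        res = maxstat_cutpoint(recs, scores, n_perm=10, seed=0)
        times = [r.time for r in recs]
        events = [r.event for r in recs]
        best_c, best_z, cands, zs = oracles.maxstat_scan(times, events, scores)
        assert np.allclose(res.candidate_cutpoints, cands)
        assert np.allclose(res.candidate_statistics, zs, atol=1e-12)
        assert res.cutpoint == pytest.approx(best_c)
        assert res.max_statistic == pytest.approx(best_z, abs=1e-12)

    def test_same_seed_same_result(self):
        recs, scores, _ = self._planted(seed=3)
        a = maxstat_cutpoint(recs, scores, n_perm=200, seed=9)
        b = maxstat_cutpoint(recs, scores, n_perm=200, seed=9)
        assert (a.cutpoint, a.max_statistic, a.perm_p) == (
            b.cutpoint, b.max_statistic, b.perm_p
        )

    def test_group_sizes_partition(self):
        recs, scores, _ = self._planted(seed=4)
        res = maxstat_cutpoint(recs, scores, n_perm=50, seed=0)
        assert res.n_low + res.n_high == len(recs)

    def test_too_few_records_rejected(self):
        recs = _records([1, 2, 3], [1, 1, 1])
        with pytest.raises(ValidationError):
            maxstat_cutpoint(recs, [0.1, 0.2, 0.3])


class TestCox:
    def test_identical_groups_give_unit_hr(self):
        times = [1, 2, 3, 4, 6, 9]
        events = [1, 0, 1, 1, 0, 1]
        recs = _records(times + times, events + events)
        group = ["high"] * 6 + ["low"] * 6
        hr = cox_binary_hr(recs, group)
        assert hr.hr == pytest.approx(1.0, abs=1e-6)

    def test_matches_lifelines(self):
        """Breslow-tie Newton-Raphson fit matches an established survival
        library's Cox estimate to 1e-4 on fixed simulated data."""
        import pandas as pd
        from lifelines import CoxPHFitter

        _, recs, grp = simulate_cohort(CohortConfig(n_patients=300, seed=11))
        mine = cox_binary_hr(recs, grp, reference="high")
        frame = pd.DataFrame(
            {
                "t": [r.time for r in recs],
                "e": [r.event for r in recs],
                "x": (np.asarray(grp) == "low").astype(float),
            }
        )
        theirs = CoxPHFitter().fit(frame, "t", "e").params_["x"]
        assert mine.beta == pytest.approx(theirs, abs=1e-4)

    def test_sign_flips_under_reference_swap(self):
        _, recs, grp = simulate_cohort(CohortConfig(n_patients=100, seed=8))
        a = cox_binary_hr(recs, grp, reference="high")
        b = cox_binary_hr(recs, grp, reference="low")
        assert a.beta == pytest.approx(-b.beta, abs=1e-8)

    def test_ci_and_p_consistency(self):
        _, recs, grp = simulate_cohort(CohortConfig(n_patients=150, seed=12))
        hr = cox_binary_hr(recs, grp)
        lo, hi = hr.ci95
        assert lo < hr.hr < hi
        assert lo == pytest.approx(np.exp(hr.beta - 1.96 * hr.log_hr_se))

    def test_monotone_likelihood_is_capped_and_flagged(self):
        recs = _records([1, 2, 3, 10, 11, 12], [1, 1, 1, 0, 0, 0])
        group = ["low"] * 3 + ["high"] * 3
        hr = cox_binary_hr(recs, group)
        assert hr.diverged


class TestStratifiedAnalysis:
    def test_end_to_end_recovery(self):
        _, recs, grp = simulate_cohort(
            CohortConfig(n_patients=400, true_hr_low_vs_high=2.0, score_shift=1.0, seed=21)
        )
        rng = np.random.default_rng(21)
        grp = np.asarray(grp)
        # scores correlated with the true group, as the enrichment stage yields
        scores = {
            r.subject_id: (-1.0 if g == "low" else 1.0) + rng.normal(0, 0.5)
            for r, g in zip(recs, grp)
        }
        report = stratified_analysis(scores, recs, n_perm=199, seed=5)
        assert report.hazard_ratio.hr > 1.0
        assert report.logrank_p < 0.05

    def test_dropped_plus_analyzed_is_conserved(self):
        _, recs, _ = simulate_cohort(CohortConfig(n_patients=50, seed=2))
        scores = {r.subject_id: float(i) for i, r in enumerate(recs)}
        scores[recs[0].subject_id] = float("nan")
        del scores[recs[1].subject_id]
        report = stratified_analysis(scores, recs, n_perm=20, seed=0)
        assert report.n_dropped == 2
        assert report.n_dropped + report.n_analyzed == report.n_input == 50

    def test_estimator_interface(self):
        _, recs, grp = simulate_cohort(CohortConfig(n_patients=100, seed=31))
        rng = np.random.default_rng(0)
        grp = np.asarray(grp)
        x = np.where(grp == "low", -1.0, 1.0) + rng.normal(0, 0.3, 100)
        y = np.array([[r.time, r.event] for r in recs])
        est = MaxstatStratifier(n_perm=100, seed=2).fit(x, y)
        labels = est.predict(x)
        assert set(labels) == {"low", "high"}
        assert (labels == "low").sum() == est.report_.cutpoint.n_low
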