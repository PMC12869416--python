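"""Lift identities, coverage matching, combined sets, significance tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import ehrlift as el


def assert_lift_identities(r: el.LiftResult):
    assert r.lift == pytest.approx(r.ppv / r.prevalence)
    assert r.lift * r.coverage == pytest.approx(r.recall)
    assert r.lift <= min(1 / r.prevalence, 1 / r.coverage) + 1e-12


def _scored(labels, scores, folds=None, person_ids=None):
    n = len(labels)
    return pd.DataFrame(
        {
            "person_id": np.arange(n) + 1 if person_ids is None else person_ids,
            "label": labels,
            "fold_id": np.ones(n, dtype=int) if folds is None else folds,
            "score": scores,
        }
    )


def _rf(flags, person_ids=None, name="rf"):
    flags = np.asarray(flags, dtype=bool)
    idx = np.arange(len(flags)) + 1 if person_ids is None else person_ids
    return el.RiskFactorFlag(name=name, flags=pd.Series(flags, index=idx))


class TestLift:
    def test_forced_arithmetic(self):
        labels = np.zeros(100, dtype=int)
        labels[:10] = 1
        flags = np.zeros(100, dtype=bool)
        flags[5:15] = True  # 10 flagged, 5 of them cases
        r = el.lift(labels, flags)
        assert (r.prevalence, r.ppv, r.lift, r.recall) == (0.10, 0.5, 5.0, 0.5)
        assert_lift_identities(r)

    def test_flag_everyone_gives_exactly_one(self):
        labels = np.array([1, 0, 0, 1, 0])
        r = el.lift(labels, np.ones(5, dtype=bool))
        assert r.lift == 1.0
        assert_lift_identities(r)

    def test_flagging_exactly_the_cases_attains_bound(self):
        labels = np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
        r = el.lift(labels, labels.astype(bool))
        assert r.lift == pytest.approx(1 / r.prevalence)
        assert r.recall == 1.0
        assert_lift_identities(r)

    def test_no_cases_raises(self):
        with pytest.raises(ValueError, match="no cases"):
            el.lift(np.zeros(10), np.ones(10, dtype=bool))

    def test_empty_flag_set_distinct_error(self):
        with pytest.raises(ValueError, match="empty"):
            el.lift(np.array([1, 0]), np.zeros(2, dtype=bool))

    def test_flagged_without_cases_is_zero_lift(self):
        r = el.lift(np.array([1, 0, 0]), np.array([False, True, False]))
        assert r.lift == 0.0

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.integers(0, 2**31 - 1))
    def test_identities_hold_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 200))
        labels = rng.integers(0, 2, n)
        flags = rng.integers(0, 2, n).astype(bool)
        if labels.sum() == 0 or flags.sum() == 0:
            return
        assert_lift_identities(el.lift(labels, flags))


class TestTopkFlags:
    def test_distinct_scores_pick_top(self):
        scores = np.arange(10) / 10
        flags = el.topk_flags(scores, 0.2)
        assert np.flatnonzero(flags).tolist() == [8, 9]

    def test_all_ties_pick_lowest_ids(self):
        flags = el.topk_flags(np.ones(10), 0.3, tie_key=np.arange(10) + 1)
        assert np.flatnonzero(flags).tolist() == [0, 1, 2]

    def test_minimum_one_person(self):
        flags = el.topk_flags(np.random.default_rng(0).random(100), 0.001)
        assert flags.sum() == 1

    def test_half_up_rounding(self):
        assert el.topk_flags(np.arange(10) / 10, 0.25).sum() == 3  # 2.5 → 3

    def test_invalid_coverage(self):
        with pytest.raises(ValueError):
            el.topk_flags(np.ones(5), 0.0)


class TestCombinedFlags:
    scores = np.linspace(0, 1, 100)

    def test_union_arithmetic(self):
        rf = np.zeros(100, dtype=bool)
        rf[:2] = True  # two rf positives with the LOWEST scores
        flags = el.combined_flags(self.scores, rf, 0.05)
        assert flags.sum() == 5
        assert flags[:2].all()  # rf positives always kept
        assert flags[97:].all()  # top-3 rf-negatives fill the rest

    def test_target_equal_to_rf_coverage_is_identity(self):
        rf = np.zeros(100, dtype=bool)
        rf[10:15] = True
        flags = el.combined_flags(self.scores, rf, 0.05)
        assert np.array_equal(flags, rf)

    def test_target_one_flags_everyone(self):
        rf = np.zeros(100, dtype=bool)
        rf[0] = True
        flags = el.combined_flags(self.scores, rf, 1.0)
        assert flags.all()
        labels = np.zeros(100, dtype=int)
        labels[:10] = 1
        assert el.lift(labels, flags).lift == 1.0

    def test_below_rf_coverage_raises(self):
        rf = np.ones(100, dtype=bool)
        with pytest.raises(ValueError, match="risk factor"):
            el.combined_flags(self.scores, rf, 0.5)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_superset_and_monotone_in_target(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 150))
        scores = rng.random(n)
        rf = rng.random(n) < 0.1
        c0 = max(rf.mean(), 0.05)
        lo = el.combined_flags(scores, rf, min(c0, 1.0))
        hi = el.combined_flags(scores, rf, min(c0 + 0.3, 1.0))
        assert (rf <= lo).all()  # superset of rf
        assert (lo <= hi).all()  # monotone in target coverage


class TestFoldCI:
    def test_zero_variance(self):
        assert el.fold_ci([1, 1, 1, 1, 1]) == (1.0, 1.0, 1.0)

    def test_hand_arithmetic_with_clipping(self):
        mean, lo, hi = el.fold_ci([0, 2])
        assert mean == 1.0
        assert lo == 0.0  # clipped from −0.96
        assert hi == pytest.approx(2.9599639845, abs=1e-6)

    def test_unclipped_option(self):
        _, lo, _ = el.fold_ci([0, 2], clip_low=None)
        assert lo == pytest.approx(-0.9599639845, abs=1e-6)

    def test_widening_a_value_widens_interval(self):
        _, lo1, hi1 = el.fold_ci([1, 2, 3])
        _, lo2, hi2 = el.fold_ci([1, 2, 4])
        assert hi2 - lo2 > hi1 - lo1

    def test_fewer_than_two_values_raises(self):
        with pytest.raises(ValueError):
            el.fold_ci([1.0])


class TestMannWhitney:
    def test_fully_separated_exact(self):
        assert el.mann_whitney_less([1, 2, 3], [4, 5, 6]) == pytest.approx(0.05)

    def test_reversed_direction_carries_no_evidence(self):
        # inclusive enumeration: observed U is the maximum, so P(U ≤ max) = 1;
        # the complement identity holds only up to the point mass at U_obs:
        # p_less(x, y) + p_less(y, x) = 1 + P(U = U_obs)
        p_rev = el.mann_whitney_less([5, 6, 7], [1, 2, 3])
        assert p_rev == pytest.approx(1.0)
        assert p_rev + el.mann_whitney_less([1, 2, 3], [5, 6, 7]) == pytest.approx(
            1.0 + 1 / 20
        )

    def test_identical_constant_samples_no_evidence(self):
        assert el.mann_whitney_less([2, 2, 2], [2, 2, 2]) >= 0.5

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            el.mann_whitney_less([], [1.0])

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 6), st.integers(1, 6))
    def test_matches_full_enumeration_oracle(self, seed, n, m):
        """Exact p equals the fraction of rank assignments at least as extreme."""
        rng = np.random.default_rng(seed)
        pooled = rng.permutation(np.arange(1, n + m + 1)).astype(float)
        x, y = pooled[:n], pooled[n:]
        u_obs = sum(1 for a in x for b in y if a < b) + 0.5 * sum(
            1 for a in x for b in y if a == b
        )
        # enumerate all C(n+m, n) assignments of the pooled values to x
        count = 0
        total = 0
        values = np.concatenate([x, y])
        for combo in itertools.combinations(range(n + m), n):
            xs = values[list(combo)]
            ys = np.delete(values, list(combo))
            u = sum(1 for a in xs for b in ys if a < b)
            total += 1
            # alternative "less": small x ⇒ many (a < b) pairs ⇒ extreme is
            # u ≥ u_obs equivalently U_x ≤ observed U_x
            if u >= u_obs:
                count += 1
        assert el.mann_whitney_less(x, y) == pytest.approx(count / total)


class TestPairedBootstrap:
    def test_equal_vectors_give_one(self):
        a = np.arange(5.0)
        assert el.paired_bootstrap_less(a, a) == 1.0

    def test_uniform_improvement_gives_zero(self):
        a = np.arange(5.0)
        assert el.paired_bootstrap_less(a, a + 1) == 0.0

    def test_mixed_signs_reproducible(self):
        a = np.array([0.6, 0.7, 0.8, 0.5])
        b = np.array([0.7, 0.6, 0.9, 0.6])
        p1 = el.paired_bootstrap_less(a, b, seed=5)
        p2 = el.paired_bootstrap_less(a, b, seed=5)
        assert p1 == p2
        assert 0 < p1 < 1

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            el.paired_bootstrap_less([1.0], [1.0, 2.0])


def _five_fold_scored(rng, n_per_fold=400, prevalence=0.1, informative=False):
    frames = []
    pid = 1
    for f in range(1, 6):
        labels = (rng.random(n_per_fold) < prevalence).astype(int)
        if labels.sum() == 0:
            labels[0] = 1
        if informative:
            scores = labels + rng.normal(0, 1e-3, n_per_fold)
        else:
            scores = rng.random(n_per_fold)
        frames.append(_scored(labels, scores, folds=np.full(n_per_fold, f),
                              person_ids=np.arange(pid, pid + n_per_fold)))
        pid += n_per_fold
    return pd.concat(frames, ignore_index=True)


class TestMatchedComparison:
    def test_oracle_rf_limit(self):
        """Risk factor = the label vector ⇒ rf lift = 1/prevalence per fold."""
        rng = np.random.default_rng(0)
        scored = _five_fold_scored(rng, informative=False)
        rf = _rf(scored["label"].to_numpy().astype(bool),
                 person_ids=scored["person_id"].to_numpy())
        result = el.matched_comparison(scored, rf)
        for r in result.rf_fold_results:
            assert r.lift == pytest.approx(1 / r.prevalence)
            assert r.recall == 1.0
        # random scores at the same coverage hover near 1
        assert result.ehr_ci[0] < 2.0

    def test_null_rf_and_scores_mean_lift_near_one(self):
        """Both arms ≈ 1 under the null (replicate average, 3 MC SEs)."""
        rng = np.random.default_rng(1)
        rf_means, ehr_means = [], []
        for _ in range(60):
            scored = _five_fold_scored(rng, n_per_fold=200)
            rf = _rf(rng.random(len(scored)) < 0.1,
                     person_ids=scored["person_id"].to_numpy())
            res = el.matched_comparison(scored, rf)
            rf_means.append(res.rf_ci[0])
            ehr_means.append(res.ehr_ci[0])
        for means in (rf_means, ehr_means):
            se = np.std(means, ddof=1) / np.sqrt(len(means))
            assert abs(np.mean(means) - 1.0) < 3 * se

    def test_perfect_scores_attain_coverage_bound(self):
        """Near-perfect ranking ⇒ ehr lift ≈ min(1/prev, 1/coverage)."""
        rng = np.random.default_rng(2)
        scored = _five_fold_scored(rng, informative=True, prevalence=0.1)
        rf = _rf(rng.random(len(scored)) < 0.05,
                 person_ids=scored["person_id"].to_numpy())
        result = el.matched_comparison(scored, rf)
        for ehr, rf_res in zip(result.ehr_fold_results, result.rf_fold_results):
            bound = min(1 / ehr.prevalence, 1 / rf_res.coverage)
            assert ehr.lift == pytest.approx(bound, rel=0.15)
        assert result.mann_whitney_p < 0.05

    def test_empty_rf_fold_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        scored = _five_fold_scored(rng, n_per_fold=100)
        flags = np.zeros(len(scored), dtype=bool)
        flags[scored["fold_id"] != 1] = rng.random((scored["fold_id"] != 1).sum()) < 0.2
        rf = _rf(flags, person_ids=scored["person_id"].to_numpy())
        with pytest.warns(UserWarning, match="dropped"):
            result = el.matched_comparison(scored, rf)
        assert result.dropped_folds == [1]
        assert len(result.rf_fold_results) == 4

    def test_all_folds_dropped_raises(self):
        rng = np.random.default_rng(4)
        scored = _five_fold_scored(rng, n_per_fold=50)
        rf = _rf(np.zeros(len(scored), dtype=bool),
                 person_ids=scored["person_id"].to_numpy())
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="all folds dropped"):
                el.matched_comparison(scored, rf)


class TestCombinedCurve:
    def test_degenerate_grid_reduces_to_rf_alone(self):
        rng = np.random.default_rng(5)
        scored = _five_fold_scored(rng)
        flags = rng.random(len(scored)) < 0.1
        rf = _rf(flags, person_ids=scored["person_id"].to_numpy())
        rf_only = el.matched_comparison(scored, rf)
        # grid pinned at each fold's own rf coverage: identity case per fold
        points, best = el.combined_curve(scored, rf, [1e-9])
        assert points[0].fold_lifts == tuple(
            r.lift for r in rf_only.rf_fold_results
        )
        assert points[0].p_vs_rf >= 0.45

    def test_uninformative_scores_dilute_toward_one(self):
        """Expanding a strong RF with random scores cannot raise mean lift."""
        rng = np.random.default_rng(6)
        diffs = []
        for _ in range(30):
            scored = _five_fold_scored(rng, n_per_fold=300, prevalence=0.1)
            labels = scored["label"].to_numpy().astype(bool)
            noisy_rf = labels & (rng.random(len(labels)) < 0.8)
            noisy_rf |= rng.random(len(labels)) < 0.02
            rf = _rf(noisy_rf, person_ids=scored["person_id"].to_numpy())
            points, _ = el.combined_curve(scored, rf, [0.3])
            rf_lift = np.mean([r.lift for r in el.matched_comparison(
                scored, rf).rf_fold_results])
            diffs.append(points[0].mean_lift - rf_lift)
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert np.mean(diffs) < 3 * se  # no improvement under dilution

    def test_perfect_scores_max_lift_at_case_geometry(self):
        """With perfect ranking the best grid point packs rf ∪ cases."""
        rng = np.random.default_rng(7)
        scored = _five_fold_scored(rng, n_per_fold=1000, prevalence=0.05,
                                   informative=True)
        rf = _rf(rng.random(len(scored)) < 0.01,
                 person_ids=scored["person_id"].to_numpy())
        grid = np.round(np.arange(0.01, 0.101, 0.01), 10)
        points, best = el.combined_curve(scored, rf, grid)
        # brute-force the best grid point from the closed-form per-fold lifts
        brute = max(points, key=lambda p: p.mean_lift)
        assert best.target_coverage == brute.target_coverage
        assert abs(best.target_coverage - 0.06) <= 0.011  # ≈ prev + rf·(1−prev)
        assert best.p_vs_rf < 0.05

    def test_empty_grid_raises(self):
        rng = np.random.default_rng(8)
        scored = _five_fold_scored(rng)
        rf = _rf(rng.random(len(scored)) < 0.1,
                 person_ids=scored["person_id"].to_numpy())
        with pytest.raises(ValueError, match="grid"):
            el.combined_curve(scored, rf, [])


class TestCandidateCoverageRange:
    def _perfect(self, prevalence=0.1, n=1000):
        rng = np.random.default_rng(9)
        labels = np.zeros(n, dtype=int)
        labels[: int(prevalence * n)] = 1
        labels = rng.permutation(labels)
        scores = labels + rng.normal(0, 1e-6, n)
        return _scored(labels, scores, folds=np.repeat([1, 2], n // 2))

    def test_closed_form_for_perfect_ranking(self):
        # lift(c) = 1/c for c > prev ⇒ largest c with lift ≥ 2 is 0.5
        scored = self._perfect(prevalence=0.1)
        assert el.candidate_coverage_range(scored, 2.0) == pytest.approx(0.5)

    def test_ref_above_upper_bound_returns_none(self):
        scored = self._perfect(prevalence=0.1)
        assert el.candidate_coverage_range(scored, 11.0) is None

    def test_ref_at_most_one_returns_full_coverage(self):
        scored = self._perfect(prevalence=0.1)
        assert el.candidate_coverage_range(scored, 1.0) == pytest.approx(1.0)

    def test_invalid_ref_raises(self):
        with pytest.raises(ValueError):
            el.candidate_coverage_range(self._perfect(), 0.0)


class TestCounterfactualSummary:
    def test_counts_and_fp_rate(self):
        labels = np.array([1] * 5 + [0] * 15)
        flags = np.array([True] * 10 + [False] * 10)
        dates = pd.to_datetime(["2019-06-15"] * 20)
        dx = pd.to_datetime(["2020-06-15"] * 20)
        s = el.counterfactual_summary(labels, flags, dates, dx)
        assert (s["n_true_positive"], s["n_false_positive"]) == (5, 5)
        assert s["fp_rate"] == 0.5

    def test_leap_year_lead_time(self):
        s = el.counterfactual_summary(
            [1], [True], pd.to_datetime(["2019-06-15"]),
            pd.to_datetime(["2020-06-15"]),
        )
        assert s["lead_time_days"] == {"min": 366, "median": 366.0, "max": 366}

    def test_zero_flagged_explicit_empty(self):
        s = el.counterfactual_summary(
            [1, 0], [False, False], pd.to_datetime(["2019-01-01"] * 2),
            pd.to_datetime(["2020-01-01"] * 2),
        )
        assert s["empty"] is True
        assert s["n_flagged"] == 0


class TestGlobalLiftAudit:
    def test_every_emitted_lift_satisfies_identities(self, small_config):
        """End-to-end audit of all LiftResults produced by a full study."""
        from ehrlift.pipeline import run_study

        result = run_study(small_config, model=el.ModelSpec(
            "xgboost", {"n_estimators": 30}))
        audited = 0
        for comp in result.comparisons.values():
            for r in comp.rf_fold_results + comp.ehr_fold_results:
                assert_lift_identities(r)
                audited += 1
            for point in comp.combined_curve:
                for r in point.fold_results:
                    assert_lift_identities(r)
                    audited += 1
        assert audited > 50
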