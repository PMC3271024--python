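"""Saccade classification, exclusions and the session-level statistics."""

import math

import numpy as np
import pytest

from sacstrat import (
    EndpointNoise,
    ObserverPolicy,
    PsychometricParams,
    TaskGeometry,
    analyze_session,
    apply_exclusions,
    classify_saccade,
    classify_trials,
    endpoint_statistics,
    estimate_psi_from_decision,
    estimate_stickiness,
    intertrial_dependency,
    latency_vs_optimality,
    near_side_preference,
    nested_lrt_vs_meg,
    optimal_switch_separation,
    realized_gain_and_deficit,
    repeated_condition_optimality,
    simulate_decision_session,
    simulate_verification_session,
    strategy_proportions,
)
from sacstrat.behavior_analysis import ClassifiedTrial
from sacstrat.errors import InsufficientDataError
from sacstrat.synthetic_data import DecisionTrial

NO_ABORTS = EndpointNoise(sigma_x=0.0, sigma_y=0.0, blink_rate=0.0)


def make_trial(
    condition=12.0,
    landing=(0.0, 0.0),
    correct=True,
    fixation_side="right",
    observer="sim",
    index=0,
    latency=250.0,
    target_side="left",
    aborted=False,
):
    return DecisionTrial(
        index=index,
        condition=condition,
        variable="separation",
        fixation=(condition / 4.0, -4.0),
        fixation_side=fixation_side,
        intended_token="center",
        landing=landing,
        latency_ms=latency,
        aborted=aborted,
        abort_reason="blink" if aborted else None,
        target_side=target_side,
        configuration="dot-up",
        response="dot-up" if correct else "dot-down",
        correct=correct,
        observer=observer,
    )


def simulate_classified(psi, schedule, policy, seed, reps=96, noise=None, prediction=None):
    trials = simulate_decision_session(
        schedule, reps, psi, policy, noise or NO_ABORTS, seed=seed, prediction=prediction
    )
    pred = prediction or optimal_switch_separation(psi, conditions=schedule)
    retained, _ = apply_exclusions(trials)
    return classify_trials(retained, pred), pred


class TestClassification:
    def test_landing_on_token_center_assigns_that_token(self):
        geo = TaskGeometry(side_separation=12.0)
        for name, pos in geo.token_positions.items():
            token, strategy = classify_saccade(pos, geo)
            assert token == name
            assert strategy == ("center" if name == "center" else "side")

    def test_equidistant_tie_breaks_to_center(self):
        geo = TaskGeometry(side_separation=12.0)
        token, strategy = classify_saccade((3.0, 0.0), geo)  # midway center-right
        assert token == "center" and strategy == "center"

    def test_matches_brute_force_argmin_on_random_points(self):
        rng = np.random.default_rng(12)
        geo = TaskGeometry(side_separation=10.0)
        tokens = geo.token_positions
        for _ in range(500):
            pt = tuple(rng.uniform(-10, 10, size=2))
            token, _ = classify_saccade(pt, geo)
            dists = {
                name: math.hypot(pt[0] - x, pt[1] - y)
                for name, (x, y) in tokens.items()
            }
            best = min(dists.values())
            assert dists[token] == pytest.approx(best, abs=1e-12)


class TestExclusions:
    def test_far_landing_excluded_with_reason(self):
        t = make_trial(landing=(3.0, 3.0))  # >1 deg from every token at D=12
        retained, tally = apply_exclusions([t], landing_criterion_radius=1.0)
        assert retained == [] and tally["landing"] == 1

    def test_clean_trial_retained(self):
        t = make_trial(landing=(0.2, -0.1))
        retained, tally = apply_exclusions([t])
        assert len(retained) == 1 and sum(tally.values()) == 0

    def test_blink_aborts_tallied_separately(self):
        t = make_trial(aborted=True)
        retained, tally = apply_exclusions([t])
        assert retained == [] and tally["blink"] == 1

    def test_exclusion_fraction_matches_gaussian_tail(self, s01_psi, s01_schedule):
        """With isotropic sigma and radius r the landing-failure probability
        per attempt is the Rayleigh tail exp(-r^2 / (2 sigma^2))."""
        sigma, r = 0.75, 1.0
        noise = EndpointNoise(sigma_x=sigma, sigma_y=sigma, blink_rate=0.0)
        trials = simulate_decision_session(
            s01_schedule,
            96,
            s01_psi,
            ObserverPolicy(kind="fixed-mixture"),
            noise,
            seed=13,
        )
        n_attempts = len(trials)
        n_landing_aborts = sum(t.aborted for t in trials)
        p_tail = math.exp(-(r**2) / (2 * sigma**2))
        se = math.sqrt(p_tail * (1 - p_tail) / n_attempts)
        assert abs(n_landing_aborts / n_attempts - p_tail) < 4 * se


class TestStrategyProportions:
    def test_ideal_observer_reproduces_step_function(
        self, s01_psi, s01_schedule, s01_prediction
    ):
        classified, pred = simulate_classified(
            s01_psi, s01_schedule, ObserverPolicy(kind="ideal"), seed=14,
            prediction=s01_prediction,
        )
        props = strategy_proportions(classified, pred)
        for _, row in props.iterrows():
            assert row["p_side"] == row["ideal_p_side"]

    def test_always_center_gives_zero_everywhere(self, s01_psi, s01_schedule):
        classified, pred = simulate_classified(
            s01_psi, s01_schedule, ObserverPolicy(kind="always-center"), seed=15
        )
        props = strategy_proportions(classified, pred)
        assert (props["p_side"] == 0).all()

    def test_fixed_mixture_proportions_within_binomial_error(
        self, s01_psi, s01_schedule
    ):
        p = 0.6
        classified, pred = simulate_classified(
            s01_psi, s01_schedule, ObserverPolicy(kind="fixed-mixture", p_side_base=p),
            seed=16,
        )
        props = strategy_proportions(classified, pred)
        se = math.sqrt(p * (1 - p) / 96)
        assert (np.abs(props["p_side"] - p) < 4 * se).all()


class TestNearSidePreference:
    @pytest.mark.parametrize("pref", [1.0, 0.5, 0.85])
    def test_recovers_generating_preference(self, pref, s01_psi, s01_schedule):
        pol = ObserverPolicy(kind="always-side", near_side_preference=pref)
        classified, _ = simulate_classified(s01_psi, s01_schedule, pol, seed=17)
        est = near_side_preference(classified)
        n = len(classified)
        se = math.sqrt(max(pref * (1 - pref), 0.25 / n) / n)
        assert abs(est - pref) <= 3 * se + 1e-12

    def test_no_side_trials_flagged(self, s01_psi, s01_schedule):
        classified, _ = simulate_classified(
            s01_psi, s01_schedule, ObserverPolicy(kind="always-center"), seed=18
        )
        with pytest.raises(InsufficientDataError):
            near_side_preference(classified)


class TestIntertrialDependency:
    def _classified_from_strategies(self, strategies, observer="o1"):
        out = []
        for i, s in enumerate(strategies):
            landing = (0.0, 0.0) if s == "center" else (6.0, 0.0)
            t = make_trial(landing=landing, observer=observer, index=i)
            out.append(
                ClassifiedTrial(
                    trial=t,
                    assigned_token="center" if s == "center" else "right",
                    strategy=s,
                    optimal=False,
                )
            )
        return out

    def test_alternating_sequence_has_zero_repeat_frequency(self):
        seq = ["center", "side"] * 20
        res = intertrial_dependency(self._classified_from_strategies(seq))
        for strat in ("side", "center"):
            assert res.per_observer["o1"][strat]["conditional"] == 0.0

    def test_constant_sequence_has_unit_repeat_frequency(self):
        seq = ["side"] * 30
        res = intertrial_dependency(self._classified_from_strategies(seq))
        assert res.per_observer["o1"]["side"]["conditional"] == 1.0

    def test_single_observer_skips_t_test_with_notice(self):
        res = intertrial_dependency(self._classified_from_strategies(["side"] * 5))
        assert res.tests is None and "skipped" in res.notice

    def test_sticky_cohort_detected_by_one_tailed_test(self):
        """Power check: cohorts of 4 sticky observers should be detected at
        alpha=0.05 in the large majority of replicates."""
        kappa, n_trials, n_cohorts = 0.76, 864, 200
        rng = np.random.default_rng(19)
        rejections = 0
        for _ in range(n_cohorts):
            cohort = []
            for j in range(4):
                seq = ["side" if rng.random() < 0.5 else "center"]
                for _ in range(n_trials - 1):
                    if rng.random() < kappa:
                        seq.append(seq[-1])
                    else:
                        seq.append("side" if rng.random() < 0.5 else "center")
                cohort.extend(self._classified_from_strategies(seq, observer=f"o{j}"))
            res = intertrial_dependency(cohort)
            if all(res.tests[s]["p"] < 0.05 for s in ("side", "center")):
                rejections += 1
        assert rejections / n_cohorts > 0.8

    def test_stickiness_estimator_recovers_kappa_from_markov_chain(self):
        kappa = 0.76
        rng = np.random.default_rng(20)
        seq = ["side"]
        for _ in range(5000):
            if rng.random() < kappa:
                seq.append(seq[-1])
            else:
                seq.append("side" if rng.random() < 0.5 else "center")
        assert estimate_stickiness(seq) == pytest.approx(kappa, abs=0.03)


class TestRepeatedConditionOptimality:
    def test_ideal_observer_is_optimal_everywhere(
        self, s01_psi, s01_schedule, s01_prediction
    ):
        classified, _ = simulate_classified(
            s01_psi, s01_schedule, ObserverPolicy(kind="ideal"), seed=21,
            prediction=s01_prediction,
        )
        res = repeated_condition_optimality(classified)
        assert res.overall_rate == 1.0
        assert res.repeated_rate == 1.0

    def test_memoryless_policy_rates_agree_on_average(self, s01_psi, s01_schedule):
        diffs = []
        for seed in range(40):
            classified, _ = simulate_classified(
                s01_psi,
                s01_schedule,
                ObserverPolicy(kind="fixed-mixture", p_side_base=0.5),
                seed=100 + seed,
                reps=24,
            )
            res = repeated_condition_optimality(classified)
            diffs.append(res.repeated_rate - res.overall_rate)
        assert abs(np.mean(diffs)) < 0.02

    def test_sequence_without_repeats_flagged(self):
        trials = [
            ClassifiedTrial(
                trial=make_trial(condition=c, index=i),
                assigned_token="center",
                strategy="center",
                optimal=True,
            )
            for i, c in enumerate([8.0, 10.0, 12.0, 14.0])
        ]
        res = repeated_condition_optimality(trials)
        assert res.n_repeated == 0 and res.notice is not None


class TestGainAndDeficit:
    def test_all_correct_realized_gain(self, s01_psi, s01_schedule, s01_prediction):
        classified, pred = simulate_classified(
            s01_psi, s01_schedule, ObserverPolicy(kind="ideal"), seed=22,
            prediction=s01_prediction,
        )
        summary = realized_gain_and_deficit(classified, pred, params=s01_psi)
        n_correct = sum(bool(c.trial.correct) for c in classified)
        assert summary.realized_gain == pytest.approx(n_correct)

    def test_ideal_observer_deficit_is_zero(
        self, s01_psi, s01_schedule, s01_prediction
    ):
        classified, pred = simulate_classified(
            s01_psi, s01_schedule, ObserverPolicy(kind="ideal"), seed=23,
            prediction=s01_prediction,
        )
        summary = realized_gain_and_deficit(classified, pred, params=s01_psi)
        assert summary.deficit == pytest.approx(0.0, abs=1e-12)

    def test_always_center_deficit_matches_closed_form(self, s01_psi, s01_prediction):
        """On conditions above the switch point, the deficit of an
        always-center observer is computable directly from the two
        strategy-probability formulas."""
        from sacstrat import p_correct_center, p_correct_side

        schedule = [14.0, 18.0, 24.0]  # all above the ~11.86 deg switch point
        pred = optimal_switch_separation(s01_psi, conditions=schedule)
        classified, _ = simulate_classified(
            s01_psi, schedule, ObserverPolicy(kind="always-center"), seed=24, reps=32
        )
        summary = realized_gain_and_deficit(classified, pred, params=s01_psi)
        eg = sum(
            32 * p_correct_center(s01_psi, TaskGeometry(side_separation=c))
            for c in schedule
        )
        meg = sum(
            32 * p_correct_side(s01_psi, TaskGeometry(side_separation=c))
            for c in schedule
        )
        assert summary.deficit == pytest.approx((meg - eg) / meg, abs=1e-9)


class TestNestedLRT:
    def test_counts_matching_null_give_zero_statistic(self):
        flat = PsychometricParams(alpha=0.75, beta=0.75, e_half=5.0, gamma=1.0)
        from sacstrat import StrategyPrediction

        prediction = StrategyPrediction(
            switch_point=12.0,
            variable="separation",
            policy={8.0: "center"},
            uniqueness_verified=True,
        )
        # 4 trials, 3 correct: phat = 0.75 = model probability under flat psi
        trials = [
            ClassifiedTrial(
                trial=make_trial(condition=8.0, correct=(i < 3), index=i),
                assigned_token="center",
                strategy="center",
                optimal=True,
            )
            for i in range(4)
        ]
        res = nested_lrt_vs_meg(trials, prediction, params=flat)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    def test_statistic_nonnegative_and_order_invariant(
        self, s01_psi, s01_schedule, s01_prediction
    ):
        classified, pred = simulate_classified(
            s01_psi, s01_schedule, ObserverPolicy(kind="fixed-mixture"), seed=25
        )
        res = nested_lrt_vs_meg(classified, pred, params=s01_psi)
        res_rev = nested_lrt_vs_meg(list(reversed(classified)), pred, params=s01_psi)
        assert res.statistic >= 0
        assert res.statistic == pytest.approx(res_rev.statistic)
        assert res.df == len(s01_schedule)

    def test_always_side_below_switch_point_rejected_with_power(self, s01_psi):
        """A policy that is side everywhere on a mostly-below-switch schedule
        should be detected nearly always."""
        schedule = [4.0, 5.0, 6.0, 7.0, 8.0]
        pred = optimal_switch_separation(s01_psi, conditions=schedule)
        rejections = 0
        n_rep = 50
        for seed in range(n_rep):
            classified, _ = simulate_classified(
                s01_psi, schedule, ObserverPolicy(kind="always-side"), seed=300 + seed,
                reps=96,
            )
            res = nested_lrt_vs_meg(classified, pred, params=s01_psi)
            if res.p_value < 0.05:
                rejections += 1
        assert rejections / n_rep > 0.95


class TestEndpointStatistics:
    def test_zero_noise_means_on_token_centers(self, s01_psi, s01_schedule):
        classified, _ = simulate_classified(
            s01_psi, s01_schedule, ObserverPolicy(kind="fixed-mixture"), seed=26
        )
        stats_df = endpoint_statistics(classified)
        assert (stats_df["mean_dx"].abs() < 1e-12).all()
        assert (stats_df["sd_x"].fillna(0) == 0).all()

    def test_sigma_recovered_before_exclusions(self, s01_psi, s01_schedule):
        sigma = 0.75
        noise = EndpointNoise(sigma_x=sigma, sigma_y=sigma, blink_rate=0.0)
        trials = simulate_decision_session(
            [12.0], 500, s01_psi,
            ObserverPolicy(kind="fixed-mixture"), noise, seed=27,
        )
        pred = optimal_switch_separation(s01_psi, conditions=[12.0])
        # pre-exclusion: classify every executed trial, including aborted
        # ones (they still carry landing points)
        import dataclasses

        classified = classify_trials(
            [dataclasses.replace(t, aborted=False, abort_reason=None) for t in trials],
            pred,
        )
        stats_df = endpoint_statistics(classified)
        pooled_sd = np.sqrt(
            np.average(stats_df["sd_x"] ** 2, weights=stats_df["n"])
        )
        assert abs(pooled_sd - sigma) / sigma < 0.1

        # post-exclusion truncation shrinks the spread
        retained, _ = apply_exclusions(trials)
        post = endpoint_statistics(classify_trials(retained, pred))
        assert (post["sd_x"] < sigma).all()


class TestLatencyVsOptimality:
    def test_ideal_observer_all_bins_at_one(
        self, s01_psi, s01_schedule, s01_prediction
    ):
        classified, _ = simulate_classified(
            s01_psi, s01_schedule, ObserverPolicy(kind="ideal"), seed=28,
            prediction=s01_prediction,
        )
        binned = latency_vs_optimality(classified, n_bins=4)
        assert (binned["p_optimal"] == 1.0).all()

    def test_latency_independent_policy_is_flat(self, s01_psi, s01_schedule):
        classified, _ = simulate_classified(
            s01_psi, s01_schedule, ObserverPolicy(kind="fixed-mixture"), seed=29
        )
        binned = latency_vs_optimality(classified, n_bins=4)
        overall = np.average(binned["p_optimal"], weights=binned["n"])
        for _, row in binned.iterrows():
            se = math.sqrt(max(overall * (1 - overall), 1e-6) / row["n"])
            assert abs(row["p_optimal"] - overall) < 4 * se

    def test_more_bins_than_trials_rejected(self, s01_psi, s01_schedule):
        classified, _ = simulate_classified(
            s01_psi, s01_schedule, ObserverPolicy(kind="fixed-mixture"), seed=30,
            reps=1,
        )
        with pytest.raises(InsufficientDataError):
            latency_vs_optimality(classified, n_bins=len(classified) + 1)


class TestPsiFromDecision:
    def test_recovers_location_parameter_from_decision_trials(
        self, s01_psi, s01_schedule
    ):
        classified, _ = simulate_classified(
            s01_psi, s01_schedule,
            ObserverPolicy(kind="fixed-mixture", p_side_base=0.5), seed=31,
        )
        fit = estimate_psi_from_decision(classified)
        assert abs(fit.params.e_half - s01_psi.e_half) < 1.0

    def test_single_separation_always_center_rejected(self, s01_psi):
        classified, _ = simulate_classified(
            s01_psi, [12.0], ObserverPolicy(kind="always-center"), seed=32, reps=24
        )
        with pytest.raises(InsufficientDataError):
            estimate_psi_from_decision(classified)

    def test_decision_and_verification_estimates_agree(
        self, s01_psi, s01_schedule, s01_prediction
    ):
        classified, _ = simulate_classified(
            s01_psi, s01_schedule,
            ObserverPolicy(kind="fixed-mixture", p_side_base=0.5), seed=33,
        )
        ver = simulate_verification_session(
            s01_schedule, 96, s01_psi, s01_prediction, NO_ABORTS, seed=33
        )
        ver_classified = classify_trials(ver, s01_prediction)
        fit_dec = estimate_psi_from_decision(classified)
        fit_ver = estimate_psi_from_decision(ver_classified)
        assert abs(fit_dec.params.e_half - fit_ver.params.e_half) < 1.5
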