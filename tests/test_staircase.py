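"""Adaptive staircase: update rule, reversal bookkeeping, threshold estimate."""

import numpy as np
import pytest

from syldiscrim import (
    Observer,
    StaircaseConfig,
    StaircaseState,
    estimate_threshold,
    logistic_observer,
    run_staircase,
    update_state,
)
from syldiscrim.staircase import EstimationError


def perfect_observer(lapse=0.0, guess=0.5):
    # threshold far below any presentable limen -> always correct on pairs
    return Observer(threshold_limen=1e-4, slope=6 / 1e-4,
                    guess_rate=guess, lapse_rate=lapse)


class TestUpdateRule:
    def test_third_correct_steps_down_two(self):
        state = StaircaseState(step=10, easiest=20, run_correct=2)
        update_state(state, correct=True)
        assert state.step == 8
        assert state.run_correct == 0
        assert state.moved

    def test_incorrect_steps_up_one(self):
        state = StaircaseState(step=10, easiest=20, run_correct=2)
        update_state(state, correct=False)
        assert state.step == 11
        assert state.run_correct == 0

    def test_incorrect_at_easiest_clamps_and_counts(self):
        state = StaircaseState(step=20, easiest=20)
        update_state(state, correct=False)
        assert state.step == 20
        assert state.consecutive_incorrect_at_easiest == 1

    def test_correct_at_easiest_resets_failure_counter(self):
        state = StaircaseState(step=20, easiest=20,
                               consecutive_incorrect_at_easiest=3)
        update_state(state, correct=True)
        assert state.consecutive_incorrect_at_easiest == 0

    def test_descent_clamps_at_hardest_pair(self):
        state = StaircaseState(step=2, easiest=20, run_correct=2)
        update_state(state, correct=True)
        assert state.step == 1  # never reaches the identical pair

    def test_alternating_responses_drift_up_one_per_two_trials(self):
        # hand-simulated: C,I,C,I,... never reaches three in a row, each
        # error steps up by one
        state = StaircaseState(step=10, easiest=20)
        for k in range(10):
            update_state(state, correct=(k % 2 == 0))
        assert state.step == 15

    def test_fine_phase_after_first_reversal(self):
        state = StaircaseState(step=10, easiest=20)
        for _ in range(3):
            update_state(state, correct=True)
        assert state.step == 8  # coarse two-step descent
        update_state(state, correct=False)  # first reversal
        assert state.n_reversals == 1
        for _ in range(3):
            update_state(state, correct=True)
        assert state.step == 8  # fine one-step descent from 9


class TestThresholdEstimate:
    def test_mean_of_last_four(self):
        limens = [600, 560, 520, 480, 520, 480, 520]
        assert estimate_threshold(limens, 4) == pytest.approx(500.0)

    def test_k_one_returns_last(self):
        assert estimate_threshold([600, 480, 520], 1) == 520

    def test_matches_brute_force_mean(self, rng):
        limens = rng.uniform(0, 800, size=9)
        expect = sum(limens[-4:]) / 4.0
        assert abs(estimate_threshold(limens, 4) - expect) < 1e-12

    def test_too_few_reversals_flagged_with_partial(self):
        with pytest.raises(EstimationError) as err:
            estimate_threshold([500, 480], 4)
        assert err.value.partial == pytest.approx(490.0)


class TestRunStaircase:
    def test_starts_at_most_discriminable_pair(self, continua):
        res = run_staircase(continua["ba_wa"], logistic_observer(30.0), seed=0)
        first_real = next(t for t in res.trials if not t.is_catch)
        assert first_real.limen == 75.0

    def test_perfect_observer_descends_monotonically(self, continua):
        res = run_staircase(continua["ba_da"], perfect_observer(), seed=1)
        steps = [t.test_step for t in res.trials if not t.is_catch]
        assert all(b <= a for a, b in zip(steps, steps[1:]))
        assert steps[-1] == 1  # clamped just above the reference
        assert res.threshold_is_partial
        # mean of the hardest limens actually reached near the reference
        assert res.threshold == pytest.approx(np.mean([40, 80, 160, 240]))

    def test_always_different_responder_fails_catches(self, continua):
        res = run_staircase(
            continua["ba_da"], perfect_observer(guess=0.0), seed=2
        )
        assert res.n_catch > 0
        assert res.n_catch_correct == 0

    def test_catch_trials_have_zero_limen_and_spacing(self, continua):
        cfg = StaircaseConfig()
        res = run_staircase(continua["ba_wa"], logistic_observer(30.0), cfg, seed=3)
        gaps, gap = [], 0
        for t in res.trials:
            if t.is_catch:
                assert t.limen == 0.0
                assert t.correct == (t.response == "same")
                gaps.append(gap)
                gap = 0
            else:
                gap += 1
        assert all(cfg.catch_min <= g <= cfg.catch_max for g in gaps)
        assert all(l > 0 for l in res.reversal_limens)

    def test_terminates_after_seven_reversals(self, continua):
        res = run_staircase(continua["ga_ka"], logistic_observer(20.0), seed=4)
        assert res.terminated_by == "reversals"
        assert len(res.reversal_limens) == 7
        assert res.threshold == pytest.approx(
            np.mean(res.reversal_limens[-4:])
        )

    def test_failure_at_easiest_terminates(self, continua):
        # an observer that is always wrong never leaves the easiest pair
        # and trips the five-consecutive-error stop
        hopeless = Observer(threshold_limen=1e6, slope=1e-5,
                            guess_rate=0.0, lapse_rate=0.0)
        res = run_staircase(continua["ba_da"], hopeless, seed=5)
        assert res.terminated_by == "failure_at_easiest"
        non_catch = [t for t in res.trials if not t.is_catch]
        assert len(non_catch) == 5

    def test_seeded_reproducibility(self, continua):
        obs = logistic_observer(300.0)
        r1 = run_staircase(continua["ba_da"], obs, seed=77)
        r2 = run_staircase(continua["ba_da"], obs, seed=77)
        assert r1.trials == r2.trials
        assert r1.threshold == r2.threshold

    @pytest.mark.parametrize("seed", range(12))
    @pytest.mark.parametrize("name", ["ba_da", "ba_wa", "ga_ka"])
    def test_threshold_within_continuum_range(self, continua, name, seed):
        c = continua[name]
        obs = logistic_observer(0.45 * c.range, seed=seed)
        res = run_staircase(c, obs, seed=seed)
        assert 0.0 <= res.threshold <= c.range


class TestConvergence:
    def test_mean_threshold_near_794_point(self, continua):
        c = continua["ba_wa"]
        target = 30.0
        obs = logistic_observer(target)
        ths = [run_staircase(c, obs, seed=s).threshold for s in range(150)]
        assert np.mean(ths) == pytest.approx(target, rel=0.15)

    def test_more_reversals_do_not_worsen_convergence(self, continua):
        c = continua["ba_wa"]
        target = 30.0
        obs = logistic_observer(target)
        bias = {}
        for stop in (7, 15):
            cfg = StaircaseConfig(reversal_stop=stop)
            ths = [run_staircase(c, obs, cfg, seed=s).threshold
                   for s in range(300)]
            bias[stop] = abs(np.mean(ths) - target)
        assert bias[15] <= max(bias[7], 0.05 * target)
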