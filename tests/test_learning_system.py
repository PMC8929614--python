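"""Detectors, categories, expectations, gain, learning rule, click, choice."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lag1.learning_system import (AssociativeWeights, BankParams, CategoryBank,
                                  ClickParams, ClickState, ExpectationBank,
                                  FeatureBank, apply_feedback_learning,
                                  choose_category, compute_gain,
                                  step_category_neurons, step_click_decision,
                                  step_feature_detectors,
                                  step_feature_expectation)

DT = 10.0


def drive_bank(bank, drives, ms, dt=DT):
    for _ in range(int(ms / dt)):
        step_feature_detectors(bank, drives, dt)
    return bank


class TestFeatureDetectors:
    def test_working_memory_outlasts_drive(self):
        """300 ms of suprathreshold drive, then none: output stays above 0.5
        for at least five seconds (the multi-fixation memory regime)."""
        bank = FeatureBank(3)
        d = np.zeros(6)
        d[2] = 2.0
        drive_bank(bank, d, 300.0)
        d[2] = 0.0
        for _ in range(int(5000 / DT)):
            step_feature_detectors(bank, d, DT)
            assert bank.output()[2] > 0.5

    def test_pair_competition_silences_weaker_value(self):
        bank = FeatureBank(3)
        d = np.zeros(6)
        d[0], d[1] = 2.0, 1.0  # both members driven, one twice as strong
        drive_bank(bank, d, 4000.0)
        out = bank.output()
        assert out[0] > 0.5
        assert out[1] < 0.1

    def test_undriven_bank_stays_at_rest(self):
        bank = FeatureBank(3)
        drive_bank(bank, np.zeros(6), 2000.0)
        assert np.allclose(bank.u, bank.params.h, atol=0.1)

    def test_drive_length_must_match(self):
        with pytest.raises(ValueError):
            step_feature_detectors(FeatureBank(3), np.zeros(4), DT)


class TestGain:
    def test_equal_weights_carry_no_information(self):
        w = AssociativeWeights(4, 3)
        w.W[0, 0] = w.W[0, 1] = 0.5
        gain = compute_gain(w, kappa=1.0)
        assert gain[0, 0] == pytest.approx(1.0)  # d = 0

    def test_large_contrast_is_diagnostic(self):
        w = AssociativeWeights(4, 3)
        w.W[0, 0], w.W[0, 1] = 0.02, 0.98
        d = compute_gain(w, kappa=1.0)[0, 0] - 1.0
        assert d == pytest.approx(0.96)

    def test_invariant_under_pair_label_swap(self, rng):
        w = AssociativeWeights(4, 3, rng)
        g1 = compute_gain(w)
        w.W[:, [0, 1]] = w.W[:, [1, 0]]
        assert np.allclose(compute_gain(w), g1)


class TestCategoryNeurons:
    def test_uniform_weights_give_symmetric_inputs(self):
        bank = CategoryBank(4)
        w = AssociativeWeights(4, 3, jitter=0.0)
        fd = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        for _ in range(200):
            step_category_neurons(bank, fd, w, 1.0, DT)
        assert np.ptp(bank.u) < 1e-9

    def test_feedback_boost_wins_within_500ms(self):
        bank = CategoryBank(4)
        w = AssociativeWeights(4, 3, jitter=0.0)
        fd = np.zeros(6)
        for _ in range(int(500 / DT)):
            step_category_neurons(bank, fd, w, 1.0, DT,
                                  feedback_boost_idx=2, boost_drive=1.0)
        out = bank.output()
        assert np.argmax(out) == 2
        assert out[2] > 0.9
        assert np.all(np.delete(out, 2) < 0.2)

    def test_trained_weights_separate_categories(self):
        """A weight state learned on the 4-category structure drives the
        A-side categories above the B-side for an A stimulus pattern."""
        w = AssociativeWeights(4, 3, jitter=0.0)
        # idealised post-learning state: A1 on (F1=0, F2=0), A2 on (0,1),
        # B1 on (1, F3=0), B2 on (1,1); F3 irrelevant for A, F2 for B
        w.W[:] = 0.2
        w.W[0, [0, 2]] = 0.9
        w.W[1, [0, 3]] = 0.9
        w.W[2, [1, 4]] = 0.9
        w.W[3, [1, 5]] = 0.9
        bank = CategoryBank(4)
        fd = np.array([1.0, 0, 1.0, 0, 1.0, 0])  # stimulus (0, 0, 0)
        for _ in range(300):
            step_category_neurons(bank, fd, w, 1.0, DT)
        out = bank.output()
        assert max(out[0], out[1]) > max(out[2], out[3])


class TestExpectation:
    def test_rest_without_category_activity(self):
        bank = ExpectationBank(3)
        w = AssociativeWeights(4, 3)
        for _ in range(100):
            step_feature_expectation(bank, np.zeros(4), w, 1.0, np.zeros(6), DT)
        assert np.all(bank.output() < 0.05)

    def test_unseen_diagnostic_feature_wins_expectation_race(self):
        w = AssociativeWeights(4, 3, jitter=0.0)
        w.W[:] = 0.2
        w.W[0, [0, 2]] = 0.9    # A1 diagnosed by F1=0 and F2=0
        bank = ExpectationBank(3)
        cats = np.array([1.0, 0.0, 0.0, 0.0])
        fd = np.array([1.0, 0, 0, 0, 0, 0])  # F1 already inspected
        for _ in range(200):
            step_feature_expectation(bank, cats, w, 1.0, fd, DT)
        out = bank.output()
        assert out[2] > out[0]          # unseen diagnostic beats seen
        assert out[2] > max(out[4], out[5])  # and beats the irrelevant slot

    def test_uniform_weights_give_uniform_expectation(self):
        w = AssociativeWeights(4, 3, jitter=0.0)
        bank = ExpectationBank(3)
        cats = np.array([1.0, 0.0, 0.0, 0.0])
        for _ in range(200):
            step_feature_expectation(bank, cats, w, 1.0, np.zeros(6), DT)
        assert np.ptp(bank.u) < 1e-9


class TestFeedbackLearning:
    def test_increment_is_linear_in_co_activation_time(self):
        """800 ms of constant co-activation earns exactly 4x the pre-bound
        increment of 200 ms."""
        fd = np.array([0.6, 0, 0.6, 0, 0, 0])
        rate = 1e-7  # small enough that the soft bound stays ~1 throughout

        def total(ms):
            w = AssociativeWeights(2, 3, jitter=0.0, init=0.0)
            for _ in range(int(ms / DT)):
                # init 0 keeps the soft bound factor (1 - W) ~ 1 throughout
                apply_feedback_learning(w, fd, 0, 0, rate, DT)
            return w.W[0, 0]

        assert total(800.0) == pytest.approx(4 * total(200.0), rel=1e-4)

    def test_no_activity_no_change(self):
        w = AssociativeWeights(4, 3, jitter=0.0)
        before = w.W.copy()
        apply_feedback_learning(w, np.zeros(6), 0, 1, 1e-4, DT)
        assert np.array_equal(w.W, before)

    def test_incorrect_guess_decouples_chosen_category(self):
        w = AssociativeWeights(4, 3, jitter=0.0)
        fd = np.array([1.0, 0, 1.0, 0, 0, 0])
        before = w.W.copy()
        apply_feedback_learning(w, fd, correct=0, chosen=2, rate=1e-4, dt=DT)
        active = [0, 2]
        assert np.all(w.W[2, active] < before[2, active])
        assert np.all(w.W[0, active] > before[0, active])

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            apply_feedback_learning(AssociativeWeights(2, 3), np.zeros(6),
                                    0, 0, -1e-5, DT)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_weights_always_bounded(self, seed):
        rng = np.random.default_rng(seed)
        w = AssociativeWeights(4, 3, rng)
        for _ in range(50):
            fd = rng.uniform(0, 1, 6)
            apply_feedback_learning(w, fd, int(rng.integers(4)),
                                    int(rng.integers(4)),
                                    rate=10 ** rng.uniform(-6, -2), dt=DT,
                                    correct_active=bool(rng.integers(2)))
            assert np.all((w.W >= 0.0) & (w.W <= 1.0))


def time_to_first_click(trial_impatience, cat_level=0.05, dt=DT,
                        max_ms=20000.0):
    state = ClickState(ClickParams(trial_impatience=trial_impatience))
    cats = np.full(4, cat_level)
    t = 0.0
    while t < max_ms:
        ev = step_click_decision(state, cats, False, dt)
        t += dt
        if ev == "RESPOND":
            return t
    return np.inf


class TestClickDecision:
    def test_trial_impatience_speeds_response(self):
        times = [time_to_first_click(ti) for ti in (1.6, 1.8, 2.05)]
        assert times[0] > times[1] > times[2]

    def test_liveness_with_zero_knowledge(self):
        assert time_to_first_click(1.6, cat_level=0.0) < np.inf

    def test_saturated_category_double_clicks_through_feedback(self):
        """With the correct category saturated at feedback onset, the
        second threshold falls within a couple of fixation durations."""
        state = ClickState(ClickParams(trial_impatience=1.8))
        cats = np.array([1.0, 0.0, 0.0, 0.0])
        t = 0.0
        while step_click_decision(state, cats, False, DT) != "RESPOND":
            t += DT
        gap = 0.0
        while step_click_decision(state, cats, True, DT) != "END_TRIAL":
            gap += DT
            assert gap < 20000
        assert gap < 800.0  # ~ two fixations

    def test_theta_ordering_enforced(self):
        with pytest.raises(ValueError):
            ClickState(ClickParams(theta1=2.0, theta2=1.0))


class TestChooseCategory:
    def test_uniform_outputs_are_chance(self, rng):
        outs = np.full(4, 0.3)
        picks = np.array([choose_category(outs, rng) for _ in range(10_000)])
        freqs = np.bincount(picks, minlength=4) / picks.size
        assert np.all(np.abs(freqs - 0.25) < 0.02)

    def test_saturated_output_dominates(self, rng):
        outs = np.array([0.001, 1.0, 0.001, 0.001])
        picks = [choose_category(outs, rng) for _ in range(2000)]
        assert np.mean(np.asarray(picks) == 1) > 0.99

    def test_three_to_one_ratio(self, rng):
        outs = np.array([0.75, 0.25])
        picks = np.array([choose_category(outs, rng) for _ in range(10_000)])
        ratio = np.mean(picks == 0) / np.mean(picks == 1)
        assert ratio == pytest.approx(3.0, rel=0.15)
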