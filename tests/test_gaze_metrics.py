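"""Fixation detection, AOI labelling, and the behavioural measure pipeline."""

import numpy as np
import pandas as pd
import pytest

from lag1 import gaze_metrics as gm
from lag1.experiment_harness import RawDataset, build_structure, counterbalance
from lag1.visuospatial import sim1_layout


def samples_df(rows):
    return pd.DataFrame(rows, columns=["trial", "t_ms", "x", "y",
                                       "phase", "in_saccade"])


def stationary(t0, n, x, y, dt=10.0, trial=0, phase="response", sac=0):
    return [(trial, t0 + i * dt, x, y, phase, sac) for i in range(n)]


def brute_force_idt(t, x, y, thr, min_dur, dt):
    """Greedy maximal-window I-DT recomputing dispersion from scratch."""
    out = []
    i, n = 0, len(t)
    while i < n:
        j = i + 1
        while j <= n:
            xs, ys = x[i:j], y[i:j]
            if (xs.max() - xs.min()) + (ys.max() - ys.min()) > thr:
                break
            j += 1
        j -= 1
        if j > i:
            dur = t[j - 1] - t[i] + dt
            if dur >= min_dur:
                out.append((t[i], dur, x[i:j].mean(), y[i:j].mean()))
                i = j
                continue
        i += 1
    return out


class TestDetectFixations:
    def test_stationary_samples_single_fixation(self):
        df = samples_df(stationary(0.0, 50, 20.0, 30.0))
        fx = gm.detect_fixations(df)
        assert len(fx) == 1
        assert fx[0].duration == pytest.approx(500.0)
        assert (fx[0].x, fx[0].y) == (20.0, 30.0)

    def test_two_episodes_two_fixations(self):
        rows = stationary(0.0, 30, 20.0, 30.0) + \
            stationary(300.0, 30, 45.0, 10.0)
        fx = gm.detect_fixations(samples_df(rows))
        assert len(fx) == 2
        assert (fx[0].x, fx[1].x) == (20.0, 45.0)

    def test_empty_input_empty_output(self):
        assert gm.detect_fixations(samples_df([])) == []

    def test_saccade_samples_break_windows(self):
        rows = stationary(0.0, 30, 20.0, 30.0) + \
            [(0, 300.0 + i * 10, 30.0, 30.0, "response", 1) for i in range(3)] + \
            stationary(330.0, 30, 20.0, 30.0)
        fx = gm.detect_fixations(samples_df(rows))
        assert len(fx) == 2

    def test_matches_exhaustive_window_oracle(self, rng):
        """50 random-walk traces: I-DT output equals the brute-force greedy
        maximal-window computation exactly."""
        for _ in range(50):
            n = int(rng.integers(20, 120))
            x = np.cumsum(rng.normal(0, 1.2, n)) + 30
            y = np.cumsum(rng.normal(0, 1.2, n)) + 30
            t = np.arange(n) * 10.0
            df = samples_df([(0, t[i], x[i], y[i], "response", 0)
                             for i in range(n)])
            got = gm.detect_fixations(df, dispersion_threshold=5.0,
                                      min_duration=60.0)
            want = brute_force_idt(t, x, y, 5.0, 60.0, 10.0)
            assert len(got) == len(want)
            for g, w in zip(got, want):
                assert g.onset == pytest.approx(w[0])
                assert g.duration == pytest.approx(w[1])
                assert g.x == pytest.approx(w[2])


class TestAssignAoi:
    def test_centroid_on_feature_gets_its_label(self):
        layout = sim1_layout()
        fx = [gm.Fixation(0, 0, 100, *layout.feature_locations[1])]
        gm.assign_aoi(fx, layout)
        assert fx[0].aoi == 1

    def test_far_fixation_unlabelled(self):
        layout = sim1_layout()
        fx = [gm.Fixation(0, 0, 100, 2.0, 2.0)]
        gm.assign_aoi(fx, layout)
        assert fx[0].aoi is None

    def test_button_label(self):
        layout = sim1_layout()
        fx = [gm.Fixation(0, 0, 100, *layout.button_location)]
        gm.assign_aoi(fx, layout)
        assert fx[0].aoi == "button"

    def test_tie_goes_to_lowest_index(self):
        layout = sim1_layout()
        a = np.asarray(layout.feature_locations[1], float)
        b = np.asarray(layout.feature_locations[2], float)
        mid = (a + b) / 2
        fx = [gm.Fixation(0, 0, 100, *mid)]
        gm.assign_aoi(fx, layout, radius=30.0)
        assert fx[0].aoi == 1


def toy_dataset(blair):
    """Handcrafted two-trial dataset with known fixation structure."""
    layout = sim1_layout()
    locs = layout.feature_locations
    rows = []
    # trial 0 (stimulus 0, an A1 stimulus): fixations at locations 0 and 1
    rows += stationary(0.0, 30, *locs[0], trial=0)
    rows += stationary(300.0, 30, *locs[1], trial=0)
    rows += stationary(600.0, 30, *locs[1], trial=0, phase="feedback")
    # trial 1 (stimulus 4, a B1 stimulus): same fixation locations
    rows += stationary(0.0, 30, *locs[0], trial=1)
    rows += stationary(300.0, 30, *locs[1], trial=1)
    gaze = samples_df(rows)
    gaze.insert(0, "subject", "toy")
    trials = pd.DataFrame([
        {"subject": "toy", "trial": 0, "stimulus_id": 0,
         "stimulus_label": "A1", "phase_type": "training", "response": "A1",
         "correct": 1, "rt_ms": 600.0, "feedback_ms": 300.0,
         "trial_ms": 900.0, "truncated": False},
        {"subject": "toy", "trial": 1, "stimulus_id": 4,
         "stimulus_label": "B1", "phase_type": "training", "response": "A1",
         "correct": 0, "rt_ms": 600.0, "feedback_ms": 0.0,
         "trial_ms": 600.0, "truncated": False},
    ])
    return RawDataset(trials=trials, gaze=gaze, structure="blair",
                      counterbalance=counterbalance(blair, 0))


class TestTrialMeasures:
    def test_stimulus_specific_irrelevant_flag(self, blair):
        """Fixating locations 1 and 2 only: not irrelevant viewing for an A
        stimulus (F3 is A's irrelevant feature) but irrelevant viewing for a
        B stimulus (F2 is B's)."""
        ds = toy_dataset(blair)
        fx = gm.dataset_fixations(ds, sim1_layout())
        meas = gm.trial_measures(ds, fx, blair)
        # fixations at locations 0 and 1; A1's irrelevant location is 2
        assert meas.loc[0, "irrelevant_fixated"] == 0
        # B1's irrelevant location is 1, which was fixated
        assert meas.loc[1, "irrelevant_fixated"] == 1

    def test_counts_and_durations(self, blair):
        ds = toy_dataset(blair)
        fx = gm.dataset_fixations(ds, sim1_layout())
        meas = gm.trial_measures(ds, fx, blair)
        assert meas.loc[0, "fix_count"] == 2
        assert meas.loc[0, "mean_fix_dur_ms"] == pytest.approx(300.0)
        assert meas.loc[0, "feedback_feature_ms"] == pytest.approx(300.0)


class TestBinsAndSummaries:
    def test_360_trials_give_24_bins(self):
        meas = pd.DataFrame({
            "trial": np.arange(360),
            "phase_type": "training",
            "accuracy": np.ones(360),
            "fix_count": np.full(360, 5.0),
        })
        b = gm.bin_measures(meas, 15, columns=("accuracy", "fix_count"))
        assert len(b) == 24
        assert np.allclose(b[("fix_count", "mean")], 5.0)

    def test_bins_equal_brute_force_group_means(self, rng):
        vals = rng.normal(size=45)
        meas = pd.DataFrame({"trial": np.arange(45), "phase_type": "training",
                             "accuracy": vals})
        b = gm.bin_measures(meas, 15, columns=("accuracy",))
        for k in range(3):
            assert b[("accuracy", "mean")].iloc[k] == \
                pytest.approx(vals[15 * k:15 * (k + 1)].mean())

    def test_learning_point(self):
        acc = [1] * 40
        df = pd.DataFrame({"trial": range(40), "phase_type": "training",
                           "accuracy": acc})
        assert gm.learning_point(df, 8) == 1
        acc = [1] * 8 + [0] + [1] * 23
        df = pd.DataFrame({"trial": range(32), "phase_type": "training",
                           "accuracy": acc})
        # blocks: clean, dirty, clean, clean -> two clean blocks start at 17
        assert gm.learning_point(df, 8) == 17
        acc = ([1] * 7 + [0]) * 5
        df = pd.DataFrame({"trial": range(40), "phase_type": "training",
                           "accuracy": acc})
        assert gm.learning_point(df, 8) == 41  # sentinel: never reached

    def test_constant_measure_gives_zero_slope(self):
        inter, slope = gm._ols_line(np.full(24, 3.3))
        assert inter == pytest.approx(3.3)
        assert slope == pytest.approx(0.0)

    def test_linear_measure_recovers_generating_slope(self):
        y = 2.0 + 0.5 * np.arange(24)
        inter, slope = gm._ols_line(y)
        assert inter == pytest.approx(2.0)
        assert slope == pytest.approx(0.5)


class TestWithinTrialProbability:
    def test_single_feature_trial_probability_one(self, blair):
        layout = sim1_layout()
        rows = stationary(0.0, 60, *layout.feature_locations[1], trial=0)
        gaze = samples_df(rows)
        gaze.insert(0, "subject", "toy")
        trials = pd.DataFrame([{
            "subject": "toy", "trial": 0, "stimulus_id": 0,
            "stimulus_label": "A1", "phase_type": "training",
            "response": "A1", "correct": 1, "rt_ms": 600.0,
            "feedback_ms": 0.0, "trial_ms": 600.0, "truncated": False}])
        ds = RawDataset(trials=trials, gaze=gaze, structure="blair",
                        counterbalance=counterbalance(blair, 0))
        fx = gm.dataset_fixations(ds, layout)
        prob = gm.within_trial_probability(ds, fx, blair)
        assert prob.shape == (3, 5)
        assert np.allclose(prob[1], 1.0)
        assert np.allclose(prob[[0, 2]], 0.0)

    def test_probabilities_sum_to_one_when_defined(self, blair):
        ds = toy_dataset(blair)
        fx = gm.dataset_fixations(ds, sim1_layout())
        prob = gm.within_trial_probability(ds, fx, blair)
        sums = prob.sum(axis=0)
        ok = np.isfinite(sums)
        assert np.allclose(sums[ok], 1.0)

    def test_two_trial_occupancy_matches_hand_computation(self, blair):
        # both trials: location 0 for the first 300 ms, location 1 for the
        # next 300 ms -> feature 1 occupies the first half, feature 2 the
        # second (identity counterbalance)
        ds = toy_dataset(blair)
        fx = gm.dataset_fixations(ds, sim1_layout())
        prob = gm.within_trial_probability(ds, fx, blair)
        assert np.allclose(prob[0, :2], 1.0)
        assert np.allclose(prob[1, 3:], 1.0)


class TestSummaryVector:
    def test_sim1_vector_has_eight_elements(self, sim1_run_short):
        v = gm.summary_vector(sim1_run_short, "sim1", bin_size=10)
        assert v.shape == (8,)
        assert np.all(np.isfinite(v))

    def test_unknown_kind_rejected(self, sim1_run_short):
        with pytest.raises(ValueError):
            gm.summary_vector(sim1_run_short, "sim3")
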