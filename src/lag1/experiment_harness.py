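"""Category structures, the two-phase trial state machine, and experiments.

A trial runs as it does for a human participant: gaze is re-centred by a
fixation cross, the stimulus appears, the model looks around until its Click
Decision Neuron crosses the response threshold (the category choice is
sampled by the Luce rule at that moment), then the feedback phase re-presents
the stimulus together with a correct-answer button in the periphery;
associative learning runs on every feedback timestep, and the trial ends at
the second click threshold.  Transfer trials skip feedback and learning.

Raw output mirrors an eye-tracking session: a gaze-sample stream
(t, x, y, phase, in_saccade) at the integration rate plus a per-trial table.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ModelParams
from .dnf_core import NeuralField, sigmoid
from .learning_system import (AssociativeWeights, CategoryBank, ClickState,
                              ExpectationBank, FeatureBank,
                              apply_feedback_learning, choose_category,
                              step_category_neurons, step_click_decision,
                              step_feature_detectors, step_feature_expectation)
from .saccade_timing import TimingState, execute_saccade, select_target, step_timing
from .visuospatial import (GazeState, StimulusLayout, VisuospatialState, _blob,
                           foveal_readout, render_input, sim1_layout,
                           sim2_layout, step_visuospatial)

__all__ = [
    "CategoryStructure", "ExperimentConfig", "RawDataset", "Lag1Model",
    "build_structure", "counterbalance", "run_trial", "run_experiment",
]


@dataclass(frozen=True)
class CategoryStructure:
    """Stimuli as feature-value tuples with category labels.

    ``relevance[s]`` gives, for training stimulus index ``s``, the feature
    slot that is irrelevant for classifying it (or None).  ``diagnosticity``
    ranks each feature slot (higher = more diagnostic) for structures with a
    fixed feature-level relevance ordering.
    """

    name: str
    stimuli: tuple[tuple[int, ...], ...]
    labels: tuple[str, ...]
    categories: tuple[str, ...]
    training: tuple[int, ...]
    transfer: tuple[int, ...]
    irrelevant: dict
    diagnosticity: tuple[float, ...]

    @property
    def n_features(self) -> int:
        return len(self.stimuli[0])

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    def label_index(self, stim_idx: int) -> int:
        return self.categories.index(self.labels[stim_idx])


def build_structure(name: str) -> CategoryStructure:
    """The two printed category structures.

    ``blair``: 8 stimuli over 3 binary features and 4 categories; Feature 1
    splits A from B, Feature 2 splits A1/A2 (irrelevant for B), Feature 3
    splits B1/B2 (irrelevant for A).

    ``five_four``: the classic 5/4 structure: 9 training stimuli (5 A, 4 B)
    over 4 binary features plus 7 unlabelled transfer stimuli; Feature 1 is
    of low, Feature 2 medium, Features 3 and 4 high diagnosticity.
    """
    if name == "blair":
        rows = [
            ((0, 0, 0), "A1"), ((0, 0, 1), "A1"),
            ((0, 1, 0), "A2"), ((0, 1, 1), "A2"),
            ((1, 0, 0), "B1"), ((1, 1, 0), "B1"),
            ((1, 0, 1), "B2"), ((1, 1, 1), "B2"),
        ]
        stimuli, labels = zip(*rows)
        irrelevant = {i: (2 if labels[i].startswith("A") else 1)
                      for i in range(len(rows))}
        return CategoryStructure(
            name=name, stimuli=stimuli, labels=labels,
            categories=("A1", "A2", "B1", "B2"),
            training=tuple(range(8)), transfer=(),
            irrelevant=irrelevant, diagnosticity=(3.0, 2.0, 2.0))
    if name == "five_four":
        rows = [
            ((1, 0, 1, 1), "A1"), ((0, 0, 1, 1), "A2"), ((0, 1, 1, 1), "A3"),
            ((1, 1, 1, 0), "A4"), ((1, 1, 0, 1), "A5"),
            ((1, 0, 1, 0), "B1"), ((1, 0, 0, 1), "B2"), ((0, 1, 0, 0), "B3"),
            ((0, 0, 0, 0), "B4"),
            ((0, 1, 1, 0), "T1"), ((0, 0, 1, 0), "T2"), ((1, 1, 1, 1), "T3"),
            ((0, 0, 0, 1), "T4"), ((1, 1, 0, 1), "T5"), ((0, 1, 0, 1), "T6"),
            ((1, 0, 0, 0), "T7"),
        ]
        stimuli, labels = zip(*rows)
        cat_of = tuple(l[0] if l[0] in "AB" else l for l in labels)
        return CategoryStructure(
            name=name, stimuli=stimuli, labels=cat_of,
            categories=("A", "B"),
            training=tuple(range(9)), transfer=tuple(range(16)),
            irrelevant={}, diagnosticity=(1.0, 2.0, 3.0, 3.0))
    raise ValueError(f"unknown category structure {name!r}")


@dataclass(frozen=True)
class Counterbalance:
    """Assignment of abstract features to screen locations and of abstract
    values to value identities (a per-subject permutation)."""

    feature_to_location: tuple[int, ...]
    value_flip: tuple[int, ...]

    def place(self, stimulus: tuple[int, ...]) -> dict:
        """Map an abstract stimulus to {location: displayed value}."""
        return {self.feature_to_location[f]: v ^ self.value_flip[f]
                for f, v in enumerate(stimulus)}

    def location_of(self, feature: int) -> int:
        return self.feature_to_location[feature]


def counterbalance(structure: CategoryStructure, seed: int) -> Counterbalance:
    """Deterministic permutation per seed; seed 0 is the identity."""
    n = structure.n_features
    if seed == 0:
        return Counterbalance(tuple(range(n)), (0,) * n)
    rng = np.random.default_rng(seed)
    return Counterbalance(tuple(rng.permutation(n).tolist()),
                          tuple(rng.integers(0, 2, size=n).tolist()))


# ---------------------------------------------------------------------------
# model assembly


class Lag1Model:
    """The full model: visuospatial fields, saccade timing trio, and the
    learning system, wired per trial phase."""

    def __init__(self, structure: CategoryStructure, layout: StimulusLayout,
                 params: ModelParams, rng: np.random.Generator):
        self.structure = structure
        self.layout = layout
        self.p = params
        self.rng = rng
        g = params.grid
        self.vs = VisuospatialState(
            visual=NeuralField(params.visual, "visual"),
            attention=NeuralField(params.attention, "attention"),
            motor=NeuralField(params.motor, "motor"),
            fovea_sigma=params.fovea_sigma)
        self.gaze = GazeState(position=np.array([(g - 1) / 2.0, (g - 1) / 2.0]))
        self.timing = TimingState(params.timing)
        self.fd = FeatureBank(layout.n_locations, params.fd_bank)
        self.cat = CategoryBank(structure.n_categories, params.cat_bank)
        self.exp = ExpectationBank(layout.n_locations, params.exp_bank)
        self.W = AssociativeWeights(structure.n_categories, layout.n_locations,
                                    rng, params.w_init, params.w_jitter)
        self.click = ClickState(params.click)
        # unit spatiotopic blobs per feature location, for expectation boosts
        self.loc_blobs = np.stack([
            _blob(g, g, loc, params.fovea_sigma)
            for loc in layout.feature_locations])
        self._stack = None
        self._drives = None
        # expectation -> attention location reentry; disabled for tasks where
        # feature locations are unknown (visual search)
        self.location_reentry = True

    # -- caches -----------------------------------------------------------
    def _invalidate(self) -> None:
        self._stack = None

    def _ensure_stack(self, stimulus: dict, phase: str) -> None:
        if self._stack is None:
            p = self.p
            self._stack = render_input(
                stimulus, self.layout, self.gaze, phase,
                fovea_sigma=p.fovea_sigma, stim_sigma=p.stim_sigma,
                stim_amp=p.stim_amp, button_amp=p.button_amp,
                acuity_k=p.acuity_k, acuity_floor=p.acuity_floor)
            self._drives = foveal_readout(self._stack, p.fovea_sigma,
                                          p.stim_sigma)

    def reset_trial(self) -> None:
        g = self.p.grid
        self.vs.reset()
        self.gaze.position = np.array([(g - 1) / 2.0, (g - 1) / 2.0])
        self.gaze.fixation_onset = 0.0
        self.gaze.in_saccade = False
        self.timing.reset_fixation()
        self.timing.u_x.reset()
        for bank in (self.fd, self.cat, self.exp):
            bank.reset()
        self.click.reset()
        self._invalidate()

    # -- one timestep ------------------------------------------------------
    def step(self, stimulus: dict, phase: str, correct_idx: int,
             chosen_idx: int | None, t: float, learn: bool,
             salience: np.ndarray | None = None,
             select_mode: str | None = None) -> str | None:
        p = self.p
        dt = p.dt
        feedback = phase == "feedback"
        self._ensure_stack(stimulus, phase)

        f_exp = self.exp.output()
        visual_gains = p.c_rv * f_exp
        if self.location_reentry:
            loc_act = f_exp[0::2] + f_exp[1::2]
            boosts = p.c_eb * np.tensordot(loc_act, self.loc_blobs, axes=(0, 0))
        else:
            boosts = np.zeros_like(self.vs.attention.u)
        step_visuospatial(
            self.vs, self._stack, visual_gains, boosts,
            fixation_boost=self.timing.u_x.output(), gaze=self.gaze,
            dt=dt, rng=self.rng, c_va=p.c_va, c_am=p.c_am, c_fix=p.c_fix,
            fix_inh_amp=p.fix_inh_amp, fix_inh_sigma=p.fix_inh_sigma,
            salience=salience)

        drives = self._drives
        feat_drives = drives[:-1]
        button_drive = drives[-1] / p.button_amp if feedback else 0.0
        step_feature_detectors(self.fd, feat_drives, dt, self.rng, c_in=p.c_in)
        f_fd = self.fd.output()
        step_category_neurons(
            self.cat, f_fd, self.W, p.kappa, dt, self.rng,
            feedback_boost_idx=correct_idx if feedback else None,
            boost_drive=min(button_drive, 1.0), c_w=p.c_w)
        f_cat = self.cat.output()
        step_feature_expectation(self.exp, f_cat, self.W, p.kappa, f_fd, dt,
                                 self.rng, c_bw=p.c_bw, c_fd=p.c_fd)
        event = step_click_decision(self.click, f_cat, feedback, dt, self.rng)

        if feedback and learn and p.learning_rate > 0 and chosen_idx is not None:
            apply_feedback_learning(
                self.W, f_fd, correct_idx, chosen_idx,
                p.learning_rate * p.learning_scale, dt,
                correct_active=f_cat[correct_idx] >= 0.5)

        motor_peak = float(sigmoid(self.vs.motor.u.max(),
                                   p.motor.beta, p.motor.theta))
        step_timing(self.timing, float(feat_drives.sum()) +
                    (drives[-1] / p.button_amp if feedback else 0.0),
                    motor_peak, dt, self.rng)

        # saccade bookkeeping
        if self.gaze.in_saccade and t + dt >= self.gaze.fixation_onset:
            self.gaze.in_saccade = False
        elif not self.gaze.in_saccade and self.timing.saccade_pending():
            target = select_target(self.vs.motor,
                                   select_mode or p.target_mode, self.rng)
            execute_saccade(self.gaze, target, self.timing, self.vs, t + dt)
            self._invalidate()
        return event


# ---------------------------------------------------------------------------
# trials and experiments


@dataclass
class ExperimentConfig:
    structure: str = "blair"
    n_trials: int = 360
    learning_rate: float = 1.1e-5
    fixation_impatience: float = 1.7
    trial_impatience: float = 1.8
    seed: int = 0
    subject: str = "sim"
    max_training_trials: int = 189      # five_four stopping rule
    correct_streak_stop: int = 18
    transfer_repeats: int = 2
    block_randomized: bool = True
    params: ModelParams | None = None

    def model_params(self) -> ModelParams:
        p = self.params or ModelParams()
        p.learning_rate = self.learning_rate
        p.fixation_impatience = self.fixation_impatience
        p.trial_impatience = self.trial_impatience
        p.timing.lambda_P2 = self.fixation_impatience
        p.click.trial_impatience = self.trial_impatience
        return p


@dataclass
class RawDataset:
    """Raw simulated session: per-trial table + 100 Hz gaze stream."""

    trials: pd.DataFrame
    gaze: pd.DataFrame
    structure: str
    counterbalance: Counterbalance | None = None

    def write_csv(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.trials.to_csv(outdir / "trials.csv", index=False)
        self.gaze.to_csv(outdir / "gaze.csv", index=False)

    @classmethod
    def read_csv(cls, outdir, structure: str = "blair") -> "RawDataset":
        outdir = Path(outdir)
        return cls(trials=pd.read_csv(outdir / "trials.csv"),
                   gaze=pd.read_csv(outdir / "gaze.csv"),
                   structure=structure)


def run_trial(model: Lag1Model, stim_idx: int, cb: Counterbalance,
              trial_idx: int, rng: np.random.Generator,
              transfer: bool = False, learn: bool = True):
    """Run one two-phase trial; returns (record dict, samples array)."""
    structure = model.structure
    stimulus = cb.place(structure.stimuli[stim_idx])
    correct_idx = structure.label_index(stim_idx) if not transfer else \
        _nearest_label(structure, stim_idx)
    model.reset_trial()
    p = model.p
    dt = p.dt
    phase = "transfer" if transfer else "response"
    samples = []
    t = 0.0
    chosen = None
    rt_ms = np.nan
    truncated = False
    while True:
        step_phase = "feedback" if phase == "feedback" else "response"
        event = model.step(stimulus, step_phase, correct_idx, chosen, t,
                           learn=learn and not transfer)
        t += dt
        samples.append((t, model.gaze.position[0], model.gaze.position[1],
                        phase, model.gaze.in_saccade))
        if event == "RESPOND":
            chosen = choose_category(model.cat.output(), rng)
            rt_ms = t
            if transfer:
                break
            phase = "feedback"
            model._invalidate()
        elif event == "END_TRIAL":
            break
        if t >= p.max_trial_ms:
            truncated = True
            if chosen is None:
                chosen = choose_category(model.cat.output(), rng)
                rt_ms = t
            break
    record = {
        "trial": trial_idx,
        "stimulus_id": stim_idx,
        "stimulus_label": structure.labels[stim_idx],
        "phase_type": "transfer" if transfer else "training",
        "response": structure.categories[chosen],
        "correct": int(structure.categories[chosen] == structure.labels[stim_idx])
        if not transfer or structure.labels[stim_idx] in structure.categories
        else np.nan,
        "rt_ms": rt_ms,
        "feedback_ms": (t - rt_ms) if not transfer else 0.0,
        "trial_ms": t,
        "truncated": truncated,
    }
    return record, samples


def _nearest_label(structure: CategoryStructure, stim_idx: int) -> int:
    """Nominal 'correct' index for an unlabelled transfer stimulus (unused
    for learning; transfer trials are feedback-free)."""
    lab = structure.labels[stim_idx]
    if lab in structure.categories:
        return structure.categories.index(lab)
    return 0


def _training_sequence(structure: CategoryStructure, n_trials: int,
                       rng: np.random.Generator,
                       block_randomized: bool) -> list[int]:
    train = list(structure.training)
    if block_randomized:
        seq = []
        while len(seq) < n_trials:
            block = list(train)
            rng.shuffle(block)
            seq.extend(block)
        return seq[:n_trials]
    return [int(rng.choice(train)) for _ in range(n_trials)]


def run_experiment(config: ExperimentConfig,
                   progress: bool = False) -> RawDataset:
    """Run a whole simulated subject; identical seed gives identical output."""
    structure = build_structure(config.structure)
    layout = sim1_layout() if config.structure == "blair" else sim2_layout()
    rng = np.random.default_rng(config.seed)
    cb = counterbalance(structure, int(rng.integers(1 << 31)))
    params = config.model_params()
    model = Lag1Model(structure, layout, params, rng)

    records, gaze_rows = [], []
    trial_idx = 0

    def _log(rec, samples):
        records.append(rec)
        tr = rec["trial"]
        gaze_rows.extend((config.subject, tr, s[3], s[0], s[1], s[2], int(s[4]))
                         for s in samples)

    if config.structure == "blair":
        seq = _training_sequence(structure, config.n_trials, rng,
                                 config.block_randomized)
        for stim in seq:
            rec, samples = run_trial(model, stim, cb, trial_idx, rng)
            _log(rec, samples)
            trial_idx += 1
    else:
        seq = _training_sequence(structure, config.max_training_trials, rng,
                                 config.block_randomized)
        streak = 0
        for stim in seq:
            rec, samples = run_trial(model, stim, cb, trial_idx, rng)
            _log(rec, samples)
            trial_idx += 1
            streak = streak + 1 if rec["correct"] == 1 else 0
            if streak >= config.correct_streak_stop:
                break
        transfer_seq = []
        for _ in range(config.transfer_repeats):
            rep = list(structure.transfer)
            rng.shuffle(rep)
            transfer_seq.extend(rep)
        for stim in transfer_seq:
            rec, samples = run_trial(model, stim, cb, trial_idx, rng,
                                     transfer=True, learn=False)
            _log(rec, samples)
            trial_idx += 1

    trials = pd.DataFrame(records)
    trials.insert(0, "subject", config.subject)
    gaze = pd.DataFrame(gaze_rows, columns=[
        "subject", "trial", "phase", "t_ms", "x", "y", "in_saccade"])
    return RawDataset(trials=trials, gaze=gaze, structure=config.structure,
                      counterbalance=cb)
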