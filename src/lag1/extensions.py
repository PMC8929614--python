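"""Free viewing over a salience map, and guided visual search.

Free viewing: a precomputed nonnegative salience grid drives the Visual
Field directly; nothing reaches the Feature Detection Neurons, so no
top-down attention forms, and saccade targets are chosen probabilistically
over the motor field so the model samples the salience landscape instead of
locking onto its maximum.

Visual search: "target" and "distractor" are categorical designations with a
hard-coded association matrix; knowledge of the target value is routed
through the Visual-Field layer reentry path only (feature-based attention:
item locations are unknown, so the location-boost path is disabled).  The
model fixates and classifies items serially until the target category
crosses threshold while the target is foveated, or trial impatience forces a
decision.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np

from .config import ModelParams
from .experiment_harness import CategoryStructure, Lag1Model
from .visuospatial import StimulusLayout

__all__ = ["SalienceInput", "SearchArray", "run_free_viewing",
           "run_visual_search"]


@dataclass
class SalienceInput:
    """2-D nonnegative salience grid matched to the Visual Field extent."""

    grid: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, float)
        if not np.all(np.isfinite(self.grid)) or np.any(self.grid < 0):
            raise ValueError("salience must be finite and nonnegative")


@dataclass
class SearchArray:
    """Items at known locations with binary feature values; at most one target."""

    locations: tuple[tuple[float, float], ...]
    values: tuple[int, ...]          # displayed value per item (0/1)
    target_value: int = 1
    target_index: int | None = None  # None = target absent

    def __post_init__(self) -> None:
        if len(self.locations) < 1:
            raise ValueError("search array needs at least one item")
        if self.target_index is not None and \
                self.values[self.target_index] != self.target_value:
            raise ValueError("target item must carry the target value")


@dataclass
class FreeViewingResult:
    samples: np.ndarray      # (t, x, y, in_saccade)
    fixations: list          # (onset, duration, x, y)
    heatmap: np.ndarray


def run_free_viewing(salience: SalienceInput, duration_ms: float,
                     params: ModelParams | None = None,
                     seed: int = 0) -> FreeViewingResult:
    """Let the model wander a salience landscape for ``duration_ms``."""
    params = params or ModelParams()
    params.target_mode = "probabilistic"
    rng = np.random.default_rng(seed)
    structure = CategoryStructure(
        name="freeview", stimuli=((0,),), labels=("A",), categories=("A", "B"),
        training=(0,), transfer=(), irrelevant={}, diagnosticity=(1.0,))
    layout = StimulusLayout(
        feature_locations=((10.0, 10.0), (50.0, 50.0)),
        button_location=(30.0, 30.0), rows=params.grid, cols=params.grid)
    model = Lag1Model(structure, layout, params, rng)
    model.reset_trial()
    g = params.grid
    sal = salience.grid
    if sal.shape != (g, g):
        raise ValueError("salience grid must match the field extent")

    t = 0.0
    samples = []
    fix_start, fix_pos = 0.0, model.gaze.position.copy()
    fixations = []
    empty_stim: dict = {}
    while t < duration_ms:
        # no stimulus layers, no detector input: bottom-up only
        pos_before = model.gaze.position.copy()
        model.step(empty_stim, "response", 0, None, t, learn=False,
                   salience=_retinotopic_salience(sal, model.gaze),
                   select_mode="probabilistic")
        model._invalidate()   # salience is rendered retinotopically per step
        t += params.dt
        samples.append((t, model.gaze.position[0], model.gaze.position[1],
                        model.gaze.in_saccade))
        if not np.array_equal(model.gaze.position, pos_before):
            fixations.append((fix_start, t - fix_start, *fix_pos))
            fix_start, fix_pos = t, model.gaze.position.copy()
    fixations.append((fix_start, t - fix_start, *fix_pos))

    heat = np.zeros((g, g))
    for _, dur, x, y in fixations:
        heat[int(y), int(x)] += dur
    return FreeViewingResult(np.array(samples), fixations, heat)


def _retinotopic_salience(sal: np.ndarray, gaze) -> np.ndarray:
    """Shift the spatiotopic salience grid into the current retinal frame."""
    rows, cols = sal.shape
    centre = np.array([(cols - 1) / 2.0, (rows - 1) / 2.0])
    dx, dy = (centre - gaze.position).astype(int)
    out = np.zeros_like(sal)
    src_y = slice(max(0, -dy), min(rows, rows - dy))
    src_x = slice(max(0, -dx), min(cols, cols - dx))
    dst_y = slice(max(0, dy), max(0, dy) + (src_y.stop - src_y.start))
    dst_x = slice(max(0, dx), max(0, dx) + (src_x.stop - src_x.start))
    out[dst_y, dst_x] = sal[src_y, src_x]
    return out


@dataclass
class SearchResult:
    scan_path: list
    found: bool
    time_to_target_ms: float
    fixations_to_target: int


def run_visual_search(array: SearchArray, params: ModelParams | None = None,
                      seed: int = 0, guided: bool = True,
                      max_ms: float = 20_000.0,
                      confirm_threshold: float = 0.4) -> SearchResult:
    """Serial fixate-and-classify search for the target value.

    Unlike category learning, classification here must track the currently
    fixated item, so the detector and category banks run in a transient
    (non-self-sustaining) regime; the trial ends when the target category
    crosses threshold while the target is foveated, or when trial impatience
    forces a quit (the target-absent route).
    """
    params = params or ModelParams()
    params.fd_bank.self_exc = 2.0   # no working memory: track current item
    params.cat_bank.self_exc = 2.0
    params.cat_bank.glob_inh = 0.5  # a fixated distractor must not lock out
    rng = np.random.default_rng(seed)
    structure = CategoryStructure(
        name="search", stimuli=((0,),), labels=("target",),
        categories=("target", "distractor"), training=(0,), transfer=(),
        irrelevant={}, diagnosticity=(1.0,))
    # one "location slot" per item so each item gets its own value layers
    layout = StimulusLayout(
        feature_locations=array.locations,
        button_location=(1.0, 1.0), rows=params.grid, cols=params.grid)
    model = Lag1Model(structure, layout, params, rng)
    # hard-coded information-gain matrix: the target category is coupled to
    # the target value at every item slot, the distractor category to the
    # other value
    W = model.W.W
    W[...] = 0.05
    for slot in range(len(array.locations)):
        W[0, 2 * slot + array.target_value] = 0.95
        W[1, 2 * slot + (1 - array.target_value)] = 0.95
    model.reset_trial()
    model.location_reentry = False  # item locations are unknown to the model

    stimulus = {i: v for i, v in enumerate(array.values)}

    def clamp_expectations() -> None:
        """Expectations are hard-coded here, not learned: target-value
        layers held active (guided) or the whole bank held at rest."""
        model.exp.u[:] = model.exp.params.h
        if guided:
            model.exp.u[array.target_value::2] = 1.0

    clamp_expectations()

    from .learning_system import ClickState, step_click_decision
    quit_click = ClickState(params.click)

    t = 0.0
    scan = [tuple(model.gaze.position)]
    fix_count = 0
    found = False
    while t < max_ms:
        pos_before = model.gaze.position.copy()
        model.step(stimulus, "response", 0, None, t, learn=False)
        clamp_expectations()
        t += params.dt
        if not np.array_equal(model.gaze.position, pos_before):
            fix_count += 1
            scan.append(tuple(model.gaze.position))
        # target confirmed: target category above threshold while foveating it
        if array.target_index is not None:
            tgt = np.asarray(array.locations[array.target_index])
            on_target = np.hypot(*(model.gaze.position - tgt)) <= 1.5 * params.fovea_sigma
            if on_target and model.cat.output()[0] >= confirm_threshold:
                found = True
                break
        # only target-category evidence presses the button: a fixated
        # distractor match must not end the trial, impatience alone does
        # (the target-absent route)
        quit_cats = np.array([model.cat.output()[0], 0.0])
        if step_click_decision(quit_click, quit_cats, False, params.dt) == "RESPOND":
            break
    return SearchResult(scan, found, t, fix_count)
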