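"""Stimulus rendering, coordinate frames, and the three visuospatial fields.

The Visual Field is retinotopic (the fovea sits at the grid centre); the
Spatial Attention and Saccade Motor Fields are spatiotopic (screen
coordinates).  A saccade therefore translates Visual Field activation but
leaves spatiotopic feature coordinates untouched.

Coordinates are (x, y) pairs in grid units with the origin at the top-left
cell; grids are indexed ``[y, x]``.  Gaze positions snap to grid cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield
from functools import lru_cache

import numpy as np

from .dnf_core import NeuralField, step_field

__all__ = [
    "StimulusLayout",
    "GazeState",
    "VisuospatialState",
    "sim1_layout",
    "sim2_layout",
    "to_retinotopic",
    "from_retinotopic",
    "render_input",
    "foveal_readout",
    "remap_on_saccade",
    "step_visuospatial",
]

GRID = 61  # default field extent per side (spatial units)


@dataclass(frozen=True)
class StimulusLayout:
    """Screen geometry of one experiment: feature slots and feedback button.

    ``feature_locations[i]`` is the spatiotopic (x, y) centre of feature slot
    i.  Each slot carries two value layers (value 0 at layer 2i, value 1 at
    layer 2i+1); the feedback button, when shown, occupies one extra layer.
    """

    feature_locations: tuple[tuple[float, float], ...]
    button_location: tuple[float, float]
    rows: int = GRID
    cols: int = GRID

    def __post_init__(self) -> None:
        locs = np.array(self.feature_locations, dtype=float)
        for i in range(len(locs)):
            for j in range(i + 1, len(locs)):
                if np.hypot(*(locs[i] - locs[j])) < 20.0:
                    raise ValueError("feature locations closer than twice the foveal radius")
        if any(np.allclose(self.button_location, l) for l in self.feature_locations):
            raise ValueError("button location must be distinct from feature locations")

    @property
    def n_locations(self) -> int:
        return len(self.feature_locations)

    @property
    def n_value_layers(self) -> int:
        return 2 * self.n_locations

    def min_feature_distance(self) -> float:
        locs = np.array(self.feature_locations, dtype=float)
        d = [np.hypot(*(locs[i] - locs[j]))
             for i in range(len(locs)) for j in range(i + 1, len(locs))]
        return float(min(d))


def sim1_layout() -> StimulusLayout:
    """Three feature slots on an equilateral triangle, button below."""
    cx, cy, r = 30.0, 26.0, 19.0
    ang = np.deg2rad([90.0, 210.0, 330.0])
    locs = tuple((round(cx + r * np.cos(a)), round(cy - r * np.sin(a))) for a in ang)
    return StimulusLayout(feature_locations=locs, button_location=(30.0, 56.0))


def sim2_layout() -> StimulusLayout:
    """Four feature slots on a square, 24 units apart, button below."""
    locs = ((18.0, 14.0), (42.0, 14.0), (18.0, 38.0), (42.0, 38.0))
    return StimulusLayout(feature_locations=locs, button_location=(30.0, 57.0))


@dataclass
class GazeState:
    """Current spatiotopic gaze position and fixation clock."""

    position: np.ndarray = dfield(default_factory=lambda: np.array([30.0, 30.0]))
    fixation_onset: float = 0.0
    in_saccade: bool = False

    def snap(self, rows: int, cols: int) -> None:
        self.position = np.clip(np.round(self.position),
                                [0, 0], [cols - 1, rows - 1]).astype(float)


def to_retinotopic(location, gaze: GazeState, rows: int = GRID,
                   cols: int = GRID) -> np.ndarray:
    """retinotopic = spatiotopic - gaze + field centre (clipping flagged by caller)."""
    centre = np.array([(cols - 1) / 2.0, (rows - 1) / 2.0])
    return np.asarray(location, dtype=float) - gaze.position + centre


def from_retinotopic(location, gaze: GazeState, rows: int = GRID,
                     cols: int = GRID) -> np.ndarray:
    centre = np.array([(cols - 1) / 2.0, (rows - 1) / 2.0])
    return np.asarray(location, dtype=float) + gaze.position - centre


def _blob(rows: int, cols: int, centre_xy, sigma: float, amp: float = 1.0) -> np.ndarray:
    x = np.arange(cols, dtype=float) - centre_xy[0]
    y = np.arange(rows, dtype=float) - centre_xy[1]
    gx = np.exp(-(x**2) / (2.0 * sigma**2))
    gy = np.exp(-(y**2) / (2.0 * sigma**2))
    return amp * np.outer(gy, gx)


@lru_cache(maxsize=256)
def _blob_cached(rows: int, cols: int, cx: float, cy: float,
                 sigma: float) -> np.ndarray:
    b = _blob(rows, cols, (cx, cy), sigma)
    b.setflags(write=False)
    return b


@dataclass
class VisuospatialState:
    """The coupled Visual (retinotopic), Attention and Motor (spatiotopic) fields."""

    visual: NeuralField
    attention: NeuralField
    motor: NeuralField
    fovea_sigma: float = 5.0

    def __post_init__(self) -> None:
        shapes = {f.u.shape for f in (self.visual, self.attention, self.motor)}
        if len(shapes) != 1:
            raise ValueError("all three fields must share one grid extent")

    def reset(self) -> None:
        for f in (self.visual, self.attention, self.motor):
            f.reset()


def acuity_factor(eccentricity, fovea_sigma: float, k: float = 3.0,
                  floor: float = 0.35):
    """Gaussian acuity falloff with a peripheral floor.

    The floor models coarse peripheral localisation: a feature far from the
    fovea is still visible as "something there" even though its value cannot
    be read out (value readout uses the much narrower foveal mask).  Strictly
    decreasing in eccentricity; equals 1 at the fovea.
    """
    e = np.asarray(eccentricity, dtype=float)
    g = np.exp(-(e**2) / (2.0 * (k * fovea_sigma) ** 2))
    out = floor + (1.0 - floor) * g
    return out if out.ndim else float(out)


def render_input(stimulus, layout: StimulusLayout, gaze: GazeState,
                 phase: str, *, fovea_sigma: float = 5.0,
                 stim_sigma: float = 2.5, stim_amp: float = 6.0,
                 button_amp: float = 8.0, acuity_k: float = 3.0,
                 acuity_floor: float = 0.35) -> np.ndarray:
    """Layered retinotopic input stack for the current stimulus and gaze.

    ``stimulus`` maps feature-slot index -> value (0/1); missing slots are
    blank.  Returns an array of shape (2L + 1, rows, cols); the last layer is
    the feedback button, active only during the feedback phase.
    """
    rows, cols = layout.rows, layout.cols
    stack = np.zeros((layout.n_value_layers + 1, rows, cols))
    for loc_idx, value in stimulus.items():
        if value not in (0, 1):
            raise ValueError(f"unknown feature value {value!r} at slot {loc_idx}")
        ret = to_retinotopic(layout.feature_locations[loc_idx], gaze, rows, cols)
        ecc = float(np.hypot(*(np.asarray(layout.feature_locations[loc_idx]) - gaze.position)))
        a = stim_amp * acuity_factor(ecc, fovea_sigma, acuity_k, acuity_floor)
        stack[2 * loc_idx + value] = _blob(rows, cols, ret, stim_sigma, a)
    if phase == "feedback":
        ret = to_retinotopic(layout.button_location, gaze, rows, cols)
        ecc = float(np.hypot(*(np.asarray(layout.button_location) - gaze.position)))
        a = button_amp * acuity_factor(ecc, fovea_sigma, acuity_k, acuity_floor)
        stack[-1] = _blob(rows, cols, ret, stim_sigma, a)
    return stack


def _fovea_mask(rows: int, cols: int, fovea_sigma: float) -> np.ndarray:
    centre = ((cols - 1) / 2.0, (rows - 1) / 2.0)
    return _blob(rows, cols, centre, fovea_sigma)


def foveal_readout(stack: np.ndarray, fovea_sigma: float = 5.0,
                   stim_sigma: float = 2.5) -> np.ndarray:
    """Per-layer foveally weighted sums, normalised so a unit-acuity feature
    exactly at the fovea reads ~1.  Layers at unfixated locations read ~0."""
    nlayers, rows, cols = stack.shape
    mask = _fovea_mask(rows, cols, fovea_sigma)
    centre = ((cols - 1) / 2.0, (rows - 1) / 2.0)
    # normalisation: a stim_amp-free blob of width stim_sigma dead on the fovea
    norm = float((_blob(rows, cols, centre, stim_sigma) * mask).sum())
    return stack.reshape(nlayers, -1) @ mask.ravel() / norm


def remap_on_saccade(visual: NeuralField, saccade_vector) -> NeuralField:
    """Translate Visual Field activation by -saccade_vector (dx, dy).

    Cells shifted in from outside the field start at the resting level.
    Mutates and returns ``visual``.
    """
    dx, dy = int(round(saccade_vector[0])), int(round(saccade_vector[1]))
    u = visual.u
    h = visual.spec.h
    shifted = np.full_like(u, h)
    rows, cols = u.shape
    src_y = slice(max(0, dy), min(rows, rows + dy))
    src_x = slice(max(0, dx), min(cols, cols + dx))
    dst_y = slice(max(0, -dy), max(0, -dy) + (src_y.stop - src_y.start))
    dst_x = slice(max(0, -dx), max(0, -dx) + (src_x.stop - src_x.start))
    shifted[dst_y, dst_x] = u[src_y, src_x]
    visual.u = shifted
    return visual


def _shift_to_spatiotopic(grid: np.ndarray, gaze: GazeState, fill: float = 0.0) -> np.ndarray:
    """Translate a retinotopic grid into spatiotopic coordinates."""
    rows, cols = grid.shape
    centre = np.array([(cols - 1) / 2.0, (rows - 1) / 2.0])
    dx, dy = (gaze.position - centre).astype(int)
    out = np.full_like(grid, fill)
    src_y = slice(max(0, -dy), min(rows, rows - dy))
    src_x = slice(max(0, -dx), min(cols, cols - dx))
    dst_y = slice(max(0, dy), max(0, dy) + (src_y.stop - src_y.start))
    dst_x = slice(max(0, dx), max(0, dx) + (src_x.stop - src_x.start))
    out[dst_y, dst_x] = grid[src_y, src_x]
    return out


def step_visuospatial(state: VisuospatialState, stack: np.ndarray,
                      visual_gains: np.ndarray, location_boosts: np.ndarray,
                      fixation_boost: float, gaze: GazeState, dt: float,
                      rng: np.random.Generator | None, *,
                      c_va: float = 5.0, c_am: float = 5.0,
                      c_fix: float = 2.0, fix_inh_amp: float = 8.0,
                      fix_inh_sigma: float = 6.0,
                      salience: np.ndarray | None = None) -> VisuospatialState:
    """Advance the three coupled fields by one Euler step.

    visual_gains: per-value-layer reentrant weighting (feature-based
    attention); location_boosts: spatiotopic grid of expectation-driven
    boosts; fixation_boost: Fixation-Neuron drive to the attended (foveated)
    location.
    """
    rows, cols = state.visual.u.shape
    nval = stack.shape[0] - 1
    gains = np.ones(stack.shape[0])
    gains[:nval] += visual_gains
    vis_in = np.tensordot(gains, stack, axes=(0, 0))
    if salience is not None:
        vis_in = vis_in + salience
    step_field(state.visual, vis_in, dt, rng)

    f_vis = state.visual.output()
    f_vis_spat = _shift_to_spatiotopic(f_vis, gaze)
    gx, gy = float(gaze.position[0]), float(gaze.position[1])
    att_in = c_va * f_vis_spat + location_boosts
    if fixation_boost != 0.0:
        att_in = att_in + c_fix * fixation_boost * _blob_cached(
            rows, cols, gx, gy, state.fovea_sigma)
    step_field(state.attention, att_in, dt, rng)

    mot_in = c_am * state.attention.output() - fix_inh_amp * _blob_cached(
        rows, cols, gx, gy, fix_inh_sigma)
    step_field(state.motor, mot_in, dt, rng)
    return state
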