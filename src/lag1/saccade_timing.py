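"""The three-neuron saccade timing circuit and saccade execution.

Gaze Change Neuron (u_g): driven by a geometric urgency accumulator whose
growth rate is the Fixation Impatience free parameter; compels exploration.
Fixation Neuron (u_x): driven by foveal featural input; suppresses saccades.
Saccade Initiation Neuron (u_s): excited by f(u_g) and by the Saccade Motor
Field peak (learned spatial priority), inhibited by f(u_x).  A saccade fires
when u_s crosses threshold.

The impatience accumulator compounds continuously, g *= lambda**(dt/tick),
with lambda defined per 100 ms impatience tick; this keeps the printed
1.5-1.9 growth factors in the 300-500 ms fixation regime and leaves saccade
initiation sensitive to learned motor priority.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np

from .dnf_core import NeuralField, NodeParams, NodeState, sigmoid, step_node
from .visuospatial import GazeState, VisuospatialState, remap_on_saccade

__all__ = ["TimingParams", "TimingState", "step_timing", "select_target",
           "execute_saccade"]


@dataclass
class TimingParams:
    lambda_P2: float = 1.7          # Fixation Impatience (free parameter)
    imp_tick_ms: float = 100.0      # impatience compounding interval
    imp_init: float = 0.58          # accumulator reset value
    a_g: float = 12.0               # f(u_g) -> u_s excitation
    b_x: float = 6.0                # f(u_x) -> u_s inhibition
    c_m: float = 7.0                # motor-peak -> u_s excitation
    c_x: float = 8.0                # foveal drive -> u_x
    saccade_threshold: float = 0.0  # u_s threshold
    saccade_duration_ms: float = 30.0
    node_g: NodeParams = dfield(default_factory=lambda: NodeParams(tau=40.0))
    node_x: NodeParams = dfield(default_factory=lambda: NodeParams(tau=40.0))
    node_s: NodeParams = dfield(default_factory=lambda: NodeParams(tau=20.0))


@dataclass
class TimingState:
    params: TimingParams = dfield(default_factory=TimingParams)
    u_g: NodeState = None  # type: ignore[assignment]
    u_x: NodeState = None  # type: ignore[assignment]
    u_s: NodeState = None  # type: ignore[assignment]
    g_accum: float = None  # type: ignore[assignment]
    elapsed: float = 0.0   # ms since fixation onset

    def __post_init__(self) -> None:
        p = self.params
        if self.u_g is None:
            self.u_g = NodeState(p.node_g)
        if self.u_x is None:
            self.u_x = NodeState(p.node_x)
        if self.u_s is None:
            self.u_s = NodeState(p.node_s)
        if self.g_accum is None:
            self.g_accum = p.imp_init

    def reset_fixation(self) -> None:
        """Full post-saccade reset of the urge to move."""
        self.u_g.reset()
        self.u_s.reset()
        self.g_accum = self.params.imp_init
        self.elapsed = 0.0

    def saccade_pending(self) -> bool:
        return self.u_s.u >= self.params.saccade_threshold


def step_timing(state: TimingState, foveal_drive: float, motor_peak: float,
                dt: float, rng: np.random.Generator | None = None) -> TimingState:
    """Advance the timing trio by one Euler step."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    p = state.params
    state.g_accum *= p.lambda_P2 ** (dt / p.imp_tick_ms)
    step_node(state.u_g, state.g_accum, dt, rng)
    step_node(state.u_x, p.c_x * foveal_drive, dt, rng)
    drive_s = (p.a_g * state.u_g.output()
               - p.b_x * state.u_x.output()
               + p.c_m * motor_peak)
    step_node(state.u_s, drive_s, dt, rng)
    state.elapsed += dt
    return state


def select_target(motor: NeuralField, mode: str = "greedy",
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Choose the next saccade target from the Saccade Motor Field.

    greedy: argmax cell (ties broken by lowest row-major index).
    probabilistic: sampled with probability proportional to the sigmoided
    activation (used for free viewing).
    Returns spatiotopic (x, y).
    """
    u = motor.u
    if not np.any(np.isfinite(u)):
        raise ValueError("motor field has no finite cells")
    if mode == "greedy":
        idx = int(np.argmax(u))
    elif mode == "probabilistic":
        if rng is None:
            raise ValueError("probabilistic selection requires an rng")
        p = motor.output().ravel()
        p = p / p.sum()
        idx = int(rng.choice(p.size, p=p))
    else:
        raise ValueError(f"unknown selection mode {mode!r}")
    row, col = divmod(idx, u.shape[1])
    return np.array([float(col), float(row)])


def execute_saccade(gaze: GazeState, target, timing: TimingState,
                    vs: VisuospatialState, t: float) -> float:
    """Move gaze to ``target``: remap the Visual Field, reset the timing
    circuit and fixation clock.  Returns the time at which the saccade ends
    (samples in [t, end) are flagged in-saccade)."""
    rows, cols = vs.visual.u.shape
    target = np.clip(np.asarray(target, dtype=float),
                     [0.0, 0.0], [cols - 1.0, rows - 1.0])
    vector = target - gaze.position
    remap_on_saccade(vs.visual, vector)
    gaze.position = np.round(target)
    end = t + timing.params.saccade_duration_ms
    gaze.fixation_onset = end
    gaze.in_saccade = True
    timing.reset_fixation()
    return end
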