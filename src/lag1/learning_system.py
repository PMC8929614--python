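"""Feature detection, category, and expectation neurons; associative learning.

The associative matrix W (K categories x 2L feature-value detectors, entries
in [0, 1]) is shared between the forward detector->category path and the
backward category->expectation path.  Propagation along both paths is
modulated by a diagnosticity gain derived from the within-location weight
contrast: d(i, loc) = |W(i, loc_a) - W(i, loc_b)|, gain = 1 + kappa * d.
A location whose two value-detectors connect equally to a category carries no
information about it; a large contrast marks the location as diagnostic.

Learning runs each timestep of the feedback phase: Hebbian strengthening of
active detectors onto the (feedback-activated) correct category with a
soft bound (1 - W), homeostatic decay of all weights by the mean Hebbian
increment, and anti-Hebbian weakening (soft bound W) of the chosen category's
connections after an incorrect guess.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np

from .dnf_core import sigmoid

__all__ = [
    "BankParams", "FeatureBank", "CategoryBank", "ExpectationBank",
    "AssociativeWeights", "ClickParams", "ClickState",
    "step_feature_detectors", "compute_gain", "step_category_neurons",
    "step_feature_expectation", "apply_feedback_learning",
    "step_click_decision", "choose_category",
]


@dataclass
class BankParams:
    tau: float = 50.0
    h: float = -5.0
    beta: float = 1.0
    theta: float = 0.0
    noise_amp: float = 0.0
    self_exc: float = 6.0
    pair_inh: float = 3.0    # within-location value competition (FeatureBank)
    glob_inh: float = 0.0


class _Bank:
    """Vector of discrete neurons sharing one parameter set."""

    def __init__(self, n: int, params: BankParams):
        self.n = n
        self.params = params
        self.u = np.full(n, params.h, dtype=float)

    def output(self) -> np.ndarray:
        return sigmoid(self.u, self.params.beta, self.params.theta)

    def reset(self) -> None:
        self.u.fill(self.params.h)

    def _step(self, external_input: np.ndarray, dt: float,
              rng: np.random.Generator | None) -> None:
        p = self.params
        self.u += (-self.u + p.h + external_input) * (dt / p.tau)
        if p.noise_amp > 0.0 and rng is not None:
            self.u += p.noise_amp * np.sqrt(dt) * rng.standard_normal(self.n)
        if not np.isfinite(self.u.sum()):
            raise FloatingPointError("non-finite bank activation")


class FeatureBank(_Bank):
    """2L feature-value detectors, paired per location; acts as a visual
    working memory (suprathreshold activation self-sustains)."""

    def __init__(self, n_locations: int,
                 params: BankParams | None = None):
        params = params or BankParams(self_exc=8.0, pair_inh=12.0, glob_inh=0.2)
        super().__init__(2 * n_locations, params)
        self.n_locations = n_locations
        # pair index of each neuron: [1, 0, 3, 2, ...]
        self._pair = np.arange(self.n) ^ 1


class CategoryBank(_Bank):
    """K category neurons; winner-take-all via global inhibition, capable of
    self-sustained activation once sufficiently excited."""

    def __init__(self, n_categories: int, params: BankParams | None = None):
        params = params or BankParams(self_exc=5.5, glob_inh=1.5)
        super().__init__(n_categories, params)
        self.feedback_boost = 6.0


class ExpectationBank(_Bank):
    """2L feature-expectation neurons mirroring the detectors."""

    def __init__(self, n_locations: int, params: BankParams | None = None):
        params = params or BankParams(self_exc=0.0, glob_inh=0.0)
        super().__init__(2 * n_locations, params)
        self.n_locations = n_locations


class AssociativeWeights:
    """Bounded matrix W(i, j) of category-feature association strengths."""

    def __init__(self, n_categories: int, n_locations: int,
                 rng: np.random.Generator | None = None,
                 init: float = 0.5, jitter: float = 0.05):
        shape = (n_categories, 2 * n_locations)
        self.W = np.full(shape, init, dtype=float)
        if rng is not None and jitter > 0:
            self.W += rng.uniform(-jitter, jitter, size=shape)
        np.clip(self.W, 0.0, 1.0, out=self.W)
        self.n_categories = n_categories
        self.n_locations = n_locations


def step_feature_detectors(bank: FeatureBank, foveal_drives: np.ndarray,
                           dt: float, rng: np.random.Generator | None = None,
                           c_in: float = 8.0) -> FeatureBank:
    """Integrate drives with self-excitation, pair and global inhibition."""
    if len(foveal_drives) != bank.n:
        raise ValueError("drive vector length must be 2L")
    p = bank.params
    out = bank.output()
    inp = (c_in * np.asarray(foveal_drives, dtype=float)
           + p.self_exc * out
           - p.pair_inh * out[bank._pair]
           - p.glob_inh * (out.sum() - out))
    bank._step(inp, dt, rng)
    return bank


def compute_gain(weights: AssociativeWeights, kappa: float = 1.0) -> np.ndarray:
    """Diagnosticity gain per (category, location): 1 + kappa * |W_a - W_b|."""
    W = weights.W
    d = np.abs(W[:, 0::2] - W[:, 1::2])
    return 1.0 + kappa * d


def _gained_weights(weights: AssociativeWeights, kappa: float) -> np.ndarray:
    """W elementwise-scaled by the gain of its (category, location) pair."""
    gain = compute_gain(weights, kappa)
    return weights.W * np.repeat(gain, 2, axis=1)


def step_category_neurons(bank: CategoryBank, fd_outputs: np.ndarray,
                          weights: AssociativeWeights, kappa: float,
                          dt: float, rng: np.random.Generator | None = None,
                          feedback_boost_idx: int | None = None,
                          boost_drive: float = 0.0,
                          c_w: float = 2.4) -> CategoryBank:
    """input_i = c_w * sum_j gain(i, loc j) W(i,j) fd*_j + self-exc - glob-inh
    (+ feedback boost to the correct category while the button is foveated)."""
    p = bank.params
    out = bank.output()
    inp = (c_w * (_gained_weights(weights, kappa) @ fd_outputs)
           + p.self_exc * out
           - p.glob_inh * (out.sum() - out))
    if feedback_boost_idx is not None and boost_drive > 0.0:
        inp[feedback_boost_idx] += bank.feedback_boost * boost_drive
    bank._step(inp, dt, rng)
    return bank


def step_feature_expectation(bank: ExpectationBank, category_outputs: np.ndarray,
                             weights: AssociativeWeights, kappa: float,
                             fd_outputs: np.ndarray, dt: float,
                             rng: np.random.Generator | None = None,
                             c_bw: float = 6.0, c_fd: float = 3.0) -> ExpectationBank:
    """Backward pass through the shared weights, inhibited by already-active
    detectors so that unseen diagnostic features win the expectation race."""
    inp = (c_bw * (_gained_weights(weights, kappa).T @ category_outputs)
           - c_fd * np.asarray(fd_outputs, dtype=float))
    bank._step(inp, dt, rng)
    return bank


def apply_feedback_learning(weights: AssociativeWeights, fd_outputs: np.ndarray,
                            correct: int, chosen: int, rate: float, dt: float,
                            correct_active: bool = True) -> AssociativeWeights:
    """One feedback-phase learning step (Hebbian / homeostatic / anti-Hebbian).

    ``correct_active`` gates the Hebbian term on the correct Category Neuron
    being above threshold (normally via the feedback-button boost); credit
    accrues in proportion to co-activation time, so an 800 ms fixation earns
    4x the pre-bound increment of a 200 ms one.
    """
    if rate < 0:
        raise ValueError("learning rate must be >= 0")
    W = weights.W
    fd = np.asarray(fd_outputs, dtype=float)
    if correct_active:
        hebb = rate * dt * fd * (1.0 - W[correct])
        W[correct] += hebb
        # homeostatic decay: all weights shed the matrix-mean Hebbian
        # increment
        W -= hebb.sum() / W.size
    if chosen != correct:
        W[chosen] -= rate * dt * fd * W[chosen]
    np.clip(W, 0.0, 1.0, out=W)
    return weights


@dataclass
class ClickParams:
    theta1: float = 0.0          # response (phase-change) threshold on u
    theta2: float = 5.5          # trial-end threshold on u
    trial_impatience: float = 1.8   # free parameter
    imp_tick_ms: float = 400.0
    imp_init: float = 0.015
    c_cat: float = 8.5           # max category output -> click drive
    c_feedback: float = 2.0      # feedback-on-screen signal
    tau: float = 100.0
    h: float = -5.0
    noise_amp: float = 0.0


@dataclass
class ClickState:
    """Two-threshold decision neuron driving phase transitions."""

    params: ClickParams = dfield(default_factory=ClickParams)
    u: float = None        # type: ignore[assignment]
    g_accum: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        p = self.params
        if p.theta1 >= p.theta2:
            raise ValueError("theta1 must be < theta2")
        if self.u is None:
            self.u = p.h
        if self.g_accum is None:
            self.g_accum = p.imp_init

    def reset(self) -> None:
        self.u = self.params.h
        self.g_accum = self.params.imp_init


def step_click_decision(state: ClickState, category_outputs: np.ndarray,
                        feedback_present: bool, dt: float,
                        rng: np.random.Generator | None = None) -> str | None:
    """Advance the Click Decision Neuron; returns "RESPOND" on the first
    threshold crossing, "END_TRIAL" on the second, else None.

    The impatience accumulator restarts at the response so that the feedback
    phase is itself finite; near-saturated category knowledge plus the
    feedback signal can bridge theta1 -> theta2 almost immediately (a
    feedback-skipping double-click).
    """
    p = state.params
    state.g_accum *= p.trial_impatience ** (dt / p.imp_tick_ms)
    drive = p.c_cat * float(np.max(category_outputs)) + state.g_accum
    if feedback_present:
        drive += p.c_feedback
    state.u += (-state.u + p.h + drive) * (dt / p.tau)
    if p.noise_amp > 0.0 and rng is not None:
        state.u += p.noise_amp * np.sqrt(dt) * rng.standard_normal()
    if not np.isfinite(state.u):
        raise FloatingPointError("non-finite click activation")
    if not feedback_present and state.u >= p.theta1:
        state.g_accum = p.imp_init
        return "RESPOND"
    if feedback_present and state.u >= p.theta2:
        return "END_TRIAL"
    return None


def choose_category(category_outputs: np.ndarray,
                    rng: np.random.Generator) -> int:
    """Luce choice: sample with probability proportional to sigmoided output."""
    out = np.asarray(category_outputs, dtype=float)
    if not np.any(np.isfinite(out)):
        raise ValueError("no finite category output")
    p = out / out.sum()
    return int(rng.choice(out.size, p=p))
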