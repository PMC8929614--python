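"""Model parameter containers and named defaults.

Everything here is a fixed scaling constant calibrated once so that the
no-knowledge model moves its eye roughly three times per second, starts a
category-learning trial around the empirical 3-4 s reaction-time band, and
learns within a few hundred feedback phases.  The only subject-level free
parameters are ``learning_rate``, ``fixation_impatience`` and
``trial_impatience``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .dnf_core import FieldSpec
from .learning_system import BankParams, ClickParams
from .saccade_timing import TimingParams

GRID = 61

# Fig-3-style free-parameter levels (low, median, high) used throughout the
# calibration checks and as default search bounds for fitting.
LEARNING_RATE_LEVELS = (2.5e-6, 1.1e-5, 1.65e-5)
FIXATION_IMPATIENCE_LEVELS = (1.5, 1.7, 1.9)
TRIAL_IMPATIENCE_LEVELS = (1.6, 1.8, 2.05)


@dataclass
class ModelParams:
    """All wiring constants of the model plus the three free parameters."""

    # integration
    dt: float = 10.0                # ms; records every step (~120 Hz tracker)
    grid: int = GRID

    # free parameters (per simulated subject)
    learning_rate: float = 1.1e-5   # weight change per ms of co-activation
    fixation_impatience: float = 1.7
    trial_impatience: float = 1.8

    # stimulus rendering / optics
    fovea_sigma: float = 5.0
    stim_sigma: float = 2.5
    stim_amp: float = 7.0
    button_amp: float = 8.0
    acuity_k: float = 3.0
    acuity_floor: float = 0.5

    # field wiring
    c_va: float = 8.0       # visual -> attention
    c_am: float = 8.0       # attention -> motor
    c_fix: float = 1.0      # fixation neuron -> foveal attention boost
    fix_inh_amp: float = 14.0
    fix_inh_sigma: float = 7.0
    c_rv: float = 1.5       # expectation -> visual layer reentry gain
    c_eb: float = 10.0      # expectation -> attention location boost

    # learning-system wiring
    c_in: float = 8.0       # foveal drive -> feature detectors
    c_w: float = 2.4        # detectors -> categories (through W)
    c_bw: float = 6.0       # categories -> expectations (through W)
    c_fd: float = 3.0       # detector -> expectation inhibition
    kappa: float = 1.2      # diagnosticity gain coefficient
    learning_scale: float = 4.0   # internal scaling of the free learning rate
    w_init: float = 0.5
    w_jitter: float = 0.05

    # field specs
    visual: FieldSpec = field(default_factory=lambda: FieldSpec(
        GRID, GRID, tau=30.0, h=-5.0, beta=1.0, theta=-2.0,
        exc_amp=0.0, exc_sigma=3.0, glob_inh=0.0, noise_amp=0.02))
    # NB: a Gaussian kernel of width sigma has mass exc_amp * 2 pi sigma^2;
    # with sigma = 3 an amplitude of 0.06 recruits ~3.4 units of local
    # excitation from a saturated neighbourhood.  This is the sharpening
    # (input-driven) regime: bumps here track their input and dissolve when
    # it goes.  Self-sustaining bumps need a steeper sigmoid and an edge
    # excitation that beats the rest-to-threshold gap (e.g. beta ~ 4,
    # exc_amp ~ 0.6 at sigma 2 against glob_inh ~ 0.02).
    attention: FieldSpec = field(default_factory=lambda: FieldSpec(
        GRID, GRID, tau=30.0, h=-5.0, beta=1.0, theta=0.0,
        exc_amp=0.06, exc_sigma=3.0, glob_inh=0.03, noise_amp=0.03))
    motor: FieldSpec = field(default_factory=lambda: FieldSpec(
        GRID, GRID, tau=20.0, h=-5.0, beta=1.0, theta=1.0,
        exc_amp=0.05, exc_sigma=3.0, glob_inh=0.02, noise_amp=0.02))

    # neuron banks
    fd_bank: BankParams = field(default_factory=lambda: BankParams(
        tau=50.0, self_exc=8.0, pair_inh=12.0, glob_inh=0.2))
    cat_bank: BankParams = field(default_factory=lambda: BankParams(
        tau=50.0, self_exc=5.5, glob_inh=1.5))
    exp_bank: BankParams = field(default_factory=lambda: BankParams(
        tau=50.0, self_exc=0.0, glob_inh=0.0))

    timing: TimingParams = field(default_factory=TimingParams)
    click: ClickParams = field(default_factory=ClickParams)

    max_trial_ms: float = 30_000.0  # runaway-trial guard
    target_mode: str = "greedy"     # saccade target selection

    def __post_init__(self) -> None:
        self.timing.lambda_P2 = self.fixation_impatience
        self.click.trial_impatience = self.trial_impatience


def _to_dict(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_dict(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    return obj


def dump_params(params: ModelParams, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_dict(params), fh, sort_keys=False)


def load_params(path) -> ModelParams:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    for key, cls in (("visual", FieldSpec), ("attention", FieldSpec),
                     ("motor", FieldSpec), ("fd_bank", BankParams),
                     ("cat_bank", BankParams), ("exp_bank", BankParams),
                     ("timing", TimingParams), ("click", ClickParams)):
        if key in raw and isinstance(raw[key], dict):
            sub = raw[key]
            if cls is TimingParams:
                from .dnf_core import NodeParams
                for nk in ("node_g", "node_x", "node_s"):
                    if nk in sub and isinstance(sub[nk], dict):
                        sub[nk] = NodeParams(**sub[nk])
            raw[key] = cls(**sub)
    return ModelParams(**raw)
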