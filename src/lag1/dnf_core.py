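"""Generic dynamic-neural-field machinery.

Fields follow the standard Amari form

    tau * du/dt = -u + h + s(x, t) + [k * f(u)](x) - w_inh * sum(f(u)) + noise

where ``f`` is a logistic sigmoid, ``k`` a Gaussian excitatory kernel and the
global-inhibition term is uniform over the field.  Integration is explicit
Euler with Euler--Maruyama noise scaling (``noise_amp * sqrt(dt)``), additive
on the activation variable.  Single model neurons use the same dynamics
without the lateral term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "FieldSpec",
    "NeuralField",
    "NodeParams",
    "NodeState",
    "sigmoid",
    "gaussian_kernel",
    "lateral_interaction",
    "step_field",
    "step_node",
]


def sigmoid(u, beta: float, theta: float = 0.0):
    """Logistic output nonlinearity: 0.5 at ``u == theta``, slope ``beta``."""
    if beta <= 0:
        raise ValueError("sigmoid steepness beta must be > 0")
    u = np.asarray(u, dtype=float)
    # a finite array sums to a finite value; inf/nan poison the sum
    if not np.isfinite(u.sum()):
        raise ValueError("non-finite activation passed to sigmoid")
    # scipy.special.expit without the import cost on hot paths
    out = np.empty_like(u)
    np.multiply(u - theta, -beta, out=out)
    np.exp(out, out=out)
    out += 1.0
    np.reciprocal(out, out=out)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class FieldSpec:
    """Fixed structural parameters of a 2-D neural field.

    Distances are in abstract spatial units (grid cells), times in ms.  The
    fixed scaling constants of the model live here and in the wiring gains of
    the higher modules; they are not subject-level free parameters.
    """

    rows: int
    cols: int
    tau: float = 30.0          # time constant (ms)
    h: float = -5.0            # resting level (negative)
    beta: float = 1.0          # sigmoid steepness
    theta: float = 0.0         # sigmoid threshold
    exc_amp: float = 0.0       # excitatory kernel amplitude
    exc_sigma: float = 3.0     # excitatory kernel width (spatial units)
    glob_inh: float = 0.0      # global inhibition strength
    noise_amp: float = 0.0     # noise sd per sqrt(ms)

    def __post_init__(self) -> None:
        if self.rows <= 0 or self.cols <= 0:
            raise ValueError("field extent must be positive")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.exc_sigma <= 0:
            raise ValueError("exc_sigma must be > 0")
        if self.glob_inh < 0 or self.noise_amp < 0:
            raise ValueError("glob_inh and noise_amp must be >= 0")


def gaussian_kernel(spec: FieldSpec, truncate: float = 4.0) -> np.ndarray:
    """Excitatory interaction kernel k(d) = exc_amp * exp(-d^2 / 2 sigma^2).

    Truncated at ``truncate`` sigma; this is the kernel the FFT path and the
    brute-force oracle both use.
    """
    r = int(np.ceil(truncate * spec.exc_sigma))
    ax = np.arange(-r, r + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax)
    return spec.exc_amp * np.exp(-(xx**2 + yy**2) / (2.0 * spec.exc_sigma**2))


class _Convolver:
    """Separable Gaussian convolution with zero-padded boundaries.

    The truncated 2-D kernel is an outer product of two 1-D Gaussians, so
    two ``correlate1d`` passes reproduce the dense convolution exactly."""

    def __init__(self, spec: FieldSpec, truncate: float = 4.0):
        r = int(np.ceil(truncate * spec.exc_sigma))
        ax = np.arange(-r, r + 1, dtype=float)
        g = np.exp(-(ax**2) / (2.0 * spec.exc_sigma**2))
        self.k1d = g
        self.amp = spec.exc_amp

    def __call__(self, grid: np.ndarray) -> np.ndarray:
        tmp = ndimage.correlate1d(grid, self.k1d, axis=0, mode="constant")
        tmp = ndimage.correlate1d(tmp, self.k1d, axis=1, mode="constant",
                                  output=tmp)
        tmp *= self.amp
        return tmp


class NeuralField:
    """A 2-D activation grid with Amari dynamics."""

    __slots__ = ("spec", "u", "t", "_conv", "name")

    def __init__(self, spec: FieldSpec, name: str = "field"):
        self.spec = spec
        self.u = np.full((spec.rows, spec.cols), spec.h, dtype=float)
        self.t = 0.0
        self.name = name
        self._conv = _Convolver(spec) if spec.exc_amp != 0.0 else None

    def output(self) -> np.ndarray:
        return sigmoid(self.u, self.spec.beta, self.spec.theta)

    def reset(self) -> None:
        self.u.fill(self.spec.h)


def lateral_interaction(output_grid: np.ndarray, spec: FieldSpec,
                        _conv: _Convolver | None = None) -> np.ndarray:
    """Local excitation (Gaussian kernel) minus uniform global inhibition.

    ``output_grid`` holds sigmoided activations in [0, 1].  Boundary handling
    is zero-padded: activation does not wrap.
    """
    output_grid = np.asarray(output_grid, dtype=float)
    if output_grid.shape != (spec.rows, spec.cols):
        raise ValueError(
            f"output grid shape {output_grid.shape} does not match spec "
            f"extent {(spec.rows, spec.cols)}"
        )
    if spec.exc_amp != 0.0:
        conv = _conv if _conv is not None else _Convolver(spec)
        exc = conv(output_grid)
    else:
        exc = np.zeros_like(output_grid)
    if spec.glob_inh != 0.0:
        exc -= spec.glob_inh * output_grid.sum()
    return exc


def step_field(field: NeuralField, external_input: np.ndarray, dt: float,
               rng: np.random.Generator | None = None) -> NeuralField:
    """One explicit-Euler step of the field equation (mutates ``field``)."""
    spec = field.spec
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if external_input.shape != field.u.shape:
        raise ValueError("external input shape mismatch")
    out = field.output()
    lat = lateral_interaction(out, spec, field._conv)
    # in-place Euler update: lat becomes du
    lat += external_input
    lat -= field.u
    lat += spec.h
    lat *= dt / spec.tau
    field.u += lat
    if spec.noise_amp > 0.0 and rng is not None:
        field.u += spec.noise_amp * np.sqrt(dt) * rng.standard_normal(field.u.shape)
    if not np.isfinite(field.u.sum()):
        raise FloatingPointError(f"activation overflow in field '{field.name}'")
    field.t += dt
    return field


@dataclass
class NodeParams:
    tau: float = 50.0
    h: float = -5.0
    beta: float = 1.0
    theta: float = 0.0
    noise_amp: float = 0.0


@dataclass
class NodeState:
    """Scalar neuron: same relaxation dynamics as a field, no lateral term."""

    params: NodeParams = field(default_factory=NodeParams)
    u: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.u is None:
            self.u = self.params.h

    def output(self) -> float:
        return float(sigmoid(self.u, self.params.beta, self.params.theta))

    def reset(self) -> None:
        self.u = self.params.h


def step_node(node: NodeState, external_input: float, dt: float,
              rng: np.random.Generator | None = None) -> NodeState:
    """One explicit-Euler step of the node equation (mutates ``node``)."""
    p = node.params
    if dt <= 0:
        raise ValueError("dt must be > 0")
    node.u += (-node.u + p.h + external_input) * (dt / p.tau)
    if p.noise_amp > 0.0 and rng is not None:
        node.u += p.noise_amp * np.sqrt(dt) * rng.standard_normal()
    if not np.isfinite(node.u):
        raise FloatingPointError("non-finite node activation")
    return node
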