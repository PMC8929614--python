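"""Per-subject objective over summary vectors and a cached grid search.

Three free parameters are fit per subject: learning rate, fixation
impatience, trial impatience.  The objective is a weighted sum of squared,
per-component-scaled differences between the model's summary vector and the
subject's target vector; candidate points are evaluated on a grid (optionally
refined locally), each averaged over a small number of seeds, with a cache
keyed by (parameters, structure, seed) so no simulation runs twice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np

from .config import (FIXATION_IMPATIENCE_LEVELS, LEARNING_RATE_LEVELS,
                     TRIAL_IMPATIENCE_LEVELS)

__all__ = ["FitTarget", "ParamPoint", "objective", "fit_subject",
           "DEFAULT_BOUNDS", "SummaryCache"]

DEFAULT_BOUNDS = {
    "learning_rate": (LEARNING_RATE_LEVELS[0], LEARNING_RATE_LEVELS[-1]),
    "fixation_impatience": (FIXATION_IMPATIENCE_LEVELS[0],
                            FIXATION_IMPATIENCE_LEVELS[-1]),
    "trial_impatience": (TRIAL_IMPATIENCE_LEVELS[0],
                         TRIAL_IMPATIENCE_LEVELS[-1]),
}


@dataclass
class FitTarget:
    subject: str
    summary: np.ndarray
    weights: np.ndarray | None = None
    scales: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.summary = np.asarray(self.summary, float)
        if self.weights is None:
            self.weights = np.ones_like(self.summary)
        self.weights = np.asarray(self.weights, float)
        if self.weights.shape != self.summary.shape:
            raise ValueError("weight vector length must match summary length")
        if self.scales is None:
            # equalise component magnitudes so no single measure dominates
            self.scales = np.maximum(np.abs(self.summary), 1e-3)
        self.scales = np.asarray(self.scales, float)


@dataclass
class ParamPoint:
    learning_rate: float
    fixation_impatience: float
    trial_impatience: float
    objective: float = np.inf
    summary: np.ndarray | None = None
    seeds: tuple[int, ...] = ()

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.learning_rate, self.fixation_impatience,
                self.trial_impatience)


def objective(model_summary: np.ndarray, target: FitTarget,
              weights: np.ndarray | None = None) -> float:
    """Weighted, scaled sum of squared differences; zero iff vectors equal."""
    w = np.asarray(weights, float) if weights is not None else target.weights
    m = np.asarray(model_summary, float)
    d = (m - target.summary) / target.scales
    return float(np.sum(w * d * d))


class SummaryCache:
    """On-disk keyed table of simulated summary vectors."""

    def __init__(self, path=None):
        self.path = Path(path) if path else None
        self._table: dict[str, list] = {}
        if self.path and self.path.exists():
            self._table = json.loads(self.path.read_text())

    @staticmethod
    def key(params: tuple, structure: str, seed: int) -> str:
        lr, fi, ti = params
        return f"{structure}|{lr:.6g}|{fi:.4g}|{ti:.4g}|{seed}"

    def get(self, params, structure, seed):
        v = self._table.get(self.key(params, structure, seed))
        return None if v is None else np.asarray(v, float)

    def put(self, params, structure, seed, summary) -> None:
        self._table[self.key(params, structure, seed)] = \
            np.asarray(summary, float).tolist()
        if self.path:
            self.path.write_text(json.dumps(self._table))


def _candidates(bounds: dict, budget: int) -> list[tuple[float, float, float]]:
    """Deterministic space-filling candidate sequence over the bounds.

    A Halton sequence makes budgets nested: a larger budget evaluates a
    strict superset of a smaller one, so the best objective can only
    improve.  The corners and centre of the box are seeded first so tiny
    budgets still bracket the space.
    """
    names = ("learning_rate", "fixation_impatience", "trial_impatience")
    lows = np.array([bounds[n][0] for n in names])
    highs = np.array([bounds[n][1] for n in names])
    if np.any(lows > highs):
        raise ValueError("empty parameter bounds")
    seeds = [np.array([0.5, 0.5, 0.5])]
    seeds += [np.array(c, float) for c in
              [(a, b, d) for a in (0, 1) for b in (0, 1) for d in (0, 1)]]
    from scipy.stats import qmc
    n_extra = max(0, budget - len(seeds))
    extra = qmc.Halton(d=3, scramble=False).random(n_extra) if n_extra else \
        np.empty((0, 3))
    unit = np.vstack([seeds, extra])[:budget]
    pts = lows + unit * (highs - lows)
    return [tuple(map(float, p)) for p in pts]


def fit_subject(target: FitTarget, simulate, bounds: dict | None = None,
                budget: int = 27, n_seeds: int = 1, seeds: tuple[int, ...] = (0,),
                cache: SummaryCache | None = None,
                structure: str = "blair") -> ParamPoint:
    """Grid search over the three free parameters.

    ``simulate(learning_rate, fixation_impatience, trial_impatience, seed)``
    must return a summary vector; it is the caller's bridge to
    ``run_experiment`` + ``summary_vector`` (injected so the search is
    testable against cheap surrogates).  ``budget`` caps the number of grid
    points evaluated.  Deterministic given (target, bounds, budget, seeds).
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    bounds = bounds or DEFAULT_BOUNDS
    cache = cache or SummaryCache()
    seeds = tuple(seeds[:n_seeds]) if len(seeds) >= n_seeds else tuple(seeds)
    points = _candidates(bounds, budget)
    best = None
    for pt in points:
        summaries = []
        for seed in seeds:
            s = cache.get(pt, structure, seed)
            if s is None:
                s = np.asarray(simulate(*pt, seed), float)
                cache.put(pt, structure, seed, s)
            summaries.append(s)
        mean_summary = np.mean(summaries, axis=0)
        val = objective(mean_summary, target)
        if best is None or val < best.objective:
            best = ParamPoint(*pt, objective=val, summary=mean_summary,
                              seeds=seeds)
    return best
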