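"""Fixation detection, AOI assignment, and behavioural measures.

The same pipeline applies to simulated and human-format raw gaze data: a
dispersion-threshold (I-DT) pass aggregates samples into fixations, fixations
are labelled by nearest area of interest (feature slot or feedback button),
and per-trial measures are binned across the experiment or resampled within
trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .experiment_harness import CategoryStructure, Counterbalance, RawDataset
from .visuospatial import StimulusLayout

__all__ = [
    "Fixation", "detect_fixations", "assign_aoi", "trial_measures",
    "bin_measures", "within_trial_probability", "learning_point",
    "transfer_matrix", "summary_vector", "dataset_fixations",
]


@dataclass
class Fixation:
    trial: int
    onset: float
    duration: float
    x: float
    y: float
    phase: str = ""
    aoi: object = None


def _dispersion(xs: np.ndarray, ys: np.ndarray) -> float:
    """Bounding-box dispersion: (max x - min x) + (max y - min y)."""
    return float((xs.max() - xs.min()) + (ys.max() - ys.min()))


def detect_fixations(samples: pd.DataFrame, dispersion_threshold: float = 5.0,
                     min_duration: float = 60.0) -> list[Fixation]:
    """I-DT over time-ordered samples; in-saccade samples break windows.

    Grows a window while its bounding-box dispersion stays within threshold;
    emits a fixation when the window covers at least ``min_duration`` ms.
    """
    fixations: list[Fixation] = []
    if len(samples) == 0:
        return fixations
    trial = int(samples["trial"].iloc[0]) if "trial" in samples else 0
    phase = samples["phase"].iloc[0] if "phase" in samples else ""
    sac = samples["in_saccade"].to_numpy().astype(bool) \
        if "in_saccade" in samples else np.zeros(len(samples), bool)
    t = samples["t_ms"].to_numpy(float)
    x = samples["x"].to_numpy(float)
    y = samples["y"].to_numpy(float)
    ph = samples["phase"].to_numpy() if "phase" in samples else np.array([""] * len(t))

    # contiguous runs of non-saccade samples; phase changes break windows
    # (a fixation belongs to exactly one trial phase)
    keep = ~sac
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        return fixations
    gap = np.diff(idx) > 1
    phase_change = ph[idx[1:]] != ph[idx[:-1]]
    breaks = np.flatnonzero(gap | phase_change)
    run_bounds = np.split(idx, breaks + 1)

    dt = np.median(np.diff(t)) if len(t) > 1 else min_duration

    for run in run_bounds:
        i = 0
        n = run.size
        while i < n:
            j = i + 1
            while j <= n:
                seg = run[i:j]
                if _dispersion(x[seg], y[seg]) > dispersion_threshold:
                    break
                j += 1
            j -= 1  # last admissible end (exclusive index into run is j)
            seg = run[i:j]
            if seg.size:
                dur = t[seg[-1]] - t[seg[0]] + dt
                if dur >= min_duration:
                    fixations.append(Fixation(
                        trial=trial, onset=float(t[seg[0]]), duration=float(dur),
                        x=float(x[seg].mean()), y=float(y[seg].mean()),
                        phase=str(ph[seg[0]])))
                    i = j
                    continue
            i += 1
    return fixations


def assign_aoi(fixations: list[Fixation], layout: StimulusLayout,
               radius: float | None = None) -> list[Fixation]:
    """Label each fixation with the nearest feature slot (by index) or the
    feedback button within ``radius``; ties go to the lowest index."""
    if radius is None:
        radius = layout.min_feature_distance() / 2.0
    targets = [(i, np.asarray(loc, float))
               for i, loc in enumerate(layout.feature_locations)]
    targets.append(("button", np.asarray(layout.button_location, float)))
    for f in fixations:
        pos = np.array([f.x, f.y])
        best, best_d = None, np.inf
        for label, loc in targets:
            d = float(np.hypot(*(pos - loc)))
            if d < best_d - 1e-12:
                best, best_d = label, d
        f.aoi = best if best_d <= radius else None
    return fixations


def dataset_fixations(dataset: RawDataset, layout: StimulusLayout,
                      dispersion_threshold: float = 5.0,
                      min_duration: float = 60.0) -> pd.DataFrame:
    """Fixation table for a whole raw dataset (per trial, AOI-labelled)."""
    rows = []
    for trial, g in dataset.gaze.groupby("trial", sort=True):
        fixes = detect_fixations(g, dispersion_threshold, min_duration)
        assign_aoi(fixes, layout)
        # phase per fixation from the sample at onset
        for f in fixes:
            f.trial = int(trial)
            rows.append((f.trial, f.onset, f.duration, f.x, f.y, f.phase,
                         f.aoi if f.aoi is not None else ""))
    return pd.DataFrame(rows, columns=[
        "trial", "onset_ms", "duration_ms", "x", "y", "phase", "aoi"])


def trial_measures(dataset: RawDataset, fixations: pd.DataFrame,
                   structure: CategoryStructure,
                   cb: Counterbalance | None = None) -> pd.DataFrame:
    """Per-trial behavioural measures.

    The irrelevant-fixated flag uses the stimulus-specific irrelevant
    location (which feature is irrelevant depends on the category of the
    stimulus shown on that trial).
    """
    cb = cb or dataset.counterbalance
    rows = []
    fx_by_trial = dict(tuple(fixations.groupby("trial"))) if len(fixations) else {}
    for rec in dataset.trials.itertuples():
        fx = fx_by_trial.get(rec.trial)
        resp = fx[fx["phase"].isin(["response", "transfer"])] if fx is not None \
            else pd.DataFrame(columns=["duration_ms", "aoi"])
        fb = fx[fx["phase"] == "feedback"] if fx is not None \
            else pd.DataFrame(columns=["duration_ms", "aoi"])
        irrelevant_fixated = np.nan
        irr_feature = structure.irrelevant.get(rec.stimulus_id)
        if irr_feature is not None:
            irr_loc = cb.location_of(irr_feature) if cb is not None else irr_feature
            irrelevant_fixated = int((resp["aoi"] == irr_loc).any())
        feat_aois = set(range(structure.n_features))
        per_feature = {}
        for f in range(structure.n_features):
            loc = cb.location_of(f) if cb is not None else f
            per_feature[f"fix_count_f{f + 1}"] = int((resp["aoi"] == loc).sum())
        rows.append({
            "trial": rec.trial,
            "stimulus_id": rec.stimulus_id,
            "phase_type": rec.phase_type,
            "accuracy": rec.correct,
            "rt_ms": rec.rt_ms,
            "fix_count": int(len(resp)),
            "mean_fix_dur_ms": float(resp["duration_ms"].mean())
            if len(resp) else np.nan,
            "irrelevant_fixated": irrelevant_fixated,
            "feedback_feature_ms": float(
                fb.loc[fb["aoi"].isin(feat_aois), "duration_ms"].sum())
            if len(fb) else 0.0,
            **per_feature,
        })
    return pd.DataFrame(rows)


def bin_measures(measures: pd.DataFrame, bin_size: int = 15,
                 columns: tuple[str, ...] = ("accuracy", "fix_count",
                                             "mean_fix_dur_ms",
                                             "irrelevant_fixated", "rt_ms",
                                             "feedback_feature_ms")) -> pd.DataFrame:
    """Trial-bin means and standard errors (default 15-trial bins)."""
    df = measures[measures["phase_type"] == "training"] \
        if "phase_type" in measures else measures
    df = df.sort_values("trial").reset_index(drop=True)
    bins = df.index // bin_size
    cols = [c for c in columns if c in df]
    agg = df.groupby(bins)[cols].agg(["mean", "sem"])
    agg.index.name = "bin"
    return agg


def within_trial_probability(dataset: RawDataset, fixations: pd.DataFrame,
                             structure: CategoryStructure,
                             cb: Counterbalance | None = None,
                             trials: list[int] | None = None,
                             n_points: int = 100, n_bins: int = 5,
                             phase: str = "response") -> np.ndarray:
    """Per-feature fixation probability across normalised trial time.

    Each trial's response-phase AOI timeline is resampled to ``n_points``
    equal steps; occupancy is averaged over trials and then into ``n_bins``
    bins.  Samples outside any feature AOI are excluded, so at each point the
    probabilities over features sum to one (where any feature is fixated).
    Returns an (n_features, n_bins) array.
    """
    cb = cb or dataset.counterbalance
    L = structure.n_features
    loc_of = {(cb.location_of(f) if cb is not None else f): f for f in range(L)}
    counts = np.zeros((L, n_points))
    totals = np.zeros(n_points)
    fx_by_trial = dict(tuple(fixations.groupby("trial"))) if len(fixations) else {}
    trial_iter = trials if trials is not None else dataset.trials["trial"].tolist()
    for trial in trial_iter:
        rec = dataset.trials[dataset.trials["trial"] == trial].iloc[0]
        dur = rec.rt_ms if phase == "response" else rec.trial_ms
        if not np.isfinite(dur) or dur <= 0:
            continue
        fx = fx_by_trial.get(trial)
        if fx is None:
            continue
        fx = fx[fx["phase"].isin([phase, "transfer"])]
        grid_t = (np.arange(n_points) + 0.5) / n_points * dur
        for f in fx.itertuples():
            if f.aoi == "" or f.aoi == "button" or f.aoi is None:
                continue
            feat = loc_of.get(int(f.aoi) if f.aoi != "" else -1)
            if feat is None:
                continue
            mask = (grid_t >= f.onset_ms) & (grid_t < f.onset_ms + f.duration_ms)
            counts[feat] += mask
            totals += mask
    with np.errstate(invalid="ignore", divide="ignore"):
        prob = counts / totals
    # average into bins over the normalised timeline
    per_bin = n_points // n_bins
    out = np.full((L, n_bins), np.nan)
    for b in range(n_bins):
        seg = prob[:, b * per_bin:(b + 1) * per_bin]
        if np.any(np.isfinite(seg)):
            out[:, b] = np.nanmean(seg, axis=1)
    return out


def learning_point(measures: pd.DataFrame, block_size: int) -> int:
    """First trial (1-based) of the first of two consecutive error-free
    blocks; sentinel (max trial + 1) when that never happens."""
    df = measures[measures["phase_type"] == "training"] \
        if "phase_type" in measures else measures
    acc = df.sort_values("trial")["accuracy"].to_numpy(float)
    n_blocks = len(acc) // block_size
    clean = [bool(np.all(acc[b * block_size:(b + 1) * block_size] == 1))
             for b in range(n_blocks)]
    for b in range(n_blocks - 1):
        if clean[b] and clean[b + 1]:
            return b * block_size + 1
    return len(acc) + 1


def transfer_matrix(dataset: RawDataset,
                    structure: CategoryStructure) -> pd.DataFrame:
    """Per-stimulus response proportions over the transfer phase (16 x K)."""
    tr = dataset.trials[dataset.trials["phase_type"] == "transfer"]
    K = structure.categories
    rows = []
    for stim in structure.transfer:
        sub = tr[tr["stimulus_id"] == stim]
        if len(sub):
            props = [float((sub["response"] == c).mean()) for c in K]
        else:
            props = [np.nan] * len(K)
        rows.append(props)
    return pd.DataFrame(rows, columns=list(K),
                        index=[structure.labels[s] if structure.labels[s] in K
                               else f"T{structure.transfer.index(s)}"
                               for s in structure.transfer])


def _ols_line(y: np.ndarray) -> tuple[float, float]:
    """Least-squares (intercept, slope) of y against bin index."""
    y = np.asarray(y, float)
    ok = np.isfinite(y)
    x = np.arange(len(y), dtype=float)
    if ok.sum() < 2:
        return float(y[ok][0]) if ok.any() else np.nan, 0.0
    coef = np.polyfit(x[ok], y[ok], 1)
    return float(coef[1]), float(coef[0])


def summary_vector(dataset: RawDataset, which: str,
                   structure: CategoryStructure | None = None,
                   layout: StimulusLayout | None = None,
                   bin_size: int = 15) -> np.ndarray:
    """The behavioural target vector used by the fitter.

    sim1 (8 elements): intercept and slope over trial bins for accuracy,
    fixation count, P(fixate irrelevant), and mean fixation duration.
    sim2 (19 elements): the 16 transfer A-proportions, the learning point,
    and the mean per-feature fixation counts in the first and last training
    blocks.
    """
    from .experiment_harness import build_structure
    from .visuospatial import sim1_layout, sim2_layout
    if structure is None:
        structure = build_structure(dataset.structure)
    if layout is None:
        layout = sim1_layout() if dataset.structure == "blair" else sim2_layout()
    fixes = dataset_fixations(dataset, layout)
    meas = trial_measures(dataset, fixes, structure)
    meas = meas.merge(dataset.trials[["trial", "phase_type"]].drop_duplicates(),
                      on="trial", how="left", suffixes=("", "_t"))
    if which == "sim1":
        binned = bin_measures(meas, bin_size)
        out = []
        for col in ("accuracy", "fix_count", "irrelevant_fixated",
                    "mean_fix_dur_ms"):
            inter, slope = _ols_line(binned[(col, "mean")].to_numpy())
            out.extend([inter, slope])
        return np.array(out)
    if which == "sim2":
        tm = transfer_matrix(dataset, structure)
        a_props = tm[structure.categories[0]].to_numpy(float)
        train = meas[meas["phase_type"] == "training"].sort_values("trial")
        lp = learning_point(train, block_size=len(structure.training))
        nb = len(structure.training)
        fcols = [f"fix_count_f{f + 1}" for f in range(structure.n_features)]
        start = train.iloc[:nb][fcols].to_numpy(float).mean()
        end = train.iloc[-nb:][fcols].to_numpy(float).mean()
        return np.concatenate([a_props, [lp, start, end]])
    raise ValueError(f"unknown summary kind {which!r}")
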