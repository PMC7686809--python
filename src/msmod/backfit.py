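"""Backfitting and microstate temporal statistics.

Every sample of every kept epoch is labeled with the template of highest
absolute spatial correlation (equivalently lowest polarity-invariant
GMD). The labeled sequence yields the per-state duration, occurrence and
contribution plus the directed run-to-run transition matrix — for K = 4
the 24 parameters that feed the moderation layer.

No temporal smoothing or minimum-duration rejection is applied by
default, and runs truncated at epoch edges are counted: that choice
preserves the algebraic identity contribution = occurrence x duration
(in seconds) exactly on every input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .layout import canonical_archetypes
from .segmentation import TemplateSet, compute_gfp
from .preprocessing import EpochedEEG

__all__ = [
    "LabelSequence",
    "MicrostateStats",
    "backfit_labels",
    "temporal_statistics",
    "transition_probabilities",
    "order_templates_canonically",
    "stats_row",
    "stats_table",
]


@dataclass
class LabelSequence:
    """Per-sample microstate assignment, organized per epoch."""

    labels: np.ndarray            # (n_epochs, n_samples_per_epoch) int
    best_correlation: np.ndarray  # same shape, |C| in [0, 1]
    gfp: np.ndarray               # same shape, μV
    sampling_rate: float
    n_states: int


@dataclass
class MicrostateStats:
    duration: np.ndarray      # ms per state (mean run length; 0 if unseen)
    occurrence: np.ndarray    # runs / second
    contribution: np.ndarray  # fraction of samples
    transitions: np.ndarray   # (K, K) row-stochastic over observed departures
    transition_counts: np.ndarray
    n_epochs_used: int


def backfit_labels(
    epochs: EpochedEEG,
    templates: TemplateSet,
    smooth_window: int = 0,
    min_duration_ms: float = 0.0,
) -> LabelSequence:
    """Label every sample with its best template, polarity disregarded.

    Ties go to the lowest template index. Flat samples (GFP = 0) get
    label 0 with correlation 0. Epochs are labeled independently; no
    information crosses an epoch boundary.

    By default the labeling is purely spatial, which fragments runs when
    single noisy samples flip the best template. Two optional
    post-processing steps counter that: ``smooth_window`` (odd, > 1)
    replaces each label by the majority vote in a sliding window, and
    ``min_duration_ms`` reassigns runs shorter than the threshold to the
    neighboring label of higher mean |C| (shortest runs first). Both are
    off by default.
    """
    if epochs.channel_labels and templates.maps.shape[1] != epochs.n_channels:
        raise ValueError("channel count mismatch between epochs and templates")
    if templates.maps.shape[1] != epochs.n_channels:
        raise ValueError("channel count mismatch between epochs and templates")
    t = templates.maps                                     # (k, N) unit-norm
    n_ep, n_ch, n_s = epochs.data.shape
    labels = np.empty((n_ep, n_s), dtype=int)
    best = np.empty((n_ep, n_s))
    gfp = np.empty((n_ep, n_s))
    for e in range(n_ep):
        maps = epochs.data[e] - epochs.data[e].mean(axis=0, keepdims=True)
        g = compute_gfp(epochs.data[e])
        norms = np.linalg.norm(maps, axis=0)
        safe = np.where(norms == 0, 1.0, norms)
        corr = np.abs(t @ (maps / safe))                  # (k, n_s)
        corr[:, norms == 0] = 0.0
        lab = np.argmax(corr, axis=0)
        if smooth_window > 1:
            lab = _majority_smooth(lab, smooth_window, templates.k)
        if min_duration_ms > 0:
            min_len = int(round(min_duration_ms * epochs.sampling_rate / 1000.0))
            lab = _merge_short_runs(lab, corr, min_len)
        labels[e] = lab
        best[e] = corr[lab, np.arange(n_s)]
        gfp[e] = g
    return LabelSequence(labels, best, gfp, epochs.sampling_rate, templates.k)


def _majority_smooth(lab: np.ndarray, window: int, k: int) -> np.ndarray:
    """Sliding majority vote; ties keep the original label."""
    if window % 2 == 0:
        raise ValueError("smooth_window must be odd")
    half = window // 2
    counts = np.zeros((k, lab.size), dtype=int)
    for off in range(-half, half + 1):
        shifted = np.roll(lab, off)
        if off > 0:
            shifted[:off] = lab[:off]
        elif off < 0:
            shifted[off:] = lab[off:]
        counts[shifted, np.arange(lab.size)] += 1
    out = counts.argmax(axis=0)
    best = counts[out, np.arange(lab.size)]
    keep = counts[lab, np.arange(lab.size)] == best
    out[keep] = lab[keep]
    return out


def _merge_short_runs(lab: np.ndarray, corr: np.ndarray, min_len: int) -> np.ndarray:
    """Reassign runs shorter than ``min_len`` samples, shortest first,
    to whichever neighboring run's template fits their samples better."""
    lab = lab.copy()
    while True:
        runs = []
        start = 0
        for i in range(1, lab.size + 1):
            if i == lab.size or lab[i] != lab[start]:
                runs.append((start, i))
                start = i
        if len(runs) <= 1:
            return lab
        short = [(b - a, idx) for idx, (a, b) in enumerate(runs) if b - a < min_len]
        if not short:
            return lab
        _, idx = min(short)
        a, b = runs[idx]
        cands = []
        if idx > 0:
            cands.append(lab[runs[idx - 1][0]])
        if idx < len(runs) - 1:
            cands.append(lab[runs[idx + 1][0]])
        new = max(cands, key=lambda c: corr[c, a:b].mean())
        lab[a:b] = new


def _runs_of_epoch(lab: np.ndarray):
    """Maximal same-label segments of one epoch as (state, length) pairs."""
    change = np.flatnonzero(np.diff(lab)) + 1
    bounds = np.concatenate([[0], change, [lab.size]])
    return [(int(lab[a]), int(b - a)) for a, b in zip(bounds[:-1], bounds[1:])]


def temporal_statistics(seq: LabelSequence) -> MicrostateStats:
    """Duration, occurrence, contribution and transitions from a labeling.

    duration_k is the mean run length in ms (boundary-truncated runs
    included), occurrence_k the number of runs per analyzed second, and
    contribution_k the fraction of samples labeled k. States never
    observed get zeros. These conventions satisfy
    ``contribution = occurrence * duration / 1000`` identically.
    """
    if seq.labels.size == 0:
        raise ValueError("empty label sequence")
    k = seq.n_states
    fs = seq.sampling_rate
    run_count = np.zeros(k)
    run_samples = np.zeros(k)
    counts = np.zeros((k, k))
    for lab in seq.labels:
        runs = _runs_of_epoch(lab)
        for state, length in runs:
            run_count[state] += 1
            run_samples[state] += length
        for (s1, _), (s2, _) in zip(runs[:-1], runs[1:]):
            counts[s1, s2] += 1
    total_samples = seq.labels.size
    total_sec = total_samples / fs
    with np.errstate(invalid="ignore", divide="ignore"):
        duration = np.where(run_count > 0, run_samples / np.maximum(run_count, 1), 0.0)
    duration = duration * 1000.0 / fs
    occurrence = run_count / total_sec
    contribution = run_samples / total_samples
    out = counts.sum(axis=1, keepdims=True)
    trans = np.divide(counts, out, out=np.zeros_like(counts), where=out > 0)
    return MicrostateStats(
        duration=duration,
        occurrence=occurrence,
        contribution=contribution,
        transitions=trans,
        transition_counts=counts,
        n_epochs_used=seq.labels.shape[0],
    )


def transition_probabilities(seq: LabelSequence) -> np.ndarray:
    """Row-normalized directed transition probabilities (within epochs).

    ``p[i, j]`` is the probability that a run of state i is immediately
    followed by state j; rows with no observed departures are all zero.
    """
    return temporal_statistics(seq).transitions


def order_templates_canonically(
    group_set: TemplateSet, archetypes: np.ndarray | None = None
) -> tuple[TemplateSet, np.ndarray]:
    """Name four templates MS1-MS4 by similarity to canonical archetypes.

    Solves the 4x4 assignment maximizing total |C| to the built-in
    archetype maps (two diagonal gradients, occipital symmetric,
    fronto-central focal) exactly. For k != 4 the set is returned
    unchanged with indices as names. Returns the permuted set and the
    |C| similarity matrix (rows: archetypes, columns: input maps).
    """
    if archetypes is None:
        archetypes = canonical_archetypes(group_set.maps.shape[1])
    sim = np.abs(archetypes @ group_set.maps.T)
    if group_set.k != 4:
        import warnings

        warnings.warn("canonical MS1-MS4 naming requires k = 4; keeping indices")
        out = TemplateSet(
            maps=group_set.maps.copy(),
            k=group_set.k,
            gev=group_set.gev,
            cv_value=group_set.cv_value,
            source=group_set.source,
            names=[f"state{i}" for i in range(group_set.k)],
        )
        return out, sim
    rows, cols = linear_sum_assignment(-sim)
    order = cols[np.argsort(rows)]
    out = TemplateSet(
        maps=group_set.maps[order].copy(),
        k=4,
        gev=group_set.gev,
        cv_value=group_set.cv_value,
        source=group_set.source,
        names=["MS1", "MS2", "MS3", "MS4"],
    )
    return out, sim


def stats_row(stats: MicrostateStats, subject_id: str) -> dict:
    """Flatten one subject's statistics into the 24-predictor row."""
    k = stats.duration.size
    ms = [f"ms{i + 1}" for i in range(k)]
    row: dict = {"subject_id": subject_id}
    for i in range(k):
        row[f"duration_{ms[i]}"] = stats.duration[i]
    for i in range(k):
        row[f"occurrence_{ms[i]}"] = stats.occurrence[i]
    for i in range(k):
        row[f"contribution_{ms[i]}"] = stats.contribution[i]
    for i in range(k):
        for j in range(k):
            if i != j:
                row[f"transition_{ms[i]}_{ms[j]}"] = stats.transitions[i, j]
    return row


def stats_table(stats_list: list[MicrostateStats], subject_ids: list[str]) -> pd.DataFrame:
    """Per-subject statistics as the predictor table of the moderation stage."""
    return pd.DataFrame([stats_row(s, sid) for s, sid in zip(stats_list, subject_ids)])
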