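"""EEG microstate segmentation: modified k-means on GFP-peak topographies.

Template maps are learned from the scalp maps at global-field-power peaks
with the polarity-invariant ("modified") k-means of the microstate
literature: assignment maximizes the squared spatial correlation and the
template update is the dominant eigenvector of the assigned maps' outer
product. Every sample (not just peaks) is then back-fit to the template
with the highest absolute spatial correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .containers import EpochSet


@dataclass
class MicrostateModel:
    templates: np.ndarray     # (k, n_channels), average-referenced, unit norm
    labels: np.ndarray        # (M, epoch_samples) state index per sample
    k: int
    fs: float
    gev: float                # global explained variance on GFP peaks
    polarity_invariant: bool = True


@dataclass
class MicrostateMetrics:
    lifetime_ms: np.ndarray    # mean contiguous-run duration per state
    occurrence: np.ndarray     # runs per second per state
    converting_rate: float     # state transitions per second (global)


def gfp(maps: np.ndarray) -> np.ndarray:
    """Global field power: spatial SD across channels per time point."""
    return maps.std(axis=-1)


def _avg_ref_unit(maps: np.ndarray) -> np.ndarray:
    maps = maps - maps.mean(axis=-1, keepdims=True)
    norm = np.linalg.norm(maps, axis=-1, keepdims=True)
    norm[norm == 0] = 1.0
    return maps / norm


def _kmeans_once(v: np.ndarray, k: int, rng: np.random.Generator,
                 max_iter: int = 200) -> tuple[np.ndarray, np.ndarray, float]:
    n = v.shape[0]
    templates = v[rng.choice(n, size=k, replace=False)].copy()
    assign = np.full(n, -1)
    for _ in range(max_iter):
        corr = v @ templates.T
        new_assign = np.argmax(np.abs(corr), axis=1)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for s in range(k):
            sel = v[assign == s]
            if len(sel) == 0:
                templates[s] = v[rng.integers(n)]
                continue
            # dominant eigenvector of sel^T sel: polarity-invariant mean map
            cov = sel.T @ sel
            w, vec = np.linalg.eigh(cov)
            templates[s] = vec[:, -1]
    corr = v @ templates.T
    obj = float(np.mean(np.max(corr**2, axis=1)))
    return templates, assign, obj


def microstate_fit(epochs: EpochSet, k: int = 4, n_init: int = 10,
                   seed: int = 0, min_peaks: int = 100) -> MicrostateModel:
    """Fit k microstate templates on GFP-peak maps and back-fit all samples.

    Deterministic under a fixed seed; the best of ``n_init`` restarts (by
    mean squared peak correlation) is kept. Requires at least ``min_peaks``
    GFP peaks pooled over the subject's epochs.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if epochs.n_epochs == 0:
        raise ValueError("no epochs to fit")
    maps = epochs.data.transpose(0, 2, 1).reshape(-1, epochs.data.shape[1])
    g = gfp(maps)
    peaks, _ = sps.find_peaks(g)
    if k > 1 and len(peaks) < min_peaks:
        raise ValueError(f"only {len(peaks)} GFP peaks (< {min_peaks})")
    v = _avg_ref_unit(maps[peaks] if len(peaks) else maps)
    rng = np.random.default_rng(seed)
    if k == 1:
        cov = v.T @ v
        _, vec = np.linalg.eigh(cov)
        templates = vec[:, -1][None, :]
        obj = float(np.mean((v @ templates.T) ** 2))
    else:
        best = None
        for _ in range(n_init):
            templates_i, _, obj_i = _kmeans_once(v, k, rng)
            if best is None or obj_i > best[1]:
                best = (templates_i, obj_i)
        templates, obj = best
    all_unit = _avg_ref_unit(maps)
    labels = np.argmax(np.abs(all_unit @ templates.T), axis=1)
    labels = labels.reshape(epochs.n_epochs, epochs.epoch_samples)
    # GEV: GFP-weighted squared correlation of each peak map with its template
    corr = np.abs(v @ templates.T).max(axis=1)
    gp = g[peaks] if len(peaks) else g
    gev = float((gp**2 * corr**2).sum() / (gp**2).sum()) if gp.size else 0.0
    return MicrostateModel(templates, labels, k, epochs.fs, gev)


def _runs(labels: np.ndarray) -> list[tuple[int, int]]:
    """Run-length encode a 1-D label sequence -> [(state, length), ...]."""
    if len(labels) == 0:
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    bounds = np.concatenate(([0], change, [len(labels)]))
    return [(int(labels[a]), int(b - a)) for a, b in zip(bounds[:-1], bounds[1:])]


def microstate_segment_metrics(labels: np.ndarray, k: int,
                               fs: float) -> MicrostateMetrics:
    """Lifetime/occurrence per state plus the global converting rate for one
    contiguous label sequence (runs never span sequence boundaries).

    A state absent from the sequence gets lifetime 0 and occurrence 0, which
    keeps feature matrices finite and preserves the coverage identity
    sum_s occurrence_s * lifetime_s = 1 (absent states contribute zero).
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label sequence")
    runs = _runs(labels)
    duration_s = len(labels) / fs
    lifetime = np.zeros(k)
    occurrence = np.zeros(k)
    counts = np.zeros(k)
    for state, length in runs:
        counts[state] += 1
        lifetime[state] += length
    present = counts > 0
    lifetime[present] = lifetime[present] / counts[present] / fs * 1000.0
    occurrence = counts / duration_s
    converting = (len(runs) - 1) / duration_s
    return MicrostateMetrics(lifetime, occurrence, float(converting))


def microstate_metrics(model: MicrostateModel) -> MicrostateMetrics:
    """Aggregate metrics over all epochs (runs computed per epoch, pooled)."""
    k, fs = model.k, model.fs
    all_runs: list[tuple[int, int]] = []
    n_transitions = 0
    for e in range(model.labels.shape[0]):
        runs = _runs(model.labels[e])
        all_runs.extend(runs)
        n_transitions += len(runs) - 1
    duration_s = model.labels.size / fs
    lifetime = np.zeros(k)
    counts = np.zeros(k)
    for state, length in all_runs:
        counts[state] += 1
        lifetime[state] += length
    present = counts > 0
    lifetime[present] = lifetime[present] / counts[present] / fs * 1000.0
    occurrence = counts / duration_s
    return MicrostateMetrics(lifetime, occurrence, n_transitions / duration_s)
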