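"""Raw recording -> cleaned 5-s epochs.

Fixed stage order: band-pass (1-55 Hz) -> 50 Hz notch -> common average
reference -> windowed artifact rejection (25-s windows, >30% artifactual
samples excluded) -> non-overlapping 5-s epochs drawn from retained data.

Filters are zero-phase (forward-backward), so epoch boundaries are not
shifted by group delay. All amplitudes are microvolts.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal as sps

from .containers import ArtifactMask, EpochSet, Recording

log = logging.getLogger(__name__)

DEFAULT_BANDPASS = (1.0, 55.0)
DEFAULT_NOTCH = 50.0
ARTIFACT_WINDOW_S = 25.0
ARTIFACT_FRACTION_THRESHOLD = 0.30
EPOCH_S = 5.0

#: Per-sample artifact rule: |x| above min(100 uV, 6 x robust SD) on any
#: channel flags the sample. Robust SD is 1.4826 x median absolute deviation.
AMPLITUDE_CEILING_UV = 100.0
ROBUST_SD_FACTOR = 6.0


def bandpass_filter(rec: Recording, low: float = DEFAULT_BANDPASS[0],
                    high: float = DEFAULT_BANDPASS[1]) -> Recording:
    """Zero-phase Butterworth band-pass (order 4 effective)."""
    nyq = rec.fs / 2.0
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= nyq:
        raise ValueError(f"high cutoff {high} Hz >= Nyquist {nyq} Hz")
    sos = sps.butter(2, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    return rec.copy_with(sps.sosfiltfilt(sos, rec.signal, axis=1))


def notch_filter(rec: Recording, freq: float = DEFAULT_NOTCH,
                 quality: float = 30.0) -> Recording:
    """Zero-phase second-order IIR notch at the powerline frequency."""
    if not 0 < freq < rec.fs / 2.0:
        raise ValueError("notch frequency must lie below Nyquist")
    b, a = sps.iirnotch(freq, quality, fs=rec.fs)
    return rec.copy_with(sps.filtfilt(b, a, rec.signal, axis=1))


def common_average_reference(rec: Recording) -> Recording:
    """Subtract the instantaneous cross-channel mean from every channel."""
    if rec.n_channels < 2:
        raise ValueError("common average reference needs >= 2 channels")
    return rec.copy_with(rec.signal - rec.signal.mean(axis=0, keepdims=True))


def _artifact_samples(signal: np.ndarray) -> np.ndarray:
    """Boolean per-sample artifact flags (any channel exceeding threshold)."""
    med = np.median(signal, axis=1, keepdims=True)
    mad = np.median(np.abs(signal - med), axis=1, keepdims=True)
    robust_sd = 1.4826 * mad
    thresh = np.minimum(AMPLITUDE_CEILING_UV, ROBUST_SD_FACTOR * robust_sd)
    return (np.abs(signal) > thresh).any(axis=0)


def detect_artifacts(rec: Recording, window_s: float = ARTIFACT_WINDOW_S,
                     fraction_threshold: float = ARTIFACT_FRACTION_THRESHOLD,
                     ) -> ArtifactMask:
    """Window-wise artifact census over consecutive (non-overlapping) windows.

    A window is excluded when strictly more than ``fraction_threshold`` of
    its samples are flagged. A recording shorter than one window yields a
    single truncated window (with a warning in the log).
    """
    win = int(round(window_s * rec.fs))
    n = rec.n_samples
    if n < win:
        log.warning("recording shorter than one %ss window; using one "
                    "truncated window", window_s)
    # last window is truncated when the duration is not a multiple of the
    # window, so the census covers every sample
    starts = np.arange(0, n, win)
    flags = _artifact_samples(rec.signal)
    fractions = np.empty(len(starts))
    for i, s in enumerate(starts):
        chunk = flags[s:s + win]
        fractions[i] = chunk.mean() if len(chunk) else 0.0
    excluded = fractions > fraction_threshold
    return ArtifactMask(starts, win, fractions, excluded, fraction_threshold)


def epoch(rec: Recording, mask: ArtifactMask | None = None,
          epoch_s: float = EPOCH_S) -> EpochSet:
    """Cut non-overlapping epochs from retained windows.

    Epochs are drawn independently within each maximal run of retained
    windows (so no epoch straddles an excluded window or a gap); remainder
    samples at the end of a run are discarded.
    """
    ep_len = int(round(epoch_s * rec.fs))
    if mask is None:
        mask = ArtifactMask(np.array([0]), rec.n_samples,
                            np.array([0.0]), np.array([False]),
                            ARTIFACT_FRACTION_THRESHOLD)
    segments = []  # (start, stop) of contiguous retained sample runs
    run_start = None
    for i, s in enumerate(mask.window_starts):
        stop = min(int(s) + mask.window_length, rec.n_samples)
        if not mask.excluded[i]:
            if run_start is None:
                run_start = int(s)
            run_stop = stop
        else:
            if run_start is not None:
                segments.append((run_start, run_stop))
                run_start = None
    if run_start is not None:
        segments.append((run_start, run_stop))
    # tail samples beyond the last full window belong to no window: discard.

    chunks, offsets = [], []
    for start, stop in segments:
        n_ep = (stop - start) // ep_len
        for k in range(n_ep):
            a = start + k * ep_len
            chunks.append(rec.signal[:, a:a + ep_len])
            offsets.append(a)
    if not chunks:
        log.warning("no retained data for %s; empty epoch set", rec.subject_id)
        data = np.empty((0, rec.n_channels, ep_len))
    else:
        data = np.stack(chunks)
    return EpochSet(data, rec.fs, rec.subject_id, rec.channel_names,
                    np.asarray(offsets, dtype=int))


def preprocess_recording(rec: Recording,
                         bandpass: tuple[float, float] = DEFAULT_BANDPASS,
                         notch: float = DEFAULT_NOTCH,
                         window_s: float = ARTIFACT_WINDOW_S,
                         fraction_threshold: float = ARTIFACT_FRACTION_THRESHOLD,
                         epoch_s: float = EPOCH_S) -> EpochSet:
    """Full cleaning pipeline in the fixed stage order."""
    rec = bandpass_filter(rec, *bandpass)
    rec = notch_filter(rec, notch)
    rec = common_average_reference(rec)
    mask = detect_artifacts(rec, window_s, fraction_threshold)
    return epoch(rec, mask, epoch_s)
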