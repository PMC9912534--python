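"""Per-epoch EEG feature families and feature-matrix assembly.

Six families are computed from each cleaned 5-s epoch:

* absolute band power (Welch PSD integrated over each band, per channel);
* relative band power (share of the five-band total, per channel);
* Hjorth activity / mobility / complexity (broadband, per channel);
* sample entropy (broadband, per channel);
* STFT band-power trajectory summaries (temporal mean and SD of the
  cross-channel band power, per band);
* microstate statistics (per-state lifetime and occurrence plus a global
  converting rate), from a per-subject microstate model.

Column names encode (family, band, channel) as ``family/band/channel``;
broadband time-domain families use band ``bb``, cross-channel families use
channel ``all``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy import signal as sps

from .containers import EpochSet
from .microstate import MicrostateModel, microstate_fit, microstate_segment_metrics
from .montage import DEFAULT_BANDS, BandScheme

log = logging.getLogger(__name__)

BROADBAND = (1.0, 45.0)


# --------------------------------------------------------------------------
# Spectral power
# --------------------------------------------------------------------------

def band_power(x: np.ndarray, band: tuple[float, float], fs: float) -> float:
    """Absolute band power: Welch PSD (1-s Hann windows, 50% overlap)
    integrated over the band. Units uV^2 for a microvolt signal."""
    low, high = band
    if not 0 < low < high < fs / 2.0:
        raise ValueError(f"band {band} outside (0, {fs / 2})")
    x = np.asarray(x, dtype=float)
    nperseg = min(int(fs), len(x))
    f, psd = sps.welch(x, fs=fs, nperseg=nperseg, noverlap=nperseg // 2)
    m = (f >= low) & (f <= high)
    return float(np.trapezoid(psd[m], f[m]))


def band_powers(x: np.ndarray, fs: float,
                bands: BandScheme = DEFAULT_BANDS) -> dict[str, float]:
    return {name: band_power(x, interval, fs) for name, interval in bands.items()}


def relative_power(abs_powers: dict[str, float]) -> dict[str, float]:
    """Each band's share of the summed five-band power (sums to 1)."""
    total = float(sum(abs_powers.values()))
    if total <= 0:
        raise ValueError("all band powers zero: degenerate epoch")
    return {k: v / total for k, v in abs_powers.items()}


# --------------------------------------------------------------------------
# Hjorth parameters
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HjorthParams:
    activity: float       # variance, uV^2
    mobility: float       # sqrt(var(dx)/var(x)), unitless
    complexity: float     # mobility(dx)/mobility(x), unitless
    degenerate: bool = False


def hjorth(x: np.ndarray) -> HjorthParams:
    """Hjorth descriptors with derivatives taken as first differences."""
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    var0 = np.var(x)
    if var0 == 0:
        return HjorthParams(0.0, np.nan, np.nan, degenerate=True)
    d1 = np.diff(x)
    d2 = np.diff(d1)
    var1, var2 = np.var(d1), np.var(d2)
    mob = np.sqrt(var1 / var0)
    comp = np.sqrt(var2 / var1) / mob if var1 > 0 else np.nan
    return HjorthParams(float(var0), float(mob), float(comp))


# --------------------------------------------------------------------------
# Sample entropy
# --------------------------------------------------------------------------

@njit(cache=False)
def _sampen_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Counts of template pairs matching at length m (B) and m+1 (A) under
    Chebyshev distance <= r, self-matches excluded."""
    n = x.shape[0]
    n_templates = n - m
    b_count = 0
    a_count = 0
    for i in range(n_templates - 1):
        for j in range(i + 1, n_templates):
            match = True
            for k in range(m):
                if abs(x[i + k] - x[j + k]) > r:
                    match = False
                    break
            if match:
                b_count += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a_count += 1
    return a_count, b_count


def sample_entropy(x: np.ndarray, m: int = 2,
                   r: float | None = None) -> float:
    """SampEn(m, r): -log(A/B) over length-m / length-(m+1) template matches.

    ``r`` defaults to 0.2 x SD of the signal. When no matches exist at
    either length the value is undefined and NaN is returned (callers
    aggregate with NaN-aware reductions and log the count).
    """
    x = np.asarray(x, dtype=float)
    if len(x) < m + 2:
        raise ValueError("signal too short for the template length")
    if r is None:
        r = 0.2 * float(np.std(x))
    if not r > 0:
        raise ValueError("tolerance r must be positive")
    a, b = _sampen_counts(x, m, r)
    if a == 0 or b == 0:
        log.debug("sample entropy undefined (A=%d, B=%d)", a, b)
        return float("nan")
    return float(-np.log(a / b))


# --------------------------------------------------------------------------
# STFT band-power trajectories
# --------------------------------------------------------------------------

def stft_band_features(epoch: np.ndarray, fs: float,
                       band: tuple[float, float]) -> tuple[float, float]:
    """Temporal (mean, SD) of cross-channel band power from a short-time
    spectrogram (1-s Hann windows, 50% overlap) of one epoch."""
    low, high = band
    if not 0 < low < high < fs / 2.0:
        raise ValueError(f"band {band} outside (0, {fs / 2})")
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    nperseg = min(int(fs), epoch.shape[1])
    f, _, sxx = sps.spectrogram(epoch, fs=fs, nperseg=nperseg,
                                noverlap=nperseg // 2, axis=1)
    m = (f >= low) & (f <= high)
    if not m.any():
        raise ValueError("band empty under the STFT frequency grid")
    # sxx: (channels, freqs, frames) -> band power per frame, channel-mean
    traj = np.trapezoid(sxx[:, m, :], f[m], axis=1).mean(axis=0)
    return float(traj.mean()), float(traj.std())


# --------------------------------------------------------------------------
# Feature-matrix assembly
# --------------------------------------------------------------------------

def feature_columns(channel_names: tuple[str, ...],
                    bands: BandScheme = DEFAULT_BANDS, k_states: int = 4,
                    ) -> list[str]:
    """The fixed column layout of the epoch-level feature matrix."""
    cols: list[str] = []
    for band in bands.names:
        cols += [f"abs_power/{band}/{ch}" for ch in channel_names]
    for band in bands.names:
        cols += [f"rel_power/{band}/{ch}" for ch in channel_names]
    for fam in ("hjorth_activity", "hjorth_mobility", "hjorth_complexity"):
        cols += [f"{fam}/bb/{ch}" for ch in channel_names]
    cols += [f"sampen/bb/{ch}" for ch in channel_names]
    for band in bands.names:
        cols += [f"stft_mean/{band}/all", f"stft_sd/{band}/all"]
    states = [chr(ord("A") + i) for i in range(k_states)]
    cols += [f"ms_lifetime/-/{s}" for s in states]
    cols += [f"ms_occurrence/-/{s}" for s in states]
    cols += ["ms_converting_rate/-/all"]
    return cols


def parse_column(name: str) -> tuple[str, str, str]:
    family, band, channel = name.split("/")
    return family, band, channel


def epoch_features(es: EpochSet, model: MicrostateModel | None = None,
                   bands: BandScheme = DEFAULT_BANDS,
                   k_states: int = 4, seed: int = 0) -> pd.DataFrame:
    """One row of named features per epoch of a single subject.

    The microstate model is fit once per subject across all its epochs
    (unless one is supplied) and back-fit metrics are computed per epoch.
    Time-domain families (Hjorth, sample entropy) use the broadband signal.
    """
    if es.n_epochs == 0:
        return pd.DataFrame(columns=feature_columns(es.channel_names, bands,
                                                    k_states))
    if model is None:
        model = microstate_fit(es, k=k_states, seed=seed)
    fs = es.fs
    rows = []
    nan_sampen = 0
    for e in range(es.n_epochs):
        row: dict[str, float] = {}
        abs_by_ch = {}
        for c, ch in enumerate(es.channel_names):
            x = es.data[e, c]
            powers = band_powers(x, fs, bands)
            abs_by_ch[ch] = powers
            for band, p in powers.items():
                row[f"abs_power/{band}/{ch}"] = p
        for ch, powers in abs_by_ch.items():
            rel = relative_power(powers)
            for band, p in rel.items():
                row[f"rel_power/{band}/{ch}"] = p
        for c, ch in enumerate(es.channel_names):
            hj = hjorth(es.data[e, c])
            row[f"hjorth_activity/bb/{ch}"] = hj.activity
            row[f"hjorth_mobility/bb/{ch}"] = hj.mobility
            row[f"hjorth_complexity/bb/{ch}"] = hj.complexity
            se = sample_entropy(es.data[e, c])
            if np.isnan(se):
                nan_sampen += 1
            row[f"sampen/bb/{ch}"] = se
        for band, interval in bands.items():
            mu, sd = stft_band_features(es.data[e], fs, interval)
            row[f"stft_mean/{band}/all"] = mu
            row[f"stft_sd/{band}/all"] = sd
        ms = microstate_segment_metrics(model.labels[e], model.k, fs)
        states = [chr(ord("A") + i) for i in range(model.k)]
        for s, name in enumerate(states):
            row[f"ms_lifetime/-/{name}"] = ms.lifetime_ms[s]
            row[f"ms_occurrence/-/{name}"] = ms.occurrence[s]
        row["ms_converting_rate/-/all"] = ms.converting_rate
        rows.append(row)
    if nan_sampen:
        log.info("%s: %d undefined sample-entropy values left as NaN",
                 es.subject_id, nan_sampen)
    fm = pd.DataFrame(rows, columns=feature_columns(es.channel_names, bands,
                                                    k_states))
    fm.insert(0, "subject_id", es.subject_id)
    fm.insert(1, "epoch", np.arange(es.n_epochs))
    return fm


def build_feature_matrix(epoch_sets: list[EpochSet], level: str = "epoch",
                         bands: BandScheme = DEFAULT_BANDS,
                         k_states: int = 4, seed: int = 0) -> pd.DataFrame:
    """Assemble the cohort feature matrix at epoch or subject level.

    ``level='epoch'`` keeps one row per epoch (classification use);
    ``level='subject'`` averages each subject's epochs (NaN-aware mean) to
    one row per subject (statistics / correlation / prediction use).
    """
    if level not in ("epoch", "subject"):
        raise ValueError("level must be 'epoch' or 'subject'")
    frames = []
    ref_cols: list[str] | None = None
    for es in epoch_sets:
        if es.n_epochs == 0:
            log.warning("%s has no epochs; skipped", es.subject_id)
            continue
        fm = epoch_features(es, bands=bands, k_states=k_states, seed=seed)
        cols = list(fm.columns)
        if ref_cols is None:
            ref_cols = cols
        elif cols != ref_cols:
            raise ValueError("inconsistent feature sets across subjects")
        frames.append(fm)
    if not frames:
        raise ValueError("no epochs available in any subject")
    fm = pd.concat(frames, ignore_index=True)
    if level == "subject":
        value_cols = [c for c in fm.columns if c not in ("subject_id", "epoch")]
        fm = (fm.groupby("subject_id", sort=False)[value_cols]
                .mean().reset_index())
    return fm
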