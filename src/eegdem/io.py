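"""File interfaces: subject tables, feature matrices with column manifests,
and optional EDF/BDF import onto the standard montage.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .containers import Recording
from .features import parse_column
from .montage import MONTAGE_16


def save_subject_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def load_subject_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_feature_matrix(fm: pd.DataFrame, path: str | Path) -> Path:
    """CSV plus a JSON manifest mapping column -> (family, band, channel)."""
    path = Path(path)
    fm.to_csv(path, index=False)
    manifest = {}
    for col in fm.columns:
        if col in ("subject_id", "epoch"):
            continue
        family, band, channel = parse_column(col)
        manifest[col] = {"family": family, "band": band, "channel": channel}
    path.with_suffix(".manifest.json").write_text(json.dumps(manifest, indent=1))
    return path


def load_feature_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def map_channels(raw_names: list[str],
                 channel_map: dict[str, str] | None = None,
                 montage: tuple[str, ...] = MONTAGE_16) -> list[int]:
    """Indices of the raw channels corresponding to the montage, in montage
    order. ``channel_map`` translates recorder-specific names (e.g.
    ``"EEG Fp1-REF"``) to montage names; without it, a case-insensitive
    substring match against montage names is attempted."""
    resolved: dict[str, int] = {}
    for i, name in enumerate(raw_names):
        target = None
        if channel_map and name in channel_map:
            target = channel_map[name]
        else:
            for ch in montage:
                if ch.lower() == name.strip().lower() or \
                        ch.lower() in name.lower().split("-")[0].lower().split():
                    target = ch
                    break
        if target is not None and target not in resolved:
            resolved[target] = i
    missing = [ch for ch in montage if ch not in resolved]
    if missing:
        raise ValueError(f"channels not found in the file: {missing}")
    return [resolved[ch] for ch in montage]


def read_edf(path: str | Path, channel_map: dict[str, str] | None = None,
             subject_id: str | None = None) -> Recording:
    """Read an EDF/BDF file onto the 16-channel montage (requires mne)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF input requires the optional 'mne' dependency "
                          "(pip install eegdem[edf])") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    idx = map_channels(raw.ch_names, channel_map)
    data = raw.get_data()[idx] * 1e6  # volts -> microvolts
    return Recording(data, float(raw.info["sfreq"]), MONTAGE_16,
                     subject_id or Path(path).stem)
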