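"""Raw-signal handling: loading, filtering, rectification, epoching.

EEG channels are bandpassed at 0.05-100 Hz and EMG channels at 30-200 Hz
(order-4 Butterworth, applied forward-backward so the filtering is
zero-phase: any group delay would masquerade as lagged dependence between
channels).  A 50 Hz notch (quality factor 30) removes mains interference
from all channels, and EMG channels are full-wave rectified after
filtering.  Trials are cut into fixed-length epochs (3000 samples at
1000 Hz in the motivating experiments).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import signal

__all__ = [
    "ChannelMatrix",
    "PreprocConfig",
    "load_manifest",
    "load_signals",
    "preprocess",
    "epoch_trials",
]

MODALITIES = ("EEG", "EMG")


@dataclass
class ChannelMatrix:
    """Labeled multichannel series: channels x samples."""

    channel_ids: list
    modalities: list
    fs: float
    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if not (len(self.channel_ids) == len(self.modalities) == self.data.shape[0]):
            raise ValueError("channel_ids, modalities and data rows must align")
        bad = [m for m in self.modalities if m not in MODALITIES]
        if bad:
            raise ValueError(f"unknown modalities {bad}; use EEG or EMG")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def rows(self, modality: str) -> np.ndarray:
        return np.array([m == modality for m in self.modalities])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data.T, columns=self.channel_ids)


@dataclass
class PreprocConfig:
    eeg_band: tuple = (0.05, 100.0)
    emg_band: tuple = (30.0, 200.0)
    notch_freq: float | None = 50.0
    notch_q: float = 30.0
    rectify_emg: bool = True
    filter_order: int = 4


def load_manifest(manifest) -> dict:
    """Channel manifest: ordered mapping channel id -> modality.

    Accepts a dict or a YAML file path.
    """
    if isinstance(manifest, (str, Path)):
        with open(manifest) as f:
            manifest = yaml.safe_load(f)
    if not isinstance(manifest, dict) or not manifest:
        raise ValueError("manifest must be a non-empty mapping id -> modality")
    out = {}
    for cid, mod in manifest.items():
        mod = str(mod).upper()
        if mod not in MODALITIES:
            raise ValueError(f"channel {cid!r}: modality must be EEG or EMG, got {mod!r}")
        out[str(cid)] = mod
    return out


def _load_edf(path, names):
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    missing = [c for c in names if c not in raw.ch_names]
    if missing:
        raise ValueError(f"channels missing from {path}: {missing}")
    data = raw.get_data(picks=names)
    return data, float(raw.info["sfreq"])


def load_signals(path, manifest, fs: float = 1000.0) -> ChannelMatrix:
    """Read a CSV/TSV (one column per channel, header row) or EDF recording.

    Row order follows the manifest.  For CSV/TSV the sampling rate must be
    supplied (``fs``); EDF carries its own.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    man = load_manifest(manifest)
    names = list(man)
    suffix = path.suffix.lower()
    if suffix == ".edf":
        data, fs = _load_edf(path, names)
    else:
        sep = "\t" if suffix in (".tsv", ".txt") else ","
        df = pd.read_csv(path, sep=sep)
        missing = [c for c in names if c not in df.columns]
        if missing:
            raise ValueError(f"channels missing from {path}: {missing}")
        sub = df[names]
        if sub.isna().any().any():
            ragged = sub.columns[sub.isna().any()].tolist()
            raise ValueError(f"ragged/missing samples in columns {ragged}")
        data = sub.to_numpy(dtype=float).T
    return ChannelMatrix(
        channel_ids=names,
        modalities=[man[c] for c in names],
        fs=fs,
        data=data,
    )


def _bandpass(x, band, fs, order):
    lo, hi = band
    nyq = fs / 2.0
    if not 0 < lo < hi < nyq:
        raise ValueError(f"band edges {band} must satisfy 0 < lo < hi < Nyquist ({nyq})")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


def _notch(x, freq, q, fs):
    if freq >= fs / 2.0:
        raise ValueError(f"notch frequency {freq} must be below Nyquist ({fs / 2.0})")
    b, a = signal.iirnotch(freq, q, fs=fs)
    return signal.filtfilt(b, a, x, axis=-1)


def preprocess(cm: ChannelMatrix, cfg: PreprocConfig | None = None) -> ChannelMatrix:
    """Zero-phase bandpass per modality, 50 Hz notch, full-wave EMG
    rectification (after filtering).  Returns a new ChannelMatrix."""
    cfg = cfg or PreprocConfig()
    if not np.all(np.isfinite(cm.data)):
        raise ValueError("non-finite samples in input")
    data = cm.data.copy()
    eeg = cm.rows("EEG")
    emg = cm.rows("EMG")
    if cfg.eeg_band is not None and eeg.any():
        data[eeg] = _bandpass(data[eeg], cfg.eeg_band, cm.fs, cfg.filter_order)
    if cfg.emg_band is not None and emg.any():
        data[emg] = _bandpass(data[emg], cfg.emg_band, cm.fs, cfg.filter_order)
    if cfg.notch_freq is not None:
        data = _notch(data, cfg.notch_freq, cfg.notch_q, cm.fs)
    if cfg.rectify_emg and emg.any():
        data[emg] = np.abs(data[emg])
    return replace(cm, data=data)


def epoch_trials(cm: ChannelMatrix, onsets, length: int) -> list:
    """Cut fixed-length epochs starting at the given sample indices."""
    if length <= 0:
        raise ValueError("epoch length must be positive")
    out = []
    for onset in onsets:
        onset = int(onset)
        if onset < 0 or onset + length > cm.n_samples:
            raise ValueError(
                f"onset {onset} with length {length} exceeds {cm.n_samples} samples"
            )
        out.append(replace(cm, data=cm.data[:, onset : onset + length].copy()))
    return out
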