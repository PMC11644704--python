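"""Raw recordings → normalized 61 × 250 model-ready samples.

The chain follows offline MI-EEG practice: epoch extraction around event
markers, EOG removal with linked-mastoid re-referencing, a zero-phase
band-pass (5th-order Butterworth, 7–31 Hz), downsampling to 250 Hz,
nonoverlapping 1 s sliding-window augmentation (five 61 × 250 windows per
5 s trial), and per-sample min–max normalization to [0, 1].

All windows are half-open ``[start, end)`` with 0-based sample indexing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from macnet.errors import (
    ConfigurationError,
    EpochBoundsError,
    MontageError,
    SegmentationError,
)
from macnet.simulate import RawRecording

LINEAGE_DTYPE = np.dtype(
    [("subject", "i4"), ("session", "i4"), ("trial", "i4"), ("window", "i4")]
)


@dataclass
class EpochSet:
    """Epoched trials: data [trials × channels × time] in µV."""

    data: np.ndarray
    labels: np.ndarray              # class index per trial
    sfreq: float
    channel_names: tuple[str, ...]
    classes: tuple[str, ...]
    trial_ids: np.ndarray = None    # global trial index, default arange
    session_ids: np.ndarray = None

    def __post_init__(self):
        n = self.data.shape[0]
        if len(self.labels) != n:
            raise ConfigurationError("labels length must equal trial count")
        if self.trial_ids is None:
            self.trial_ids = np.arange(n)
        if self.session_ids is None:
            self.session_ids = np.zeros(n, dtype=np.int64)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


@dataclass
class SampleSet:
    """Model-ready samples: data [N × channels × time], labels, lineage."""

    data: np.ndarray
    labels: np.ndarray
    lineage: np.ndarray             # structured (subject, session, trial, window)
    sfreq: float
    channel_names: tuple[str, ...]
    classes: tuple[str, ...]

    def __post_init__(self):
        if len(self.labels) != self.data.shape[0]:
            raise ConfigurationError("labels length must equal sample count")

    def __len__(self) -> int:
        return self.data.shape[0]

    def select_channels(self, names) -> "SampleSet":
        idx = [self.channel_names.index(c) for c in names]
        return replace(
            self, data=self.data[:, idx, :], channel_names=tuple(names)
        )


def extract_epochs(rec: RawRecording, t_start: float = 0.5,
                   t_end: float = 5.5) -> EpochSet:
    """One epoch per event, window [event + t_start, event + t_end)."""
    if t_end <= t_start:
        raise ConfigurationError(f"t_end={t_end} must exceed t_start={t_start}")
    fs = rec.sfreq
    offset = int(round(t_start * fs))
    length = int(round((t_end - t_start) * fs))
    n_samples = rec.data.shape[1]
    label_to_idx = {c: i for i, c in enumerate(rec.classes)}

    epochs, labels = [], []
    for k, (onset, label) in enumerate(rec.events):
        start = onset + offset
        stop = start + length
        if start < 0 or stop > n_samples:
            raise EpochBoundsError(
                f"event {k} at sample {onset} needs [{start}, {stop}) but the "
                f"recording has {n_samples} samples"
            )
        epochs.append(rec.data[:, start:stop])
        labels.append(label_to_idx[label])

    return EpochSet(
        data=np.stack(epochs, axis=0).astype(np.float64),
        labels=np.asarray(labels, dtype=np.int64),
        sfreq=fs,
        channel_names=tuple(rec.channel_names),
        classes=tuple(rec.classes),
    )


def drop_eog_and_rereference(ep: EpochSet,
                             mastoids: tuple[str, str] = ("M1", "M2"),
                             eog: str = "EOG") -> EpochSet:
    """Drop EOG, subtract the mastoid mean from every channel, drop mastoids."""
    names = list(ep.channel_names)
    for required in (eog, *mastoids):
        if required not in names:
            raise MontageError(f"channel {required!r} missing from montage")
    m1, m2 = (names.index(m) for m in mastoids)
    ref = 0.5 * (ep.data[:, m1, :] + ep.data[:, m2, :])
    drop = {eog, *mastoids}
    keep = [i for i, c in enumerate(names) if c not in drop]
    data = ep.data[:, keep, :] - ref[:, None, :]
    return replace(
        ep, data=data, channel_names=tuple(names[i] for i in keep)
    )


def bandpass(ep: EpochSet, low: float = 7.0, high: float = 31.0,
             order: int = 5) -> EpochSet:
    """Zero-phase (forward–backward) Butterworth band-pass per channel."""
    nyq = ep.sfreq / 2.0
    if not 0 < low < high < nyq:
        raise ConfigurationError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < Nyquist {nyq}"
        )
    sos = signal.butter(order, [low, high], btype="bandpass", fs=ep.sfreq,
                        output="sos")
    data = signal.sosfiltfilt(sos, ep.data, axis=-1)
    return replace(ep, data=data)


def downsample(ep: EpochSet, target_sfreq: float = 250.0,
               method: str = "decimate") -> EpochSet:
    """Downsample by an integer factor (plain decimation by default).

    The preceding 31 Hz low-pass makes every-kth-sample decimation alias-safe
    at 250 Hz; ``method="poly"`` uses polyphase resampling instead.
    """
    factor = ep.sfreq / target_sfreq
    if abs(factor - round(factor)) > 1e-9:
        raise ConfigurationError(
            f"sfreq {ep.sfreq} is not an integer multiple of target {target_sfreq}"
        )
    factor = int(round(factor))
    if factor == 1:
        return ep
    if method == "decimate":
        data = ep.data[:, :, ::factor]
    elif method == "poly":
        data = signal.resample_poly(ep.data, up=1, down=factor, axis=-1)
    else:
        raise ConfigurationError(f"unknown downsample method {method!r}")
    return replace(ep, data=data, sfreq=target_sfreq)


def segment_windows(ep: EpochSet, win_len: int = 250,
                    subject: int = 0) -> SampleSet:
    """Cut each trial into nonoverlapping windows inheriting the trial label."""
    n_trials, n_ch, n_time = ep.data.shape
    if n_time % win_len != 0:
        raise SegmentationError(
            f"trial length {n_time} is not divisible by window length {win_len}"
        )
    n_win = n_time // win_len
    data = ep.data.reshape(n_trials, n_ch, n_win, win_len)
    data = np.ascontiguousarray(data.transpose(0, 2, 1, 3)).reshape(
        n_trials * n_win, n_ch, win_len
    )
    labels = np.repeat(ep.labels, n_win)
    lineage = np.zeros(n_trials * n_win, dtype=LINEAGE_DTYPE)
    lineage["subject"] = subject
    lineage["session"] = np.repeat(ep.session_ids, n_win)
    lineage["trial"] = np.repeat(ep.trial_ids, n_win)
    lineage["window"] = np.tile(np.arange(n_win), n_trials)
    return SampleSet(
        data=data,
        labels=labels,
        lineage=lineage,
        sfreq=ep.sfreq,
        channel_names=ep.channel_names,
        classes=ep.classes,
    )


def minmax_normalize(s: SampleSet, per_channel: bool = False) -> SampleSet:
    """x̃ = (x − min x)/(max x − min x) per sample; constant samples → zeros.

    The min/max are taken jointly over the whole channels × time array by
    default; ``per_channel=True`` normalizes each channel row separately.
    """
    axes = (-1,) if per_channel else (-2, -1)
    mn = s.data.min(axis=axes, keepdims=True)
    mx = s.data.max(axis=axes, keepdims=True)
    rng_ = mx - mn
    safe = np.where(rng_ > 0, rng_, 1.0)
    data = np.where(rng_ > 0, (s.data - mn) / safe, 0.0)
    return replace(s, data=data)


def preprocess_recording(rec: RawRecording, t_start: float = 0.5,
                         t_end: float = 5.5, low: float = 7.0,
                         high: float = 31.0, order: int = 5,
                         target_sfreq: float = 250.0, win_len: int = 250,
                         per_channel_norm: bool = False,
                         subject: int = 0, session: int = 0,
                         trial_id_offset: int = 0) -> SampleSet:
    """The full chain: epoch → re-reference → filter → downsample →
    window → normalize."""
    ep = extract_epochs(rec, t_start, t_end)
    ep.trial_ids = ep.trial_ids + trial_id_offset
    ep.session_ids = np.full(ep.n_trials, session, dtype=np.int64)
    ep = drop_eog_and_rereference(ep)
    ep = bandpass(ep, low, high, order)
    ep = downsample(ep, target_sfreq)
    samples = segment_windows(ep, win_len, subject=subject)
    return minmax_normalize(samples, per_channel=per_channel_norm)


def concat_samplesets(parts: list[SampleSet]) -> SampleSet:
    """Concatenate samplesets from multiple sessions of one montage."""
    first = parts[0]
    for p in parts[1:]:
        if p.channel_names != first.channel_names:
            raise MontageError("samplesets have different montages")
    return SampleSet(
        data=np.concatenate([p.data for p in parts], axis=0),
        labels=np.concatenate([p.labels for p in parts]),
        lineage=np.concatenate([p.lineage for p in parts]),
        sfreq=first.sfreq,
        channel_names=first.channel_names,
        classes=first.classes,
    )
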