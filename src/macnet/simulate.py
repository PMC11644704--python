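"""Synthetic lower-limb motor-imagery EEG with ERD structure.

The generator emulates a 10-20, 64-channel acquisition at 1000 Hz: each
session is a continuous recording of event-marked 5 s motor-imagery (MI)
trials over four classes (sit-to-stand "S-ST", stand-to-sit "ST-S",
"walking", "standing").  Sensorimotor channels carry a stochastic
narrowband mu rhythm (7-13 Hz) on top of 1/f background noise; during an MI
trial the mu amplitude over a class-specific subset of motor channels is scaled by
(1 - erd_depth) — event-related desynchronization relative to the "standing"
class, which keeps full mu amplitude.  Because amplitude scaling is the only
class-dependent mechanism, the mu band-power ratio between a fully
desynchronized class and standing is exactly (1 - erd_depth)**2 in
expectation, which the test suite verifies with a Welch periodogram.

Class topographies (over the default motor set):

* standing — no ERD (baseline),
* walking  — ERD on every motor channel,
* S-ST     — ERD on central + anterior (FC*) motor channels,
* ST-S     — ERD on central + posterior (CP*) motor channels.

Distinct topographies make the three non-standing classes mutually
separable, which the real experiment's near-ceiling decoding implies; a
single shared ERD depth would cap 4-class accuracy at 50%.

The EOG channel carries low-frequency half-sine blink artifacts and no class
information; the preprocessing chain simply drops it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from macnet.errors import ConfigurationError

# 64-electrode 10-20 montage of the emulated acquisition system
# (includes the bilateral mastoids M1/M2 and one EOG channel).
MONTAGE_64: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2", "F7", "F3", "Fz", "F4", "F8", "FC5", "FC1", "FC2",
    "FC6", "M1", "T7", "C3", "Cz", "C4", "T8", "M2", "CP5", "CP1", "CP2",
    "CP6", "P7", "P3", "Pz", "P4", "P8", "POz", "O1", "O2", "EOG", "AF7",
    "AF3", "AF4", "AF8", "F5", "F1", "F2", "F6", "FC3", "FCz", "FC4", "C5",
    "C1", "C2", "C6", "CP3", "CP4", "P5", "P1", "P2", "P6", "PO5", "PO3",
    "PO4", "PO6", "FT7", "FT8", "TP7", "TP8", "PO7", "PO8", "Oz",
)

DEFAULT_CLASSES: tuple[str, ...] = ("S-ST", "ST-S", "walking", "standing")

DEFAULT_MOTOR_CHANNELS: tuple[str, ...] = (
    "Cz", "C1", "C2", "C3", "C4", "FCz", "FC1", "FC2", "CP1", "CP2",
)


@dataclass(frozen=True)
class SimSpec:
    """All knobs of the EEG simulator; defaults are the emulated protocol."""

    n_channels: int = 64
    sfreq: float = 1000.0
    n_sessions: int = 20
    trials_per_session: int = 60
    classes: tuple[str, ...] = DEFAULT_CLASSES
    mu_band: tuple[float, float] = (7.0, 13.0)
    erd_depth: float = 0.5
    motor_channels: tuple[str, ...] = DEFAULT_MOTOR_CHANNELS
    noise_exponent: float = 1.0
    snr: float = 2.0
    epoch_len: float = 5.0
    gap_len: float = 5.0          # inter-trial rest/stimulus gap
    mi_margin: float = 0.5        # mu stays modulated this long past epoch_len
    amplitude_jitter: float = 0.05  # per-trial relative mu-amplitude sd
    noise_sd: float = 10.0        # background sd, µV
    spatial_mixing: float = 0.0   # 0 = no leakage (keeps power oracles exact)
    channel_names: tuple[str, ...] = MONTAGE_64
    seed: int = 0

    def validate(self) -> None:
        if len(self.channel_names) != self.n_channels:
            raise ConfigurationError(
                f"n_channels={self.n_channels} does not match "
                f"channel_names (len {len(self.channel_names)})"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ConfigurationError("channel_names: duplicate labels")
        if not 0.0 <= self.erd_depth < 1.0:
            raise ConfigurationError(f"erd_depth={self.erd_depth} not in [0, 1)")
        lo, hi = self.mu_band
        if not 0 < lo < hi:
            raise ConfigurationError(f"mu_band={self.mu_band} is not an interval")
        if self.sfreq <= 2 * hi:
            raise ConfigurationError(
                f"sfreq={self.sfreq} must exceed twice the upper mu_band edge {hi}"
            )
        if len(self.classes) != 4:
            raise ConfigurationError(f"classes must have 4 entries, got {len(self.classes)}")
        missing = [ch for ch in self.motor_channels if ch not in self.channel_names]
        if missing:
            raise ConfigurationError(f"motor_channels not in montage: {missing}")
        for name in ("trials_per_session", "n_sessions"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.snr <= 0:
            raise ConfigurationError(f"snr={self.snr} must be positive")
        if self.epoch_len <= 0 or self.gap_len < 0:
            raise ConfigurationError("epoch_len must be > 0 and gap_len >= 0")

    def replace(self, **kw) -> "SimSpec":
        return dataclasses.replace(self, **kw)


@dataclass
class RawRecording:
    """Continuous multichannel EEG with event markers (one session)."""

    data: np.ndarray                      # [channels × samples], µV
    channel_names: tuple[str, ...]
    sfreq: float
    events: list[tuple[int, str]]         # (sample index of MI onset, label)
    classes: tuple[str, ...] = DEFAULT_CLASSES

    def __post_init__(self):
        if self.sfreq <= 0:
            raise ConfigurationError(f"sfreq={self.sfreq} must be positive")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ConfigurationError("channel_names: duplicate labels")


def class_erd_profiles(spec: SimSpec) -> dict[str, dict[str, float]]:
    """Per-class ERD depth for each motor channel (0 = no desynchronization).

    Channel groups are derived from 10-20 name prefixes: anterior = F*,
    posterior = CP*/P*, central = the rest.
    """
    anterior = [c for c in spec.motor_channels if c.startswith("F")]
    posterior = [c for c in spec.motor_channels if c.startswith(("CP", "P"))]
    central = [c for c in spec.motor_channels if c not in anterior and c not in posterior]
    d = spec.erd_depth
    s_st, st_s, walking, standing = spec.classes
    return {
        standing: {},
        walking: {c: d for c in spec.motor_channels},
        s_st: {c: d for c in central + anterior},
        st_s: {c: d for c in central + posterior},
    }


def _shaped_noise(rng: np.random.Generator, n: int,
                  amp_of_f) -> np.ndarray:
    """Unit-variance Gaussian noise with spectral amplitude amp_of_f(freqs)."""
    n_bins = n // 2 + 1
    freqs = np.fft.rfftfreq(n, d=1.0)
    amp = np.asarray(amp_of_f(freqs), dtype=float)
    amp[0] = 0.0
    spec = amp * (rng.standard_normal(n_bins) + 1j * rng.standard_normal(n_bins))
    if n % 2 == 0:
        spec[-1] = spec[-1].real
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _one_over_f_noise(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    """Unit-variance Gaussian noise with a 1/f**exponent power spectrum."""
    def amp(freqs):
        a = np.zeros_like(freqs)
        a[1:] = freqs[1:] ** (-exponent / 2.0)
        return a

    return _shaped_noise(rng, n, amp)


def _mu_oscillation(rng: np.random.Generator, n: int, sfreq: float,
                    band: tuple[float, float]) -> np.ndarray:
    """Unit-variance stochastic mu rhythm: band-limited Gaussian noise.

    A flat-spectrum burst inside the mu band, so the waveform's phase and
    envelope fluctuate within a trial the way an ongoing sensorimotor rhythm
    does — successive 1 s windows of one trial are effectively independent
    draws of the same band power.
    """
    lo, hi = band

    def amp(freqs):
        f = freqs * sfreq
        return ((f >= lo) & (f <= hi)).astype(float)

    return _shaped_noise(rng, n, amp)


def _balanced_sequence(rng: np.random.Generator, classes, n_trials: int) -> list[str]:
    """Seeded random order with per-class counts differing by at most one."""
    base, extra = divmod(n_trials, len(classes))
    seq = list(classes) * base
    seq += list(rng.choice(len(classes), size=extra, replace=False))
    seq = [classes[c] if isinstance(c, (int, np.integer)) else c for c in seq]
    order = rng.permutation(len(seq))
    return [seq[i] for i in order]


def generate_recording(spec: SimSpec, session: int = 0) -> RawRecording:
    """Generate one session of continuous event-marked EEG.

    Deterministic in (spec.seed, session).  Each trial occupies
    gap_len + epoch_len + mi_margin seconds; the event marks MI onset.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, session]))
    fs = spec.sfreq
    mi_len = spec.epoch_len + spec.mi_margin
    slot = int(round((spec.gap_len + mi_len) * fs))
    mi_samples = int(round(mi_len * fs))
    gap_samples = slot - mi_samples
    n_trials = spec.trials_per_session
    n_samples = slot * n_trials + int(round(0.5 * fs))  # small tail
    n_ch = spec.n_channels

    data = np.empty((n_ch, n_samples), dtype=np.float32)
    for ci in range(n_ch):
        data[ci] = spec.noise_sd * _one_over_f_noise(
            rng, n_samples, spec.noise_exponent
        )

    labels = _balanced_sequence(rng, spec.classes, n_trials)
    profiles = class_erd_profiles(spec)
    motor_idx = {c: spec.channel_names.index(c) for c in spec.motor_channels}
    base_amp = spec.noise_sd * np.sqrt(spec.snr)  # mu variance = snr · σ²

    events: list[tuple[int, str]] = []
    for k, label in enumerate(labels):
        onset = k * slot + gap_samples
        events.append((onset, label))
        jitter = max(1.0 + spec.amplitude_jitter * rng.standard_normal(), 0.1)
        depth = profiles[label]
        for ch, ci in motor_idx.items():
            amp = base_amp * (1.0 - depth.get(ch, 0.0)) * jitter
            data[ci, onset:onset + mi_samples] += (
                amp * _mu_oscillation(rng, mi_samples, fs, spec.mu_band)
            ).astype(np.float32)

    _add_eog_blinks(rng, data, spec)

    if spec.spatial_mixing > 0.0:
        m = spec.spatial_mixing
        eeg = [i for i, c in enumerate(spec.channel_names) if c != "EOG"]
        common = data[eeg].mean(axis=0)
        data[eeg] = (1.0 - m) * data[eeg] + m * common[None, :]

    return RawRecording(
        data=data,
        channel_names=tuple(spec.channel_names),
        sfreq=fs,
        events=events,
        classes=tuple(spec.classes),
    )


def _add_eog_blinks(rng: np.random.Generator, data: np.ndarray, spec: SimSpec) -> None:
    """Random 0.5-2 Hz half-sine blink artifacts on the EOG channel only."""
    if "EOG" not in spec.channel_names:
        return
    eog = spec.channel_names.index("EOG")
    n = data.shape[1]
    fs = spec.sfreq
    n_blinks = rng.poisson(0.2 * n / fs)  # ~1 blink / 5 s
    for _ in range(n_blinks):
        freq = rng.uniform(0.5, 2.0)
        dur = int(round(fs / (2.0 * freq)))  # half period
        start = rng.integers(0, max(n - dur, 1))
        amp = rng.uniform(50.0, 150.0)
        data[eog, start:start + dur] += (
            amp * np.sin(np.pi * np.arange(dur) / dur)
        ).astype(np.float32)


def generate_sampleset(spec: SimSpec, n_per_class: int, t_samples: int = 250,
                       target_sfreq: float = 250.0):
    """Fast path: emit already-preprocessed, min-max-normalized samples.

    Bypasses the 1000 Hz acquisition chain and synthesizes 61 × t_samples
    arrays directly at `target_sfreq` with the same per-class ERD contrast.
    One sample per synthetic trial; lineage marks each sample as its own
    trial.  Intended for unit tests and quick training smoke runs.
    """
    from macnet.preprocess import SampleSet, minmax_normalize

    spec.validate()
    if n_per_class < 1:
        raise ConfigurationError(f"n_per_class={n_per_class} must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x5A]))
    drop = {"EOG", "M1", "M2"}
    names = tuple(c for c in spec.channel_names if c not in drop)
    n_ch = len(names)
    profiles = class_erd_profiles(spec)
    base_amp = spec.noise_sd * np.sqrt(spec.snr)

    n_total = n_per_class * len(spec.classes)
    data = np.empty((n_total, n_ch, t_samples), dtype=np.float64)
    labels = np.empty(n_total, dtype=np.int64)
    order = rng.permutation(n_total)
    i = 0
    for class_idx, label in enumerate(spec.classes):
        depth = profiles[label]
        for _ in range(n_per_class):
            k = order[i]
            for ci in range(n_ch):
                data[k, ci] = spec.noise_sd * _one_over_f_noise(
                    rng, t_samples, spec.noise_exponent
                )
            jitter = max(1.0 + spec.amplitude_jitter * rng.standard_normal(), 0.1)
            for ch in spec.motor_channels:
                ci = names.index(ch)
                amp = base_amp * (1.0 - depth.get(ch, 0.0)) * jitter
                data[k, ci] += amp * _mu_oscillation(
                    rng, t_samples, target_sfreq, spec.mu_band
                )
            labels[k] = class_idx
            i += 1

    lineage = np.zeros(
        n_total,
        dtype=[("subject", "i4"), ("session", "i4"), ("trial", "i4"), ("window", "i4")],
    )
    lineage["trial"] = np.arange(n_total)
    out = SampleSet(
        data=data,
        labels=labels,
        lineage=lineage,
        sfreq=target_sfreq,
        channel_names=names,
        classes=tuple(spec.classes),
    )
    return minmax_normalize(out)
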