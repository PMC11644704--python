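"""Experiment battery: branch ablation, channel reduction, ConvNet module
removal, complexity audit, and mu-band PSD topography maps."""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from macnet.errors import ConfigurationError
from macnet.metrics import EvalReport
from macnet.model import ModelConfig, build_model
from macnet.preprocess import EpochSet, SampleSet
from macnet.train import TrainConfig, tenfold_cv


# ---------------------------------------------------------------------------
# ablation / module removal / channel reduction
# ---------------------------------------------------------------------------

def _cv_mean_acc(samples: SampleSet, mcfg: ModelConfig, tcfg: TrainConfig,
                 seed: int, n_folds: int) -> EvalReport:
    factory = lambda fold: build_model(mcfg, seed=seed * 1000 + fold)
    return tenfold_cv(factory, samples, tcfg.replace(seed=seed), n_folds=n_folds)


def run_ablation(samples: SampleSet, mcfg: ModelConfig, tcfg: TrainConfig,
                 branches=(0, 1, 2), seeds=(0, 1, 2),
                 n_folds: int = 10) -> pd.DataFrame:
    """Train every branch under identical seeds/splits; per-branch mean ± SD
    accuracy over seeds × folds."""
    rows = []
    for branch in branches:
        cfg_b = mcfg.replace(branch=branch)
        accs = []
        for seed in seeds:
            report = _cv_mean_acc(samples, cfg_b, tcfg, seed, n_folds)
            accs.extend(report.fold_accs)
        accs = np.array(accs)
        rows.append(
            {
                "branch": branch,
                "mean_acc": accs.mean(),
                "sd_acc": accs.std(ddof=1) if accs.size > 1 else 0.0,
                "n_runs": accs.size,
            }
        )
    return pd.DataFrame(rows)


def run_module_removal(samples: SampleSet, mcfg: ModelConfig,
                       tcfg: TrainConfig, seeds=(0, 1, 2),
                       n_folds: int = 10) -> pd.DataFrame:
    """Branch-0 backbone vs the same backbone without its temporal or
    spatial convolution, trained identically."""
    variants = {
        "full_convnet": {},
        "no_temporal_conv": {"use_temporal_conv": False},
        "no_spatial_conv": {"use_spatial_conv": False},
    }
    rows = []
    for name, tweaks in variants.items():
        cfg_v = mcfg.replace(branch=0, **tweaks)
        accs = []
        for seed in seeds:
            report = _cv_mean_acc(samples, cfg_v, tcfg, seed, n_folds)
            accs.extend(report.fold_accs)
        accs = np.array(accs)
        rows.append(
            {
                "variant": name,
                "mean_acc": accs.mean(),
                "sd_acc": accs.std(ddof=1) if accs.size > 1 else 0.0,
                "n_runs": accs.size,
            }
        )
    return pd.DataFrame(rows)


# approximate 10-20 scalp coordinates are taken from MNE's standard montage
def center_out_channel_order(channel_names, center: str = "Cz") -> list[str]:
    """Order channels by distance from `center` on the standard 10-05 scalp,
    i.e. sensorimotor-strip-first nesting for channel-reduction runs."""
    import mne

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)  # montage rename
        montage = mne.channels.make_standard_montage("standard_1005")
    pos = montage.get_positions()["ch_pos"]
    if center not in pos:
        raise ConfigurationError(f"center channel {center!r} has no position")
    c = pos[center]
    known = {}
    for name in channel_names:
        if name in pos:
            known[name] = float(np.linalg.norm(pos[name] - c))
        else:
            known[name] = np.inf  # unknown sites go last
    return sorted(channel_names, key=lambda n: (known[n], n))


def run_channel_reduction(samples: SampleSet, mcfg: ModelConfig,
                          tcfg: TrainConfig, subset_sizes,
                          seeds=(0,), n_folds: int = 10,
                          order: list[str] | None = None) -> pd.DataFrame:
    """Evaluate on nested channel subsets growing center-out from Cz."""
    order = order or center_out_channel_order(list(samples.channel_names))
    rows = []
    for size in subset_sizes:
        if size > len(order):
            raise ConfigurationError(
                f"subset size {size} exceeds {len(order)} available channels"
            )
        if size == len(samples.channel_names):
            sub = samples          # identity subset: bit-identical pipeline
            names = samples.channel_names
        else:
            names = tuple(order[:size])
            sub = samples.select_channels(names)
        cfg_s = mcfg.replace(C=size)
        accs = []
        for seed in seeds:
            report = _cv_mean_acc(sub, cfg_s, tcfg, seed, n_folds)
            accs.extend(report.fold_accs)
        accs = np.array(accs)
        rows.append(
            {
                "n_channels": size,
                "mean_acc": accs.mean(),
                "sd_acc": accs.std(ddof=1) if accs.size > 1 else 0.0,
                "channels": ",".join(names),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# complexity audit
# ---------------------------------------------------------------------------

@dataclass
class ComplexityReport:
    """Parameter / multiply-accumulate / latency audit of one configuration.

    MACs are counted layer-analytically per sample (convolutions:
    output elements × kernel taps × input maps; projections: matrix-product
    dimensions; attention score and value products included; softmax,
    sigmoid gating and elementwise products excluded, consistent with
    common counters).  Inference latency is a wall-clock measurement at
    batch 64 and is reported, never asserted.
    """

    params_K: float
    macs_M: float
    inference_ms: float | None = None
    breakdown: dict = field(default_factory=dict)


def count_macs(cfg: ModelConfig) -> dict[str, float]:
    """Per-sample multiply-accumulate counts per layer."""
    cfg.validate()
    C, T, F = cfg.C, cfg.T, cfg.n_temporal_filters
    out: dict[str, float] = {}
    if cfg.branch >= 1:
        n_proj = 3 if cfg.value_projection else 2
        out["attention_projections"] = n_proj * T * C * C
        out["attention_scores"] = T * T * C
        out["attention_values"] = T * T * C
    t1 = cfg.conv_time_len()
    if cfg.use_temporal_conv:
        out["temporal_conv"] = F * C * t1 * cfg.temporal_kernel
    n_maps = F if cfg.use_temporal_conv else 1
    if cfg.branch == 2:
        hidden = n_maps // cfg.cbam_ratio
        out["cbam_mlp"] = 2 * (n_maps * hidden + hidden * n_maps)
        k = cfg.spatial_attention_kernel
        out["cbam_spatial_conv"] = C * t1 * 2 * k * k
    if cfg.use_spatial_conv:
        out["spatial_conv"] = cfg.n_spatial_filters * t1 * n_maps * C
        pool_maps, pool_h = cfg.n_spatial_filters, 1
    else:
        pool_maps, pool_h = n_maps, C
    p = cfg.pooled_len()
    out["avg_pool"] = pool_maps * pool_h * p * cfg.pool_kernel
    kh = 1 if cfg.use_spatial_conv else C
    out["classifier"] = cfg.n_classes * pool_maps * kh * p
    return out


def audit_complexity(cfg: ModelConfig, measure_time: bool = False,
                     batch_size: int = 64, runs: int = 100,
                     seed: int = 0) -> ComplexityReport:
    """Pure function of ModelConfig (plus an optional timing measurement)."""
    model = build_model(cfg, seed=seed)
    params = model.n_parameters()
    macs = count_macs(cfg)
    inference_ms = None
    if measure_time:
        rng = np.random.default_rng(seed)
        x = rng.random((batch_size, cfg.C, cfg.T), dtype=np.float32)
        model.predict_logits(x, batch_size=batch_size)  # warm-up
        t0 = time.perf_counter()
        for _ in range(runs):
            model.predict_logits(x, batch_size=batch_size)
        inference_ms = (time.perf_counter() - t0) / runs * 1000.0
    return ComplexityReport(
        params_K=params / 1000.0,
        macs_M=sum(macs.values()) / 1e6,
        inference_ms=inference_ms,
        breakdown={k: v / 1e6 for k, v in macs.items()},
    )


# ---------------------------------------------------------------------------
# mu-band PSD topography
# ---------------------------------------------------------------------------

@dataclass
class BandPowerMap:
    """Per-channel band-integrated PSD (µV²) for one condition."""

    powers: dict[str, float]
    condition: str
    band: tuple[float, float]

    def as_array(self, channel_names) -> np.ndarray:
        return np.array([self.powers[c] for c in channel_names])


def band_power(x: np.ndarray, sfreq: float,
               band: tuple[float, float]) -> np.ndarray:
    """Welch band power along the last axis (1 s Hann segments, 50% overlap)."""
    nperseg = min(int(round(sfreq)), x.shape[-1])
    freqs, psd = signal.welch(x, fs=sfreq, window="hann", nperseg=nperseg,
                              noverlap=nperseg // 2, axis=-1)
    lo, hi = band
    sel = (freqs >= lo) & (freqs <= hi)
    if not np.any(sel):
        raise ConfigurationError(f"band {band} contains no Welch frequency bin")
    return np.trapezoid(psd[..., sel], freqs[sel], axis=-1)


def psd_topography(epochs: EpochSet, band: tuple[float, float] = (7.0, 13.0),
                   condition: int | str | None = None) -> BandPowerMap:
    """Mean Welch band power per channel over (a condition's) trials."""
    if condition is None:
        data = epochs.data
        label = "all"
    else:
        if isinstance(condition, str):
            idx = epochs.classes.index(condition)
            label = condition
        else:
            idx = int(condition)
            label = epochs.classes[idx] if epochs.classes else str(idx)
        mask = epochs.labels == idx
        if not np.any(mask):
            raise ConfigurationError(f"no trials with condition {condition!r}")
        data = epochs.data[mask]
    bp = band_power(data, epochs.sfreq, band).mean(axis=0)
    return BandPowerMap(
        powers={c: float(p) for c, p in zip(epochs.channel_names, bp)},
        condition=label,
        band=band,
    )


def diff_map(a: BandPowerMap, b: BandPowerMap) -> BandPowerMap:
    """Elementwise a − b (e.g. walking minus standing)."""
    if set(a.powers) != set(b.powers):
        raise ConfigurationError("band-power maps cover different channels")
    return BandPowerMap(
        powers={c: a.powers[c] - b.powers[c] for c in a.powers},
        condition=f"{a.condition}-{b.condition}",
        band=a.band,
    )
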