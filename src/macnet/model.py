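"""The attention-enhanced convolutional classifier.

Architecture (branch II, the full model), for a 61 × 250 input sample:

    temporal self-attention refinement (+ residual)          [1, 61, 250]
    temporal convolution, 40 × (1, 25), valid                [40, 61, 226]
    CBAM (channel gate → spatial gate) + skip connection     [40, 61, 226]
    spatial convolution, 40 × (61, 1)                        [40, 1, 226]
    batch normalization (affine-free) → square               [40, 1, 226]
    average pooling (1, 75) stride (1, 15)                   [40, 1, 11]
    dropout p = 0.3 → safe log                               [40, 1, 11]
    classifying convolution, 4 × (1, 11) → softmax           [4]

Branch 0 omits both attention modules (the shallow-ConvNet backbone);
branch 1 adds only the temporal refinement; branch 2 adds CBAM as well.
The square → mean-pool → log head follows the shallow-ConvNet lineage; a
flag recovers the plain BN → pool → log reading.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, replace

import numpy as np

from macnet import nn
from macnet.attention import TemporalSelfAttention
from macnet.errors import ConfigurationError
from macnet.layers import BatchNorm2d, Conv2d, Linear, Module

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters (defaults reproduce the published model)."""

    C: int = 61                       # electrode channels
    T: int = 250                      # time points per sample
    n_classes: int = 4
    n_temporal_filters: int = 40
    temporal_kernel: int = 25
    cbam_ratio: int = 16
    spatial_attention_kernel: int = 7
    n_spatial_filters: int = 40
    pool_kernel: int = 75
    pool_stride: int = 15
    dropout_p: float = 0.3
    classifier_kernel: int = 11
    safe_log_eps: float = 1e-6
    branch: int = 2                   # 0 = ConvNet, 1 = +temporal attn, 2 = +CBAM
    dropout_before_log: bool = False  # True = literal published layer listing
    square_before_pool: bool = True
    bn_affine: bool = False
    value_projection: bool = True
    use_temporal_conv: bool = True    # module-removal variants (branch 0 studies)
    use_spatial_conv: bool = True

    def validate(self) -> None:
        for name in ("C", "T", "n_classes", "n_temporal_filters",
                     "temporal_kernel", "cbam_ratio", "n_spatial_filters",
                     "pool_kernel", "pool_stride", "classifier_kernel"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.branch not in (0, 1, 2):
            raise ConfigurationError(f"branch={self.branch} not in {{0, 1, 2}}")
        if self.use_temporal_conv and self.T < self.temporal_kernel:
            raise ConfigurationError(
                f"T={self.T} shorter than temporal kernel {self.temporal_kernel}"
            )
        if self.conv_time_len() < self.pool_kernel:
            raise ConfigurationError("pooling kernel exceeds feature length")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ConfigurationError(f"dropout_p={self.dropout_p} not in [0, 1)")
        if self.branch == 2 and self.n_temporal_filters // self.cbam_ratio < 1:
            raise ConfigurationError(
                "cbam_ratio leaves a zero-width MLP hidden layer"
            )

    def conv_time_len(self) -> int:
        """Time length after the (optional) temporal convolution."""
        return self.T - self.temporal_kernel + 1 if self.use_temporal_conv else self.T

    def pooled_len(self) -> int:
        return (self.conv_time_len() - self.pool_kernel) // self.pool_stride + 1

    def replace(self, **kw) -> "ModelConfig":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)


class ChannelAttention(Module):
    """CBAM channel gate: shared 2-layer MLP over pooled descriptors."""

    def __init__(self, n_maps: int, ratio: int, rng=None, dtype=np.float64):
        hidden = n_maps // ratio
        if hidden < 1:
            raise ConfigurationError(
                f"cbam_ratio={ratio} gives hidden width 0 for {n_maps} maps"
            )
        self.fc0 = Linear(n_maps, hidden, bias=True, rng=rng, dtype=dtype)
        self.fc1 = Linear(hidden, n_maps, bias=True, rng=rng, dtype=dtype)

    def _mlp(self, v: nn.Tensor) -> nn.Tensor:
        return self.fc1(nn.relu(self.fc0(v)))

    def __call__(self, f: nn.Tensor) -> nn.Tensor:
        """f: [B, F, H, W] → gate [B, F] in (0, 1)."""
        avg = nn.mean(f, axis=(2, 3))
        mx = nn.amax(f, axis=(2, 3))
        return nn.sigmoid(nn.add(self._mlp(avg), self._mlp(mx)))


class SpatialAttention(Module):
    """CBAM spatial gate: 7×7 same-padded conv over [avg; max] descriptors."""

    def __init__(self, kernel: int = 7, rng=None, dtype=np.float64):
        pad = kernel // 2
        self.conv = Conv2d(1, 2, kernel, kernel, bias=True,
                           padding=(pad, pad), rng=rng, dtype=dtype)

    def __call__(self, f: nn.Tensor) -> nn.Tensor:
        """f: [B, F, H, W] → gate [B, 1, H, W] in (0, 1)."""
        avg = nn.mean(f, axis=1, keepdims=True)
        mx = nn.amax(f, axis=1, keepdims=True)
        return nn.sigmoid(self.conv(nn.concat([avg, mx], axis=1)))


class CBAM(Module):
    """Sequential channel → spatial refinement with a skip connection:
    out = F + Ms(F′) ⊗ F′ where F′ = Mc(F) ⊗ F."""

    def __init__(self, n_maps: int, ratio: int = 16, kernel: int = 7,
                 rng=None, dtype=np.float64):
        self.channel = ChannelAttention(n_maps, ratio, rng=rng, dtype=dtype)
        self.spatial = SpatialAttention(kernel, rng=rng, dtype=dtype)
        self.last_channel_gate: np.ndarray | None = None
        self.last_spatial_gate: np.ndarray | None = None

    def refined(self, f: nn.Tensor, keep_gates: bool = False) -> nn.Tensor:
        """F″ = Ms(F′) ⊗ F′ without the skip connection."""
        mc = self.channel(f)
        B, F = mc.shape
        f_prime = nn.mul(f, nn.reshape(mc, (B, F, 1, 1)))
        ms = self.spatial(f_prime)
        if keep_gates:
            self.last_channel_gate = mc.data.copy()
            self.last_spatial_gate = ms.data.copy()
        return nn.mul(f_prime, ms)

    def __call__(self, f: nn.Tensor, keep_gates: bool = False) -> nn.Tensor:
        return nn.add(f, self.refined(f, keep_gates=keep_gates))


class MACNet(Module):
    """The assembled network; see module docstring for the layer chain."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator | None = None,
                 dtype=np.float64):
        cfg.validate()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        self.dtype = dtype
        self.rng = np.random.default_rng(0)  # dropout stream; reset by train()
        self.training = False
        self._warned_negative_log = False

        self.temporal_attn = (
            TemporalSelfAttention(cfg.C, cfg.value_projection, rng=rng, dtype=dtype)
            if cfg.branch >= 1 else None
        )
        self.temporal_conv = (
            Conv2d(cfg.n_temporal_filters, 1, 1, cfg.temporal_kernel,
                   bias=True, rng=rng, dtype=dtype)
            if cfg.use_temporal_conv else None
        )
        n_maps = cfg.n_temporal_filters if cfg.use_temporal_conv else 1
        self.cbam = (
            CBAM(n_maps, cfg.cbam_ratio, cfg.spatial_attention_kernel,
                 rng=rng, dtype=dtype)
            if cfg.branch == 2 else None
        )
        self.spatial_conv = (
            Conv2d(cfg.n_spatial_filters, n_maps, cfg.C, 1,
                   bias=True, rng=rng, dtype=dtype)
            if cfg.use_spatial_conv else None
        )
        n_out_maps = cfg.n_spatial_filters if cfg.use_spatial_conv else n_maps
        self.bn = BatchNorm2d(n_out_maps, affine=cfg.bn_affine, dtype=dtype)
        # the classifier kernel consumes the whole remaining map; with the
        # default geometry that is (1, 11) exactly
        kh = 1 if cfg.use_spatial_conv else cfg.C
        self.classifier = Conv2d(cfg.n_classes, n_out_maps, kh,
                                 cfg.pooled_len(), bias=True, rng=rng,
                                 dtype=dtype)

    # -- mode switches ----------------------------------------------------
    def train_mode(self, flag: bool = True) -> "MACNet":
        self.training = flag
        return self

    def eval_mode(self) -> "MACNet":
        return self.train_mode(False)

    # -- forward ----------------------------------------------------------
    def features(self, x: nn.Tensor, keep_attention: bool = False) -> nn.Tensor:
        """Everything up to (and including) the safe log: [B, Fₙ, ·, P]."""
        cfg = self.cfg
        if self.temporal_attn is not None:
            x = self.temporal_attn(x, keep_attention=keep_attention)
        if self.temporal_conv is not None:
            x = self.temporal_conv(x)
        if self.cbam is not None:
            x = self.cbam(x, keep_gates=keep_attention)
        if self.spatial_conv is not None:
            x = self.spatial_conv(x)
        x = self.bn(x, training=self.training)
        if cfg.square_before_pool:
            x = nn.square(x)
        x = nn.avg_pool2d(x, (1, cfg.pool_kernel), (1, cfg.pool_stride))
        if not cfg.square_before_pool and not self._warned_negative_log:
            if np.any(x.data <= cfg.safe_log_eps):
                logger.warning(
                    "safe log clamping non-positive pooled values to eps=%g "
                    "(square_before_pool is off)", cfg.safe_log_eps,
                )
                self._warned_negative_log = True
        if cfg.dropout_before_log:
            # literal reading of the published layer listing: dropped pooled
            # values hit the log clamp and become log(eps) outliers
            x = nn.dropout(x, cfg.dropout_p, self.rng, training=self.training)
            return nn.safe_log(x, eps=cfg.safe_log_eps)
        x = nn.safe_log(x, eps=cfg.safe_log_eps)
        return nn.dropout(x, cfg.dropout_p, self.rng, training=self.training)

    def __call__(self, x: nn.Tensor, keep_attention: bool = False) -> nn.Tensor:
        """x: [B, 1, C, T] → logits [B, n_classes]."""
        feats = self.features(x, keep_attention=keep_attention)
        logits = self.classifier(feats)
        B = logits.shape[0]
        return nn.reshape(logits, (B, self.cfg.n_classes))

    # -- inference conveniences -------------------------------------------
    def predict_logits(self, data: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """data: [N, C, T] ndarray → logits [N, n_classes] (eval mode)."""
        was_training = self.training
        self.eval_mode()
        outs = []
        for i in range(0, data.shape[0], batch_size):
            chunk = np.asarray(data[i:i + batch_size], dtype=self.dtype)
            outs.append(self(nn.Tensor(chunk[:, None])).data)
        self.training = was_training
        return np.concatenate(outs, axis=0)

    def predict_proba(self, data: np.ndarray, batch_size: int = 64) -> np.ndarray:
        return softmax_probs(self.predict_logits(data, batch_size))

    def predict(self, data: np.ndarray, batch_size: int = 64) -> np.ndarray:
        return self.predict_logits(data, batch_size).argmax(axis=1)


@dataclass
class AttentionState:
    """Interpretability record for one sample's pass through the network."""

    temporal: np.ndarray | None       # [T × T] attention weights
    channel_gate: np.ndarray | None   # [Fₙ] channel attention
    spatial_gate: np.ndarray | None   # [1 × H × W] spatial attention map


def attention_state(model: MACNet, sample: np.ndarray) -> AttentionState:
    """Run one [C × T] sample and export all attention maps (eval mode)."""
    was_training = model.training
    model.eval_mode()
    x = nn.Tensor(np.asarray(sample, dtype=model.dtype)[None, None])
    model(x, keep_attention=True)
    model.training = was_training
    return AttentionState(
        temporal=(model.temporal_attn.last_attention[0]
                  if model.temporal_attn is not None else None),
        channel_gate=(model.cbam.last_channel_gate[0]
                      if model.cbam is not None else None),
        spatial_gate=(model.cbam.last_spatial_gate[0]
                      if model.cbam is not None else None),
    )


def softmax_probs(logits: np.ndarray) -> np.ndarray:
    """Class probabilities P_i = exp(z_i)/Σ_j exp(z_j) along the last axis."""
    z = np.asarray(logits, dtype=np.float64)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> float:
    """Mean categorical cross-entropy of integer labels."""
    p = softmax_probs(logits)
    n = p.shape[0]
    return float(-np.log(p[np.arange(n), np.asarray(labels)]).mean())


def build_model(cfg: ModelConfig, seed: int = 0, dtype=np.float32) -> MACNet:
    """Instantiate a seeded model (float32 by default for training speed)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x10DE]))
    return MACNet(cfg, rng=rng, dtype=dtype)


def count_parameters(cfg: ModelConfig) -> int:
    """Number of learnable scalars for a configuration."""
    return MACNet(cfg, rng=np.random.default_rng(0), dtype=np.float32).n_parameters()
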