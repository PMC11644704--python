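"""Temporal refining: single-head self-attention over time points.

Each 61 × 250 sample is treated as a sequence of T = 250 tokens whose
embedding is the C = 61 electrode vector.  Bias-free projections
Q = XᵀW_Qᵀ, K = XᵀW_Kᵀ (and by default V = XᵀW_Vᵀ) feed scaled dot-product
attention A = rowsoftmax(QKᵀ/√d) with d = C, and the refined signal is added
back residually: X̃ = X + (AV)ᵀ.

There is no positional encoding: permutation equivariance over time is
broken only through the data-dependent attention matrix A.

With ``value_projection=False`` the value path is the identity (V = Xᵀ),
the literal textual variant; the learnable W_V default matches the model's
published parameter budget.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from macnet import nn
from macnet.layers import Module, glorot_uniform


@dataclass
class RefinedSample:
    """Interpretability record for one sample's temporal refinement."""

    X: np.ndarray        # input [C × T]
    X_hat: np.ndarray    # attention output [C × T]
    X_tilde: np.ndarray  # residual sum X + X_hat
    A: np.ndarray        # attention weights [T × T], rows sum to 1


class TemporalSelfAttention(Module):
    """Single-head temporal self-attention with residual connection."""

    def __init__(self, n_channels: int, value_projection: bool = True,
                 rng: np.random.Generator | None = None, dtype=np.float64):
        rng = rng or np.random.default_rng(0)
        C = n_channels
        self.n_channels = C
        self.d = C  # key length = embedding dim = number of electrodes
        self.W_Q = nn.Parameter(glorot_uniform(rng, (C, C), C, C, dtype))
        self.W_K = nn.Parameter(glorot_uniform(rng, (C, C), C, C, dtype))
        self.W_V = (
            nn.Parameter(glorot_uniform(rng, (C, C), C, C, dtype))
            if value_projection else None
        )
        self.last_attention: np.ndarray | None = None

    def __call__(self, x: nn.Tensor, keep_attention: bool = False) -> nn.Tensor:
        """x: [B, 1, C, T] → X̃ = X + X̂ with the same shape."""
        B, _, C, T = x.shape
        xs = nn.reshape(x, (B, C, T))
        xt = nn.transpose(xs, (0, 2, 1))              # tokens × embedding
        q = nn.matmul(xt, nn.transpose(self.W_Q, (1, 0)))
        k = nn.matmul(xt, nn.transpose(self.W_K, (1, 0)))
        v = xt if self.W_V is None else nn.matmul(xt, nn.transpose(self.W_V, (1, 0)))
        scores = nn.mul(nn.matmul(q, nn.transpose(k, (0, 2, 1))),
                        1.0 / np.sqrt(self.d))
        a = nn.softmax(scores, axis=-1)               # [B, T, T]
        if keep_attention:
            self.last_attention = a.data.copy()
        x_hat = nn.transpose(nn.matmul(a, v), (0, 2, 1))
        return nn.add(x, nn.reshape(x_hat, (B, 1, C, T)))

    def refine(self, X: np.ndarray) -> RefinedSample:
        """Run one [C × T] sample and export all intermediate arrays."""
        X = np.asarray(X, dtype=np.float64)
        if not np.all(np.isfinite(X)):
            raise FloatingPointError("temporal attention input is not finite")
        C, T = X.shape
        if C != self.n_channels:
            raise ValueError(
                f"input has {C} channels; attention built for {self.n_channels}"
            )
        out = self(nn.Tensor(X[None, None]), keep_attention=True)
        x_tilde = out.data[0, 0]
        return RefinedSample(
            X=X,
            X_hat=x_tilde - X,
            X_tilde=x_tilde,
            A=self.last_attention[0],
        )


def temporal_attention(X: np.ndarray, W_Q: np.ndarray, W_K: np.ndarray,
                       W_V: np.ndarray | None = None) -> RefinedSample:
    """Functional form: refine one [C × T] sample with given weights."""
    C = X.shape[0]
    layer = TemporalSelfAttention(C, value_projection=W_V is not None)
    layer.W_Q.data[...] = W_Q
    layer.W_K.data[...] = W_K
    if W_V is not None:
        layer.W_V.data[...] = W_V
    return layer.refine(X)
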