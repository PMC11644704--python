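"""Light layer abstractions over the autodiff engine."""

from __future__ import annotations

import numpy as np

from macnet import nn


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int,
                   dtype=np.float64) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Module:
    """Base class: parameter discovery by attribute recursion."""

    def parameters(self) -> list[nn.Parameter]:
        params: list[nn.Parameter] = []
        for value in vars(self).values():
            if isinstance(value, nn.Parameter):
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
    # buffers (running stats) live as plain ndarrays and are not returned
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name → array map of parameters and buffers (for checkpoints)."""
        out: dict[str, np.ndarray] = {}

        def visit(obj: "Module", prefix: str):
            for name, value in vars(obj).items():
                key = f"{prefix}{name}"
                if isinstance(value, nn.Parameter):
                    out[key] = value.data
                elif isinstance(value, np.ndarray):
                    out[key] = value
                elif isinstance(value, Module):
                    visit(value, key + ".")
                elif isinstance(value, (list, tuple)):
                    for i, item in enumerate(value):
                        if isinstance(item, Module):
                            visit(item, f"{key}.{i}.")

        visit(self, "")
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        own = self.state_arrays()
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"checkpoint missing arrays: {sorted(missing)}")
        for key, arr in own.items():
            arr[...] = state[key]


class Conv2d(Module):
    """Stride-1 2-D convolution layer (optionally zero-padded)."""

    def __init__(self, out_channels: int, in_channels: int, kh: int, kw: int,
                 bias: bool = True, padding: tuple[int, int] = (0, 0),
                 rng: np.random.Generator | None = None, dtype=np.float64):
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kh * kw
        fan_out = out_channels * kh * kw
        self.weight = nn.Parameter(
            glorot_uniform(rng, (out_channels, in_channels, kh, kw),
                           fan_in, fan_out, dtype)
        )
        self.bias = nn.Parameter(np.zeros(out_channels, dtype=dtype)) if bias else None
        self.padding = padding

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        return nn.conv2d(x, self.weight, self.bias, padding=self.padding)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None, dtype=np.float64):
        rng = rng or np.random.default_rng(0)
        self.weight = nn.Parameter(
            glorot_uniform(rng, (in_features, out_features),
                           in_features, out_features, dtype)
        )
        self.bias = nn.Parameter(np.zeros(out_features, dtype=dtype)) if bias else None

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        out = nn.matmul(x, self.weight)
        if self.bias is not None:
            out = nn.add(out, self.bias)
        return out


class BatchNorm2d(Module):
    """Batch normalization over (B, H, W) per feature map.

    Affine-free by default; with ``affine=True`` a learnable per-map scale
    and shift are applied after standardization.
    """

    def __init__(self, num_features: int, affine: bool = False,
                 momentum: float = 0.1, eps: float = 1e-5, dtype=np.float64):
        self.running_mean = np.zeros(num_features, dtype=dtype)
        self.running_var = np.ones(num_features, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        if affine:
            self.gamma = nn.Parameter(np.ones(num_features, dtype=dtype))
            self.beta = nn.Parameter(np.zeros(num_features, dtype=dtype))
        else:
            self.gamma = None
            self.beta = None

    def __call__(self, x: nn.Tensor, training: bool) -> nn.Tensor:
        y = nn.batch_norm(x, self.running_mean, self.running_var,
                          training=training, momentum=self.momentum,
                          eps=self.eps)
        if self.gamma is not None:
            g = nn.reshape(self.gamma, (1, -1, 1, 1))
            b = nn.reshape(self.beta, (1, -1, 1, 1))
            y = nn.add(nn.mul(y, g), b)
        return y
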