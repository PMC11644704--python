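"""Training loop and cross-validation protocols.

Adam with a cosine-annealed learning rate (period = the full run, no
restarts), mini-batches of 64, cross-entropy loss, and an exponential
moving average (EMA) shadow copy of all parameters updated every step;
evaluation uses the EMA weights.  Data are partitioned for tenfold
cross-validation at the trial level by default, so all five windows cut
from one trial land in the same fold (sample-level splitting is available
but leaks near-duplicate windows across folds).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from macnet import nn
from macnet.errors import ConfigurationError, TrainingDivergenceError
from macnet.metrics import EvalReport, accuracy, cohens_kappa, confusion
from macnet.model import MACNet
from macnet.preprocess import SampleSet


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-4
    batch_size: int = 64
    epochs: int = 300
    ema_decay: float = 0.999
    seed: int = 0
    split_mode: str = "trial"        # "trial" or "sample"
    n_folds: int = 10
    shuffle: bool = True

    def validate(self) -> None:
        if self.lr <= 0:
            raise ConfigurationError("lr must be positive")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if not 0.0 <= self.ema_decay < 1.0:
            raise ConfigurationError("ema_decay must be in [0, 1)")
        if self.split_mode not in ("trial", "sample"):
            raise ConfigurationError(f"split_mode {self.split_mode!r} unknown")
        if self.epochs < 1 or self.n_folds < 2:
            raise ConfigurationError("epochs >= 1 and n_folds >= 2 required")

    def replace(self, **kw) -> "TrainConfig":
        return replace(self, **kw)


class Adam:
    """Adam optimizer over a parameter list (β1=0.9, β2=0.999, ε=1e-8)."""

    def __init__(self, params: list[nn.Parameter], lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if g is None:
                continue
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def cosine_lr(base_lr: float, epoch: int, total_epochs: int) -> float:
    """Cosine annealing from base_lr to 0 over the whole run."""
    return float(base_lr * 0.5 * (1.0 + np.cos(np.pi * epoch / total_epochs)))


class EMA:
    """Exponential moving average shadow of the parameters.

    The effective decay is warmed up as min(decay, (1+t)/(10+t)) so the
    shadow tracks the learner early in training instead of the random
    initialization; on long runs it converges to the configured decay.
    """

    def __init__(self, params: list[nn.Parameter], decay: float):
        self.decay = decay
        self.t = 0
        self.shadow = [p.data.copy() for p in params]

    def update(self, params: list[nn.Parameter]) -> None:
        self.t += 1
        d = min(self.decay, (1.0 + self.t) / (10.0 + self.t))
        for s, p in zip(self.shadow, params):
            s *= d
            s += (1.0 - d) * p.data

    def swap_in(self, params: list[nn.Parameter]) -> list[np.ndarray]:
        """Install EMA weights; returns the raw weights for swap_out."""
        raw = [p.data.copy() for p in params]
        for p, s in zip(params, self.shadow):
            p.data[...] = s
        return raw

    @staticmethod
    def swap_out(params: list[nn.Parameter], raw: list[np.ndarray]) -> None:
        for p, r in zip(params, raw):
            p.data[...] = r


@dataclass
class TrainResult:
    model: MACNet
    ema: EMA
    history: list[float]             # per-epoch mean training loss

    def predict(self, data: np.ndarray, use_ema: bool = True,
                batch_size: int = 64) -> np.ndarray:
        params = self.model.parameters()
        if use_ema:
            raw = self.ema.swap_in(params)
            try:
                return self.model.predict(data, batch_size)
            finally:
                EMA.swap_out(params, raw)
        return self.model.predict(data, batch_size)


def train(model: MACNet, samples: SampleSet, cfg: TrainConfig,
          indices: np.ndarray | None = None) -> TrainResult:
    """Train in place on (a subset of) a SampleSet; returns loss history
    and the EMA shadow used for evaluation."""
    cfg.validate()
    if indices is None:
        indices = np.arange(len(samples))
    X = np.asarray(samples.data[indices], dtype=model.dtype)
    y = np.asarray(samples.labels[indices])
    if y.min() < 0 or y.max() >= model.cfg.n_classes:
        raise ConfigurationError("labels outside [0, n_classes)")

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x7EA1]))
    model.rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xD207]))
    model.train_mode()
    params = model.parameters()
    opt = Adam(params, cfg.lr)
    ema = EMA(params, cfg.ema_decay)

    n = X.shape[0]
    history: list[float] = []
    for epoch in range(cfg.epochs):
        opt.lr = cosine_lr(cfg.lr, epoch, cfg.epochs)
        order = rng.permutation(n) if cfg.shuffle else np.arange(n)
        losses = []
        for i in range(0, n, cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            xb = nn.Tensor(X[idx][:, None])
            loss = nn.cross_entropy_with_logits(model(xb), y[idx])
            if not np.isfinite(loss.data):
                raise TrainingDivergenceError(epoch)
            opt.zero_grad()
            nn.backward(loss)
            opt.step()
            ema.update(params)
            losses.append(float(loss.data))
        history.append(float(np.mean(losses)))
    model.eval_mode()
    return TrainResult(model=model, ema=ema, history=history)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def make_folds(samples: SampleSet, n_folds: int, seed: int,
               split_mode: str = "trial") -> list[np.ndarray]:
    """Seeded random partition into n_folds groups of sample indices.

    In trial mode the partition is over unique lineage (session, trial)
    pairs, so sliding windows of one trial never straddle folds.
    """
    if split_mode == "sample":
        order = np.random.default_rng(
            np.random.SeedSequence([seed, 0xF01D])
        ).permutation(len(samples))
        return [np.sort(part) for part in np.array_split(order, n_folds)]
    keys = np.stack([samples.lineage["session"], samples.lineage["trial"]], axis=1)
    uniq, inverse = np.unique(keys, axis=0, return_inverse=True)
    order = np.random.default_rng(
        np.random.SeedSequence([seed, 0xF01D])
    ).permutation(len(uniq))
    folds = []
    for part in np.array_split(order, n_folds):
        mask = np.isin(inverse, part)
        folds.append(np.flatnonzero(mask))
    return folds


def _fit_eval_fold(model_factory, samples: SampleSet, cfg: TrainConfig,
                   test_idx: np.ndarray, fold: int):
    all_idx = np.arange(len(samples))
    train_idx = np.setdiff1d(all_idx, test_idx)
    n_classes = len(samples.classes) or int(samples.labels.max()) + 1
    present = np.unique(samples.labels[train_idx])
    if len(present) < n_classes:
        warnings.warn(
            f"fold {fold}: classes {sorted(set(range(n_classes)) - set(present))} "
            "absent from the training split", RuntimeWarning,
        )
    model = model_factory(fold)
    result = train(model, samples, cfg, indices=train_idx)
    y_pred = result.predict(samples.data[test_idx], use_ema=True)
    y_true = samples.labels[test_idx]
    cm = confusion(y_true, y_pred, n_classes=n_classes)
    return accuracy(y_true, y_pred), cohens_kappa(cm), cm, result


def tenfold_cv(model_factory, samples: SampleSet, cfg: TrainConfig,
               n_folds: int | None = None) -> EvalReport:
    """k-fold cross-validation (default tenfold): per-fold ACC%/kappa and a
    confusion matrix summed over the test folds.

    model_factory(fold_index) must return a fresh model per fold.
    """
    cfg.validate()
    n_folds = n_folds or cfg.n_folds
    folds = make_folds(samples, n_folds, cfg.seed, cfg.split_mode)
    per_fold, cms = [], []
    for fold, test_idx in enumerate(folds):
        acc, kappa, cm, _ = _fit_eval_fold(model_factory, samples, cfg,
                                           test_idx, fold)
        per_fold.append((acc, kappa))
        cms.append(cm)
    return EvalReport(
        per_fold=per_fold,
        confusion=np.sum(cms, axis=0),
        class_names=tuple(samples.classes),
        extra={"n_folds": n_folds, "split_mode": cfg.split_mode},
    )


def holdout_eval(model_factory, samples: SampleSet, cfg: TrainConfig,
                 n_folds: int | None = None) -> EvalReport:
    """Hold out one seeded random fold (1/k of the data) as the test set."""
    cfg.validate()
    n_folds = n_folds or cfg.n_folds
    folds = make_folds(samples, n_folds, cfg.seed, cfg.split_mode)
    pick = int(np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 0x401D])
    ).integers(n_folds))
    acc, kappa, cm, _ = _fit_eval_fold(model_factory, samples, cfg,
                                       folds[pick], pick)
    return EvalReport(
        per_fold=[(acc, kappa)],
        confusion=cm,
        class_names=tuple(samples.classes),
        extra={"held_out_fold": pick, "n_folds": n_folds,
               "split_mode": cfg.split_mode},
    )
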