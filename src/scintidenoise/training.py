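"""Hybrid MSE+SSIM loss and the mini-batch Adam training loop.

The training objective is

    L_total = lambda * L_MSE + (1 - lambda) * (1 - SSIM(X_output, X_target))

computed on the normalized [0, 1] scale (data range 1). Both terms are
differentiated through the autodiff graph; the SSIM term uses the same
Gaussian-window formulation as the evaluation metrics (11 taps,
sigma 1.5), so the loss and the reported metric agree to numerical
precision.

Early stopping is defined in validation evaluations: the validation loss
is measured before the first update (baseline) and every
``validate_every`` iterations thereafter; training halts after
``patience`` consecutive evaluations without strict improvement over the
best, or at ``max_iterations`` mini-batch updates, whichever comes first.
The returned parameters are the best-validation snapshot, not the last.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .dataio import DosePair, NormalizedImage, make_batches
from .errors import ConfigurationError, ShapeError
from .metrics import NORMALIZED, MetricConfig
from .model import ModelConfig, ModelParameters, forward_batch
from .nn import Tensor


@dataclass(frozen=True)
class TrainingConfig:
    loss_weight: float = 0.7      # lambda: MSE weight; 1-lambda on SSIM term
    learning_rate: float = 1e-3
    batch_size: int = 16
    max_iterations: int = 2000
    patience: int = 50
    validate_every: int = 1
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.loss_weight <= 1.0:
            raise ConfigurationError("loss_weight must be in [0, 1]")
        if self.patience < 1:
            raise ConfigurationError("patience must be >= 1")
        if self.max_iterations < 1:
            raise ConfigurationError("max_iterations must be >= 1")
        if self.validate_every < 1:
            raise ConfigurationError("validate_every must be >= 1")


@dataclass
class LossBreakdown:
    total: float
    mse_term: float
    ssim_term: float      # 1 - SSIM, in [0, 2]


@dataclass
class IterationRecord:
    iteration: int
    train_loss: LossBreakdown
    val_loss: float | None = None


@dataclass
class TrainingHistory:
    records: list[IterationRecord] = field(default_factory=list)
    stop_reason: str = ""             # "max_iterations" | "early_stop"
    best_iteration: int = 0
    best_val_loss: float = float("inf")
    baseline_val_loss: float | None = None
    excluded_log: list = field(default_factory=list)


# --------------------------------------------------------------------------
# differentiable loss

def _ssim_tensor(out: Tensor, tgt: Tensor, cfg: MetricConfig) -> Tensor:
    """Mean Gaussian-window SSIM of (N,1,H,W) tensors, differentiable."""
    pad = (cfg.ssim_window - 1) // 2
    if out.shape[2] < cfg.ssim_window or out.shape[3] < cfg.ssim_window:
        raise ShapeError(f"images {out.shape[2]}x{out.shape[3]} smaller than "
                         f"SSIM window {cfg.ssim_window}")
    kernel = nn.gaussian_kernel1d(cfg.ssim_sigma, pad)

    def blur(t):
        return nn.separable_blur_valid(t, kernel)

    ux, uy = blur(out), blur(tgt)
    uxx, uyy, uxy = blur(out * out), blur(tgt * tgt), blur(out * tgt)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    vxy = uxy - ux * uy
    num = (2.0 * ux * uy + cfg.c1) * (2.0 * vxy + cfg.c2)
    den = (ux * ux + uy * uy + cfg.c1) * (vx + vy + cfg.c2)
    return (num / den).mean()


def loss_tensor(out: Tensor, tgt: Tensor, lam: float,
                cfg: MetricConfig = NORMALIZED) -> tuple[Tensor, LossBreakdown]:
    """Total-loss graph node plus the detached per-term breakdown."""
    if out.shape != tgt.shape:
        raise ShapeError(f"output shape {out.shape} != target shape {tgt.shape}")
    diff = out - tgt
    mse_t = (diff * diff).mean()
    ssim_t = _ssim_tensor(out, tgt, cfg)
    total = lam * mse_t + (1.0 - lam) * (1.0 - ssim_t)
    breakdown = LossBreakdown(total=float(total.data),
                              mse_term=float(mse_t.data),
                              ssim_term=float(1.0 - ssim_t.data))
    return total, breakdown


def hybrid_loss(output: NormalizedImage | np.ndarray,
                target: NormalizedImage | np.ndarray,
                lam: float = 0.7) -> LossBreakdown:
    """Hybrid loss of a single image pair on the normalized scale."""
    ov = output.values if isinstance(output, NormalizedImage) else np.asarray(output)
    tv = target.values if isinstance(target, NormalizedImage) else np.asarray(target)
    if ov.shape != tv.shape:
        raise ShapeError(f"output shape {ov.shape} != target shape {tv.shape}")
    with nn.no_grad():
        _, breakdown = loss_tensor(Tensor(ov[None, None]),
                                   Tensor(tv[None, None]), lam)
    return breakdown


# --------------------------------------------------------------------------
# training loop

def _stack(pairs: list[DosePair]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([p.low.values for p in pairs])[:, None, :, :]
    y = np.stack([p.full.values for p in pairs])[:, None, :, :]
    return x, y


def _mean_loss(params: ModelParameters, x: np.ndarray, y: np.ndarray,
               lam: float, batch_size: int) -> float:
    """Pair-weighted mean hybrid loss over a dataset (no gradients)."""
    total, n = 0.0, x.shape[0]
    with nn.no_grad():
        for i in range(0, n, batch_size):
            xb, yb = x[i:i + batch_size], y[i:i + batch_size]
            out = forward_batch(params, Tensor(xb))
            _, br = loss_tensor(out, Tensor(yb), lam)
            total += br.total * xb.shape[0]
    return total / n


def train(params: ModelParameters, model_config: ModelConfig,
          train_pairs: list[DosePair], val_pairs: list[DosePair],
          config: TrainingConfig,
          log_every: int | None = None) -> tuple[ModelParameters, TrainingHistory]:
    """Mini-batch Adam on the hybrid loss with validation-based early stopping."""
    if not train_pairs:
        raise ConfigurationError("training set is empty")
    if not val_pairs:
        raise ConfigurationError(
            "validation set is empty but early stopping (finite patience) "
            "requires validation evaluations")
    if model_config != params.config:
        raise ConfigurationError("model_config does not match parameters")

    x_tr, y_tr = _stack(train_pairs)
    x_va, y_va = _stack(val_pairs)
    lam = config.loss_weight
    opt = nn.Adam(params.tensors, lr=config.learning_rate)

    def epoch_seed(e: int) -> int:
        return int(np.random.SeedSequence([config.seed, e]).generate_state(1)[0]
                   % (2 ** 31))

    history = TrainingHistory()
    baseline = _mean_loss(params, x_va, y_va, lam, config.batch_size)
    history.baseline_val_loss = baseline
    best_val = baseline
    best_iter = 0
    best_blobs = params.copy_data()
    bad_evals = 0

    it = 0
    epoch = 0
    stop = None
    indices = list(range(len(train_pairs)))
    while stop is None:
        plan = make_batches(indices, min(config.batch_size, len(indices)),
                            seed=epoch_seed(epoch))
        if plan.excluded:
            history.excluded_log.append(
                {"epoch": epoch, "excluded": list(plan.excluded)})
        for batch in plan.batches:
            it += 1
            xb, yb = x_tr[batch], y_tr[batch]
            out = forward_batch(params, Tensor(xb))
            total, breakdown = loss_tensor(out, Tensor(yb), lam)
            opt.zero_grad()
            total.backward()
            opt.step()
            rec = IterationRecord(iteration=it, train_loss=breakdown)

            if it % config.validate_every == 0:
                val = _mean_loss(params, x_va, y_va, lam, config.batch_size)
                rec.val_loss = val
                if val < best_val:
                    best_val, best_iter, bad_evals = val, it, 0
                    best_blobs = params.copy_data()
                else:
                    bad_evals += 1
            history.records.append(rec)
            if log_every and it % log_every == 0:
                print(f"iter {it:5d}  train {breakdown.total:.5f}  "
                      f"val {rec.val_loss if rec.val_loss is not None else '-'}"
                      f"  patience {bad_evals}/{config.patience}")
            if bad_evals >= config.patience:
                stop = "early_stop"
                break
            if it >= config.max_iterations:
                stop = "max_iterations"
                break
        epoch += 1

    history.stop_reason = stop
    history.best_iteration = best_iter
    history.best_val_loss = best_val
    params.load_data(best_blobs)
    return params, history


def denoise(params: ModelParameters, model_config: ModelConfig,
            images: list[NormalizedImage],
            batch_size: int = 4) -> list[NormalizedImage]:
    """Batched inference; order preserved, outputs clipped into [0, 1]."""
    if model_config != params.config:
        raise ConfigurationError("model_config does not match parameters")
    outputs: list[NormalizedImage] = []
    i = 0
    while i < len(images):
        # batch together consecutive images of identical size
        j = i + 1
        while (j < len(images) and j - i < batch_size
               and images[j].shape == images[i].shape):
            j += 1
        xb = np.stack([im.values for im in images[i:j]])[:, None]
        with nn.no_grad():
            out = forward_batch(params, Tensor(xb))
        for k, im in enumerate(images[i:j]):
            outputs.append(NormalizedImage(
                np.clip(out.data[k, 0], 0.0, 1.0),
                dose_fraction=im.dose_fraction))
        i = j
    return outputs
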