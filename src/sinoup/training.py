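"""Network optimization: MSE loss, Adam with two learning-rate groups, the
iteration/validation cadence, snapshotting, and plateau-driven decay.

Training follows a balanced sampling discipline: one *iteration* draws one
random patch from every training sinogram (shuffled order), patches are fed
in minibatches of ten, and validation runs every 16 iterations on a frozen
set of ten random patches per validation sinogram.  The last layer is a
pure linear combination of feature maps and is error-sensitive, so it gets
its own, ten-times-smaller learning rate (0.001 vs 0.01 for the first two
layers).  When the validation loss stops improving for ``patience``
consecutive validations both rates are divided by ten; training stops after
``max_decays`` decays or ``max_iterations`` iterations, and the
best-validation snapshot is returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import model, sampling
from .model import UDNNConfig, UDNNParams


def mse_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean square error over all pixels of the predicted intermediate rows."""
    pred = np.asarray(pred)
    target = np.asarray(target)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    diff = pred.astype(np.float64) - target.astype(np.float64)
    return float(np.mean(diff * diff))


@dataclass
class TrainSchedule:
    """Optimization hyperparameters (defaults follow the training recipe)."""

    lr_first_two: float = 0.01
    lr_last: float = 0.001
    minibatch: int = 10
    validate_every: int = 16          # iterations between validations
    patience: int = 3                 # validations without improvement before decay
    lr_decay: float = 10.0
    max_decays: int = 3
    max_iterations: int = 400
    val_patches_per_sinogram: int = 10
    normalize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr_first_two <= 0 or self.lr_last <= 0:
            raise ValueError("learning rates must be positive")
        if self.minibatch < 1:
            raise ValueError("minibatch must be at least 1")


@dataclass
class ValidationRecord:
    iteration: int
    step: int
    train_loss: float
    val_loss: float
    val_psnr: float
    lr_first_two: float
    lr_last: float
    is_best: bool


@dataclass
class TrainHistory:
    records: list[ValidationRecord] = field(default_factory=list)

    @property
    def best(self) -> ValidationRecord:
        return min(self.records, key=lambda r: r.val_loss)


class Adam:
    """Adaptive moment estimation with per-parameter learning-rate groups.

    β₁=0.9, β₂=0.999, ε=1e−8 (the method's defaults); ``lr_of`` maps a
    parameter name to its current learning rate so the two-group policy is
    a lookup, not a separate optimizer.
    """

    def __init__(self, params: dict[str, np.ndarray], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1.0e-8) -> None:
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray],
             lr_of) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for k, p in params.items():
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            m_hat = self.m[k] / b1c
            v_hat = self.v[k] / b2c
            p -= (lr_of(k) * m_hat / (np.sqrt(v_hat) + self.eps)).astype(p.dtype)


def _normalize_batch(x: np.ndarray):
    """Vectorized per-patch min–max normalization over a ``(B, …)`` batch."""
    axes = tuple(range(1, x.ndim))
    lo = x.min(axis=axes, keepdims=True)
    hi = x.max(axis=axes, keepdims=True)
    scale = hi - lo
    degenerate = scale <= 1.0e-12
    safe = np.where(degenerate, 1.0, scale)
    xn = np.where(degenerate, 0.0, (x - lo) / safe)
    return xn.astype(np.float32), lo.astype(np.float32), safe.astype(np.float32)


def build_validation_set(val_sinograms: list[np.ndarray], config: UDNNConfig,
                         gap: int, rng: np.random.Generator,
                         patches_per_sinogram: int = 10):
    """Freeze the validation patch set: k seeded random patches per sinogram."""
    inputs, targets = [], []
    for s in val_sinograms:
        starts = sampling.training_patch_starts(s.shape[0], gap, config.in_rows)
        for st in rng.choice(starts, size=patches_per_sinogram, replace=True):
            pair = sampling.patch_at(s, int(st), config.n_out, gap, config.in_rows)
            inputs.append(pair.input)
            targets.append(pair.target)
    return (np.stack(inputs).astype(np.float32),
            np.stack(targets).astype(np.float32))


def validate(params: UDNNParams, config: UDNNConfig, val_inputs: np.ndarray,
             val_targets: np.ndarray, normalize: bool = True,
             peak: float | None = None, batch_size: int = 256,
             psnr_cap: float = 200.0) -> tuple[float, float]:
    """Loss and PSNR of the network on a fixed patch set.

    Outputs are denormalized with their own input's parameters before being
    compared with the raw ground truth.  PSNR is ``10·log₁₀(peak²/loss)``
    with ``peak`` defaulting to the ground truth's data range, capped at
    ``psnr_cap`` dB for (near-)exact predictions.
    """
    preds = predict_patches(params, config, val_inputs, normalize, batch_size)
    loss = mse_loss(preds, val_targets)
    if peak is None:
        peak = float(val_targets.max() - val_targets.min()) or 1.0
    psnr = psnr_cap if loss == 0 else min(psnr_cap, 10.0 * np.log10(peak ** 2 / loss))
    return loss, float(psnr)


def predict_patches(params: UDNNParams, config: UDNNConfig, inputs: np.ndarray,
                    normalize: bool = True, batch_size: int = 256) -> np.ndarray:
    """Denormalized network predictions for a batch of input patches."""
    inputs = np.asarray(inputs, dtype=np.float32)
    if normalize:
        xn, lo, safe = _normalize_batch(inputs)
    else:
        xn = inputs
        lo = np.zeros((inputs.shape[0], 1, 1), dtype=np.float32)
        safe = np.ones_like(lo)
    out = np.empty((inputs.shape[0], config.n_out, config.in_rows - 1,
                    inputs.shape[2]), dtype=np.float32)
    for b0 in range(0, inputs.shape[0], batch_size):
        b1 = min(b0 + batch_size, inputs.shape[0])
        out[b0:b1] = model.forward(params, config, xn[b0:b1])
    return out * safe[:, :, None] + lo[:, :, None]


def train(train_sinograms: list[np.ndarray], val_sinograms: list[np.ndarray],
          config: UDNNConfig, schedule: TrainSchedule | None = None,
          gap: int = 40, callback=None) -> tuple[UDNNParams, TrainHistory]:
    """Optimize the network on fully sampled sinograms.

    Returns the best-validation parameter snapshot and the per-validation
    history.  Raises ``FloatingPointError`` on a non-finite training loss
    (after recording the offending state in the history).
    """
    schedule = schedule or TrainSchedule()
    if not train_sinograms or not val_sinograms:
        raise ValueError("at least one training and one validation sinogram required")
    ss = np.random.SeedSequence(schedule.seed)
    train_rng, val_rng, init_seed = ss.spawn(3)
    params = model.init_params(config, seed=int(init_seed.generate_state(1)[0] % (2**31)))
    pdict = params.as_dict()
    adam = Adam(pdict)
    lrs = {"first_two": schedule.lr_first_two, "last": schedule.lr_last}

    def lr_of(name: str) -> float:
        return lrs["last"] if name in ("w3", "b3") else lrs["first_two"]

    val_inputs, val_targets = build_validation_set(
        val_sinograms, config, gap, np.random.default_rng(val_rng),
        schedule.val_patches_per_sinogram)
    val_peak = float(val_targets.max() - val_targets.min()) or 1.0

    history = TrainHistory()
    best_loss = np.inf
    best_params = params.copy()
    decays = 0
    since_best = 0
    step = 0
    losses: list[float] = []

    stream = sampling.iter_training_iterations(
        train_sinograms, np.random.default_rng(train_rng), config.n_out, gap,
        config.in_rows, schedule.minibatch)
    last_iteration = -1
    for iteration, inputs, targets in stream:
        if iteration != last_iteration and last_iteration >= 0:
            completed = last_iteration + 1
            if completed % schedule.validate_every == 0:
                val_loss, val_psnr = validate(params, config, val_inputs,
                                              val_targets, schedule.normalize,
                                              peak=val_peak)
                improved = val_loss < best_loss
                if improved:
                    best_loss = val_loss
                    best_params = params.copy()
                    since_best = 0
                else:
                    since_best += 1
                rec = ValidationRecord(completed, step,
                                       float(np.mean(losses)) if losses else np.nan,
                                       val_loss, val_psnr, lrs["first_two"],
                                       lrs["last"], improved)
                history.records.append(rec)
                losses.clear()
                if callback is not None:
                    callback(rec)
                if since_best >= schedule.patience:
                    decays += 1
                    since_best = 0
                    if decays > schedule.max_decays:
                        break
                    lrs["first_two"] /= schedule.lr_decay
                    lrs["last"] /= schedule.lr_decay
            if completed >= schedule.max_iterations:
                break
        last_iteration = iteration

        if schedule.normalize:
            xn, lo, safe = _normalize_batch(inputs)
            tn = ((targets - lo[:, :, None]) / safe[:, :, None]).astype(np.float32)
        else:
            xn = inputs.astype(np.float32)
            tn = targets.astype(np.float32)
        pred, cache = model.forward(params, config, xn, return_cache=True)
        diff = pred - tn
        loss = float(np.mean(diff.astype(np.float64) ** 2))
        if not np.isfinite(loss):
            history.records.append(ValidationRecord(iteration, step, loss, np.nan,
                                                    np.nan, lrs["first_two"],
                                                    lrs["last"], False))
            raise FloatingPointError(
                f"training loss became non-finite at step {step}")
        losses.append(loss)
        dout = (2.0 / diff.size) * diff
        grads = model.backward(params, config, cache, dout)
        adam.step(pdict, grads, lr_of)
        step += 1

    # final validation if none was recorded (very short schedules)
    if not history.records:
        val_loss, val_psnr = validate(params, config, val_inputs, val_targets,
                                      schedule.normalize, peak=val_peak)
        if val_loss < best_loss:
            best_loss, best_params = val_loss, params.copy()
        history.records.append(ValidationRecord(last_iteration + 1, step,
                                                float(np.mean(losses)) if losses else np.nan,
                                                val_loss, val_psnr,
                                                lrs["first_two"], lrs["last"], True))
    return best_params, history
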