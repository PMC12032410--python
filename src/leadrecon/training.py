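"""Training loops and analytic baselines for lead reconstruction.

Two trainable variants:

* **GAN** — Wasserstein critic with gradient penalty plus an L1
  reconstruction term on the generator (loss weights ``lambda_gp`` and
  ``lambda_l1``; the canonical values 10 and 100 are the defaults), Adam with
  lr 1e-4 and betas (0.5, 0.9), critic updated every batch and generator
  every other batch, gradient-norm clipping on both.
* **U-Net** — the same generator trained alone with mean-squared error and a
  smaller learning rate (5e-5) for stability.

Model selection is by validation reconstruction error; training histories are
fully reproducible given the config seed.

Two analytic baselines frame the regression-to-the-mean analysis:

* the **mean predictor** outputs the per-lead, per-sample training average
  regardless of input — the exact "predict the population mean" extreme;
* the **instantaneous linear map** is the least-squares sample-wise affine map
  from input leads to each output lead, the classical non-deep reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import nn
from .leads import LeadSet, one_lead_set
from .models import Critic, Generator, random_patch


class TrainingError(RuntimeError):
    pass


class TrainingDivergence(TrainingError):
    """Raised when a loss becomes non-finite."""


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-4                  # GAN (both networks)
    lr_unet: float = 5e-5             # pure U-Net, smaller for stability
    betas: tuple = (0.5, 0.9)
    batch_size: int = 32
    epochs: int = 1000
    lambda_gp: float = 10.0
    lambda_l1: float = 100.0
    clip_value: float = 1.0           # global gradient-norm bound
    loss_mode: str = "wgan_gp_l1"     # or "mse"
    seed: int = 0

    def __post_init__(self):
        if self.lr <= 0 or self.lr_unet <= 0:
            raise TrainingError("learning rates must be > 0")
        if self.batch_size < 1:
            raise TrainingError("batch_size must be >= 1")
        if self.lambda_gp < 0 or self.lambda_l1 < 0:
            raise TrainingError("loss weights must be >= 0")


def desk_train_config(epochs: int = 20, batch_size: int = 16,
                      seed: int = 0) -> TrainConfig:
    """CPU-scale preset used throughout the test battery."""
    return TrainConfig(epochs=epochs, batch_size=batch_size, seed=seed)


def cohort_tensors(records: Sequence, lead_set: Optional[LeadSet] = None,
                   amplitude_scale: float = 6000.0):
    """Stack records into normalized input/target arrays.

    Returns ``(x, y)`` with shapes [n, n_input, N] and [n, n_output, N], both
    divided by ``amplitude_scale`` so signals live in roughly (-1, 1).
    """
    lead_set = lead_set or one_lead_set()
    xs, ys = [], []
    for rec in records:
        sig = rec.signal if hasattr(rec, "signal") else rec
        xs.append(np.stack([sig.lead(l) for l in lead_set.input_mode]))
        ys.append(np.stack([sig.lead(l) for l in lead_set.output_leads]))
    x = np.asarray(np.stack(xs) / amplitude_scale, dtype=nn.DTYPE)
    y = np.asarray(np.stack(ys) / amplitude_scale, dtype=nn.DTYPE)
    return x, y


def wgan_gp_losses(critic, real_patch: np.ndarray, fake_patch: np.ndarray,
                   lambda_gp: float, lambda_l1: float,
                   real_signal: np.ndarray, fake_signal: np.ndarray,
                   rng: np.random.Generator) -> Tuple[float, float]:
    """Evaluate the WGAN-GP critic loss and the adversarial+L1 generator loss.

    ``critic`` needs ``score(x)`` and ``input_gradient(x)``.  The penalty
    point is the per-item uniform interpolation between real and fake patches.
    """
    if real_patch.shape != fake_patch.shape:
        raise TrainingError(
            f"real patch {real_patch.shape} vs fake patch {fake_patch.shape}")
    s_fake = np.asarray(critic.score(fake_patch), dtype=float)
    s_real = np.asarray(critic.score(real_patch), dtype=float)
    eps = rng.uniform(size=(real_patch.shape[0], 1, 1))
    interp = eps * real_patch + (1.0 - eps) * fake_patch
    grads = np.asarray(critic.input_gradient(interp), dtype=float)
    norms = np.sqrt((grads.reshape(grads.shape[0], -1) ** 2).sum(axis=1))
    penalty = float(np.mean((norms - 1.0) ** 2))
    loss_d = float(s_fake.mean() - s_real.mean() + lambda_gp * penalty)
    l1 = float(np.mean(np.abs(np.asarray(real_signal, dtype=float)
                              - np.asarray(fake_signal, dtype=float))))
    loss_g = float(-s_fake.mean() + lambda_l1 * l1)
    return loss_d, loss_g


def validation_error(generator: Generator, records: Sequence,
                     lead_set: Optional[LeadSet] = None,
                     metric: str = "l1") -> float:
    """Mean reconstruction error on a record set, in microvolts."""
    lead_set = lead_set or one_lead_set()
    scale = generator.config.amplitude_scale
    x, y = cohort_tensors(records, lead_set, scale)
    err = 0.0
    bs = 32
    n = 0
    for i in range(0, x.shape[0], bs):
        yhat = generator.forward_norm(x[i:i + bs], train=False)
        diff = (yhat - y[i:i + bs]).astype(np.float64)
        if metric == "l1":
            err += np.abs(diff).sum()
        else:
            err += (diff ** 2).sum()
        n += diff.size
    err /= n
    return float(err * scale if metric == "l1" else err * scale * scale)


def _check_finite(value: float, what: str, epoch: int):
    if not math.isfinite(value):
        raise TrainingDivergence(
            f"{what} became non-finite ({value}) at epoch {epoch}; "
            "lower the learning rate or loss weights")


def train(generator: Generator, critic: Critic, train_records: Sequence,
          val_records: Sequence, config: TrainConfig,
          lead_set: Optional[LeadSet] = None) -> Tuple[Generator, pd.DataFrame]:
    """Adversarial training with the alternating update schedule.

    The critic is updated on every batch; the generator on every other batch
    (global batch counter).  Returns the generator restored to the epoch with
    minimal validation L1 error, plus a per-epoch history.
    """
    lead_set = lead_set or one_lead_set()
    if len(train_records) == 0 or len(val_records) == 0:
        raise TrainingError("empty train or validation split")
    rng = np.random.default_rng(config.seed)
    scale = generator.config.amplitude_scale
    x, y = cohort_tensors(train_records, lead_set, scale)
    n = x.shape[0]
    patch_n = critic.config.patch_samples
    opt_g = nn.Adam(generator.params, lr=config.lr, betas=config.betas)
    opt_d = nn.Adam(critic.params, lr=config.lr, betas=config.betas)

    history = []
    best = (math.inf, generator.state(), -1)
    global_batch = 0
    d_updates = g_updates = 0
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        ep_d, ep_g, n_batches, ep_g_updates = 0.0, 0.0, 0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = x[idx], y[idx]
            fake = generator.forward_norm(xb, train=True, rng=rng)
            real8 = np.concatenate([xb, yb], axis=1)
            fake8 = np.concatenate([xb, fake], axis=1)
            rp, fp, offset = random_patch(real8, fake8, patch_n, rng)
            b = len(idx)

            # ---- critic update (every batch) ----
            opt_d.zero_grad()
            s_fake = critic.forward(fp, cache=True)
            critic.backward(np.full(b, 1.0 / b), accumulate=True)
            s_real = critic.forward(rp, cache=True)
            critic.backward(np.full(b, -1.0 / b), accumulate=True)
            eps = rng.uniform(size=(b, 1, 1)).astype(nn.DTYPE)
            interp = eps * rp + (1 - eps) * fp
            critic.forward(interp, cache=True)
            g_in = critic.backward(np.ones(b), accumulate=False, store_deltas=True)
            norms = np.sqrt((g_in.astype(np.float64).reshape(b, -1) ** 2)
                            .sum(axis=1)) + 1e-12
            penalty = float(np.mean((norms - 1.0) ** 2))
            coef = (config.lambda_gp * 2.0 * (norms - 1.0) / norms / b)
            critic.gp_accumulate(g_in * coef[:, None, None].astype(nn.DTYPE))
            nn.clip_grad_norm(critic.params, config.clip_value)
            opt_d.step()
            d_updates += 1
            loss_d = float(s_fake.mean() - s_real.mean()
                           + config.lambda_gp * penalty)
            _check_finite(loss_d, "critic loss", epoch)
            ep_d += loss_d

            # ---- generator update (every other batch) ----
            loss_g = math.nan
            if global_batch % 2 == 0:
                opt_g.zero_grad()
                s_fake2 = critic.forward(fp, cache=True)
                dfp = critic.backward(np.full(b, -1.0 / b), accumulate=False)
                dfake = np.zeros_like(fake8)
                dfake[:, :, offset:offset + patch_n] = dfp
                l1 = float(np.mean(np.abs(fake.astype(np.float64)
                                          - yb.astype(np.float64))))
                dl1 = (config.lambda_l1 / fake.size) * np.sign(fake - yb)
                gfake = dfake[:, xb.shape[1]:, :] + dl1
                generator.backward(gfake.astype(nn.DTYPE))
                nn.clip_grad_norm(generator.params, config.clip_value)
                opt_g.step()
                g_updates += 1
                loss_g = float(-s_fake2.mean() + config.lambda_l1 * l1)
                _check_finite(loss_g, "generator loss", epoch)
                ep_g += loss_g
                ep_g_updates += 1
            global_batch += 1
            n_batches += 1

        val = validation_error(generator, val_records, lead_set, "l1")
        _check_finite(val, "validation error", epoch)
        if val < best[0]:
            best = (val, generator.state(), epoch)
        history.append({
            "epoch": epoch, "loss_d": ep_d / n_batches,
            "loss_g": ep_g / max(1, ep_g_updates),
            "val_l1_uv": val, "d_updates": d_updates, "g_updates": g_updates})
    if best[2] >= 0:
        generator.load_state(best[1])
    return generator, pd.DataFrame(history)


def train_unet(generator: Generator, train_records: Sequence,
               val_records: Sequence, config: TrainConfig,
               lead_set: Optional[LeadSet] = None) -> Tuple[Generator, pd.DataFrame]:
    """Pure U-Net training with mean-squared-error loss (no discriminator)."""
    lead_set = lead_set or one_lead_set()
    if len(train_records) == 0 or len(val_records) == 0:
        raise TrainingError("empty train or validation split")
    rng = np.random.default_rng(config.seed)
    scale = generator.config.amplitude_scale
    x, y = cohort_tensors(train_records, lead_set, scale)
    n = x.shape[0]
    opt = nn.Adam(generator.params, lr=config.lr_unet, betas=config.betas)
    history = []
    best = (math.inf, generator.state(), -1)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        ep_loss, n_batches = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = x[idx], y[idx]
            pred = generator.forward_norm(xb, train=True, rng=rng)
            diff = pred - yb
            loss = float(np.mean(diff.astype(np.float64) ** 2))
            _check_finite(loss, "mse loss", epoch)
            opt.zero_grad()
            generator.backward((2.0 / diff.size) * diff)
            nn.clip_grad_norm(generator.params, config.clip_value)
            opt.step()
            ep_loss += loss
            n_batches += 1
        val = validation_error(generator, val_records, lead_set, "mse")
        if val < best[0]:
            best = (val, generator.state(), epoch)
        history.append({"epoch": epoch, "loss_mse": ep_loss / n_batches,
                        "val_mse_uv2": val})
    if best[2] >= 0:
        generator.load_state(best[1])
    return generator, pd.DataFrame(history)


class MeanPredictor:
    """Constant predictor: per-lead, per-sample average of the training set.

    The analytic regression-to-the-mean extreme — its output is identical for
    every input, so reconstructed-marker variance is zero and the
    Bland-Altman slope of (recon - real) against real is exactly -1.
    """

    def __init__(self, mean_uv: np.ndarray, lead_set: LeadSet):
        self.mean_uv = np.asarray(mean_uv, dtype=float)
        self.lead_set = lead_set

    def reconstruct(self, inputs_uv: np.ndarray) -> np.ndarray:
        x = np.asarray(inputs_uv)
        if x.ndim == 3:
            return np.broadcast_to(self.mean_uv, (x.shape[0],) + self.mean_uv.shape).copy()
        return self.mean_uv.copy()

    __call__ = reconstruct


def baseline_mean_predictor(train_records: Sequence,
                            lead_set: Optional[LeadSet] = None) -> MeanPredictor:
    lead_set = lead_set or one_lead_set()
    ys = [np.stack([(r.signal if hasattr(r, "signal") else r).lead(l)
                    for l in lead_set.output_leads]) for r in train_records]
    return MeanPredictor(np.mean(ys, axis=0), lead_set)


class LinearPredictor:
    """Sample-wise affine map from input leads to each output lead."""

    def __init__(self, coef: np.ndarray, intercept: np.ndarray, lead_set: LeadSet):
        self.coef = coef              # [n_output, n_input]
        self.intercept = intercept    # [n_output]
        self.lead_set = lead_set

    def reconstruct(self, inputs_uv: np.ndarray) -> np.ndarray:
        x = np.asarray(inputs_uv, dtype=float)
        if x.ndim == 3:
            return np.einsum("oi,bin->bon", self.coef, x) + self.intercept[None, :, None]
        return self.coef @ x + self.intercept[:, None]

    __call__ = reconstruct


def baseline_linear(train_records: Sequence,
                    lead_set: Optional[LeadSet] = None) -> LinearPredictor:
    """Least-squares instantaneous map over all training time points."""
    lead_set = lead_set or one_lead_set()
    xs, ys = [], []
    for rec in train_records:
        sig = rec.signal if hasattr(rec, "signal") else rec
        xs.append(np.stack([sig.lead(l) for l in lead_set.input_mode]))
        ys.append(np.stack([sig.lead(l) for l in lead_set.output_leads]))
    x = np.asarray(np.stack(xs), dtype=np.float64)
    y = np.asarray(np.stack(ys), dtype=np.float64)
    n_in = x.shape[1]
    xt = x.transpose(0, 2, 1).reshape(-1, n_in)
    yt = y.transpose(0, 2, 1).reshape(-1, y.shape[1])
    design = np.column_stack([xt, np.ones(len(xt))])
    beta, *_ = np.linalg.lstsq(design, yt, rcond=None)
    return LinearPredictor(beta[:n_in].T, beta[n_in], lead_set)
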