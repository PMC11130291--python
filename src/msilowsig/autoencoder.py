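"""Shallow convolutional autoencoder for MSI patches.

The encoder maps a (x, x, y) patch — x pixels squared, y m/z channels — to a
spatially organized latent tensor: a pointwise (1x1) convolution compresses
the channel axis to z1, and a second valid convolution with kernel size
``kernel2`` (default 2) reduces both the spatial extent (x -> x - kernel2 + 1)
and the channel axis to the latent size z2.  Both convolutions are followed
by batch normalization and ReLU.  The decoder mirrors the encoder layer by
layer (transposed convolution, batch normalization, ReLU), so reconstructions
are nonnegative like the [0,1]-normalized input.

Three training modes share this backbone:

* ``unsupervised`` — minimizes an *adjusted* mean absolute error that sums
  the reconstruction error over all pixels and channels of a patch (instead
  of averaging over channels), so that the many low-intensity channels are
  not washed out by the mean.
* ``semisupervised`` — adds a supervised error term computed only on pixels
  whose hypoxia annotation exceeds a threshold (default 0.6), steering the
  code to retain annotation-associated channels.
* ``variational`` — appends mean/log-variance heads and a sampling step and
  regularizes with the KL divergence to a standard Gaussian.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .nn import (
    Adam,
    BatchNorm,
    Conv1x1,
    ConvTranspose,
    ConvValid,
    ReLU,
    Sequential,
)

log = logging.getLogger(__name__)

MODES = ("unsupervised", "semisupervised", "variational")


@dataclass
class AEConfig:
    n_features: int
    patch_size: int = 3
    hidden: int = 1024
    latent: int = 64
    kernel2: int = 2
    mode: str = "unsupervised"
    epochs: int | None = None  # 25 unsupervised/variational, 50 semi-supervised
    learning_rate: float = 1e-4
    batch_size: int = 32
    hypoxia_threshold: float = 0.6
    supervised_weight: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.kernel2 >= self.patch_size:
            raise ValueError(
                "kernel2 must be smaller than patch_size "
                "(a degenerate or empty spatial latent cannot preserve structure)"
            )
        if self.latent < 1 or self.hidden < 1:
            raise ValueError("latent and hidden sizes must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    @property
    def latent_spatial(self) -> int:
        return self.patch_size - self.kernel2 + 1

    @property
    def resolved_epochs(self) -> int:
        if self.epochs is not None:
            return self.epochs
        return 50 if self.mode == "semisupervised" else 25


@dataclass
class AEModel:
    encoder: Sequential
    decoder: Sequential
    config: AEConfig
    mu_head: Conv1x1 | None = None
    logvar_head: Conv1x1 | None = None
    training_log: list[dict] = field(default_factory=list)

    @property
    def params(self) -> list[np.ndarray]:
        p = self.encoder.params + self.decoder.params
        if self.mu_head is not None:
            p += self.mu_head.params + self.logvar_head.params
        return p

    @property
    def grads(self) -> list[np.ndarray]:
        g = self.encoder.grads + self.decoder.grads
        if self.mu_head is not None:
            g += self.mu_head.grads + self.logvar_head.grads
        return g


def build_model(config: AEConfig) -> AEModel:
    """Assemble encoder/decoder (and variational heads) with seeded init."""
    rng = np.random.default_rng(config.seed)
    y, z1, z2, k2 = config.n_features, config.hidden, config.latent, config.kernel2
    encoder = Sequential(
        [
            Conv1x1(y, z1, rng),
            BatchNorm(z1),
            ReLU(),
            ConvValid(z1, z2, k2, rng),
            BatchNorm(z2),
            ReLU(),
        ]
    )
    decoder = Sequential(
        [
            ConvTranspose(z2, z1, k2, rng),
            BatchNorm(z1),
            ReLU(),
            Conv1x1(z1, y, rng),
            BatchNorm(y),
            ReLU(),
        ]
    )
    mu_head = logvar_head = None
    if config.mode == "variational":
        mu_head = Conv1x1(z2, z2, rng)
        logvar_head = Conv1x1(z2, z2, rng)
    return AEModel(encoder=encoder, decoder=decoder, config=config,
                   mu_head=mu_head, logvar_head=logvar_head)


# ---------------------------------------------------------------------------
# losses


def adjusted_mae(x: np.ndarray, xhat: np.ndarray) -> float:
    """Mean over patches of the SUM of absolute errors over pixels/channels.

    Summing (rather than averaging) over the channel axis keeps the
    contribution of each individual m/z channel in the loss, which is what
    lets low-abundant channels survive compression.
    """
    x = np.asarray(x, dtype=float)
    xhat = np.asarray(xhat, dtype=float)
    if x.shape != xhat.shape:
        raise ValueError("shape mismatch between input and reconstruction")
    n = x.shape[0]
    return float(np.abs(x - xhat).sum() / n)


def supervised_error(
    x: np.ndarray,
    xhat: np.ndarray,
    annotations: np.ndarray,
    threshold: float = 0.6,
) -> float:
    """Mean over annotated pixels (> threshold) of per-pixel error sums.

    ``annotations`` holds one value per patch pixel (N x p x p).  Returns 0
    when no pixel is selected.
    """
    x = np.asarray(x, dtype=float)
    xhat = np.asarray(xhat, dtype=float)
    annotations = np.asarray(annotations, dtype=float)
    if x.shape != xhat.shape:
        raise ValueError("shape mismatch between input and reconstruction")
    if annotations.shape != x.shape[:3]:
        raise ValueError("need one annotation value per patch pixel")
    sel = annotations > threshold
    n_sel = int(sel.sum())
    if n_sel == 0:
        return 0.0
    per_pixel = np.abs(x - xhat).sum(axis=-1)
    return float(per_pixel[sel].sum() / n_sel)


def kl_divergence(mu: np.ndarray, logvar: np.ndarray) -> float:
    """KL divergence of N(mu, sigma^2) from the standard Gaussian.

    -0.5 * sum_i (1 + log sigma_i^2 - mu_i^2 - sigma_i^2), summed over all
    latent dimensions.
    """
    mu = np.asarray(mu, dtype=float)
    logvar = np.asarray(logvar, dtype=float)
    return float(-0.5 * np.sum(1.0 + logvar - mu**2 - np.exp(logvar)))


# ---------------------------------------------------------------------------
# training


def _forward_backward(
    model: AEModel,
    batch: np.ndarray,
    ann_batch: np.ndarray | None,
    rng: np.random.Generator,
) -> dict:
    """One training step's loss components and parameter gradients."""
    cfg = model.config
    n = batch.shape[0]
    code = model.encoder.forward(batch, training=True)
    if cfg.mode == "variational":
        mu = model.mu_head.forward(code, training=True)
        logvar = model.logvar_head.forward(code, training=True)
        eps = rng.standard_normal(mu.shape)
        z = mu + np.exp(0.5 * logvar) * eps
        xhat = model.decoder.forward(z, training=True)
    else:
        xhat = model.decoder.forward(code, training=True)

    diff = xhat - batch
    sign = np.sign(diff)
    losses = {"mae_adj": adjusted_mae(batch, xhat)}
    grad_xhat = sign / n

    if cfg.mode == "semisupervised" and ann_batch is not None:
        sel = ann_batch > cfg.hypoxia_threshold
        n_sel = int(sel.sum())
        losses["supervised"] = supervised_error(
            batch, xhat, ann_batch, cfg.hypoxia_threshold
        )
        if n_sel > 0:
            grad_xhat = grad_xhat + cfg.supervised_weight * sign * sel[..., None] / n_sel

    gz = model.decoder.backward(grad_xhat)
    if cfg.mode == "variational":
        losses["kl"] = kl_divergence(mu, logvar) / n
        grad_mu = gz + mu / n
        grad_logvar = gz * eps * 0.5 * np.exp(0.5 * logvar) \
            - 0.5 * (1.0 - np.exp(logvar)) / n
        gcode = model.mu_head.backward(grad_mu) + model.logvar_head.backward(grad_logvar)
    else:
        gcode = gz
    model.encoder.backward(gcode)

    losses["total"] = losses["mae_adj"] \
        + model.config.supervised_weight * losses.get("supervised", 0.0) \
        + losses.get("kl", 0.0)
    return losses


def evaluate_loss(
    model: AEModel,
    patches: np.ndarray,
    annotations: np.ndarray | None = None,
    batch_size: int = 256,
) -> float:
    """Inference-mode total loss over a patch set."""
    cfg = model.config
    total = 0.0
    n = len(patches)
    for start in range(0, n, batch_size):
        batch = patches[start : start + batch_size]
        code = model.encoder.forward(batch, training=False)
        if cfg.mode == "variational":
            mu = model.mu_head.forward(code, training=False)
            logvar = model.logvar_head.forward(code, training=False)
            xhat = model.decoder.forward(mu, training=False)
            total += kl_divergence(mu, logvar)
        else:
            xhat = model.decoder.forward(code, training=False)
        total += np.abs(batch - xhat).sum()
        if cfg.mode == "semisupervised" and annotations is not None:
            ann = annotations[start : start + batch_size]
            sup = supervised_error(batch, xhat, ann, cfg.hypoxia_threshold)
            total += cfg.supervised_weight * sup * len(batch)
    return float(total / n)


def train(
    model: AEModel,
    train_patches: np.ndarray,
    val_patches: np.ndarray | None = None,
    annotations: np.ndarray | None = None,
    val_annotations: np.ndarray | None = None,
) -> AEModel:
    """Train with Adam at the configured learning rate, seeded throughout.

    ``annotations`` (N x p x p pixel-level values) are required in the
    semi-supervised mode.  Per-epoch train/validation losses are appended to
    ``model.training_log``.  Non-finite losses abort training.
    """
    cfg = model.config
    if cfg.mode == "semisupervised" and annotations is None:
        raise ValueError("semisupervised mode requires pixel-level annotations")
    if cfg.learning_rate >= 1e-3:
        warnings.warn(
            f"learning rate {cfg.learning_rate:g} is high; rates >= 1e-3 are "
            "known to deteriorate the learned representations",
            stacklevel=2,
        )
    rng = np.random.default_rng(cfg.seed + 1)
    opt = Adam(model.params, lr=cfg.learning_rate)
    n = len(train_patches)
    for epoch in range(cfg.resolved_epochs):
        order = rng.permutation(n)
        epoch_losses: list[dict] = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            ann = annotations[idx] if annotations is not None else None
            losses = _forward_backward(model, train_patches[idx], ann, rng)
            if not np.isfinite(losses["total"]):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={losses['total']}"
                )
            opt.step(model.grads)
            epoch_losses.append(losses)
        entry = {
            "epoch": epoch,
            "train_loss": float(np.mean([l["total"] for l in epoch_losses])),
        }
        for key in ("mae_adj", "supervised", "kl"):
            if key in epoch_losses[0]:
                entry[f"train_{key}"] = float(np.mean([l[key] for l in epoch_losses]))
        if val_patches is not None and len(val_patches):
            entry["val_loss"] = evaluate_loss(model, val_patches, val_annotations)
        model.training_log.append(entry)
        log.debug("epoch %d: %s", epoch, entry)
    return model


def encode(model: AEModel, patches: np.ndarray, batch_size: int = 1024) -> np.ndarray:
    """Deterministic latent activations (inference mode).

    Variational models return the mean vector of the latent distribution.
    Output shape: N x (x - kernel2 + 1) x (x - kernel2 + 1) x z2.
    """
    patches = np.asarray(patches, dtype=float)
    cfg = model.config
    if patches.ndim != 4 or patches.shape[1:3] != (cfg.patch_size, cfg.patch_size) \
            or patches.shape[3] != cfg.n_features:
        raise ValueError(
            f"expected patches of shape (N, {cfg.patch_size}, {cfg.patch_size}, "
            f"{cfg.n_features}), got {patches.shape}"
        )
    outs = []
    for start in range(0, len(patches), batch_size):
        code = model.encoder.forward(patches[start : start + batch_size], training=False)
        if cfg.mode == "variational":
            code = model.mu_head.forward(code, training=False)
        outs.append(code)
    return np.concatenate(outs) if outs else np.empty(
        (0, cfg.latent_spatial, cfg.latent_spatial, cfg.latent)
    )


def latent_patch_means(latent: np.ndarray) -> np.ndarray:
    """Mean over the latent spatial pixels, one value per latent feature."""
    return latent.mean(axis=(1, 2))
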