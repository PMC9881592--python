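"""Networks and training loops.

Three models, all small enough for CPU training:

* a Gaussian VAE baseline whose decoder emits a per-pixel (mean, log-variance)
  pair, trained on the Gaussian negative log-likelihood plus the latent KL —
  the configuration that exhibits variance shrinkage;
* a quantile-regression VAE (QR-VAE) whose decoder emits one map per quantile
  level, trained on the summed pinball losses plus the same KL term; the
  levels share all parameters except the final head layer;
* a multi-head U-Net for binary quantile regression (BQR) on multi-rater
  segmentation masks, trained with the smoothed BQR objective after a
  weighted cross-entropy warm-up epoch.

Encoder/decoder topology for the VAEs: three conv(stride 2) + batch-norm +
ReLU blocks into a fully connected bottleneck; the decoder mirrors it with
nearest-neighbor-upsample + conv blocks, ending in one head per output
(sigmoid for image intensities). A dense (MLP) variant of the same
encoder/decoder contract is provided for low-dimensional tabular data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from lesionqr import nn
from lesionqr.fields import GaussianField, QuantilePredictionField, check_levels
from lesionqr.losses import (
    SIGMA_FLOOR,
    kl_standard_normal,
    pinball_grad,
    pinball_loss,
    pos_weight_from_labels,
)


class TrainingDivergedError(RuntimeError):
    """Raised when a training loss becomes non-finite (e.g. variance collapse)."""


@dataclass
class TrainConfig:
    """Training hyperparameters; every field is logged with each run."""

    latent_dim: int = 32
    epochs: int = 20
    learning_rate: float = 1e-3
    batch_size: int = 16
    seed: int = 0
    image_shape: tuple[int, int, int] = (3, 64, 64)
    kl_weight: float = 1.0
    widths: tuple[int, int, int] = (32, 64, 128)
    sigma_floor: float = SIGMA_FLOOR

    def __post_init__(self) -> None:
        if min(self.latent_dim, self.epochs, self.batch_size) < 1:
            raise ValueError("latent_dim, epochs, batch_size must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    def with_(self, **kw) -> "TrainConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# VAE (conv or dense body, gaussian or quantile heads)
# ---------------------------------------------------------------------------


class VAE:
    """Encoder/decoder pair with either a Gaussian or a quantile head set.

    ``kind == "gaussian"``: ``heads = [mean, logvar]``.
    ``kind == "quantile"``: one head per level, levels strictly increasing.
    Heads share the full decoder trunk; only the final layer differs.
    """

    def __init__(
        self,
        enc_body: nn.Sequential,
        fc_mu: nn.Dense,
        fc_logvar: nn.Dense,
        dec_trunk: nn.Sequential,
        heads: list[nn.Sequential],
        kind: str,
        levels: tuple[float, ...] | None = None,
        sigma_floor: float = SIGMA_FLOOR,
    ):
        if kind not in ("gaussian", "quantile"):
            raise ValueError(kind)
        if kind == "quantile":
            levels = check_levels(levels)
            if len(heads) != len(levels):
                raise ValueError("one head per level required")
        self.enc_body = enc_body
        self.fc_mu = fc_mu
        self.fc_logvar = fc_logvar
        self.dec_trunk = dec_trunk
        self.heads = heads
        self.kind = kind
        self.levels = levels
        self.sigma_floor = sigma_floor

    def params(self) -> list[nn.Param]:
        out = self.enc_body.params() + self.fc_mu.params() + self.fc_logvar.params()
        out += self.dec_trunk.params()
        for h in self.heads:
            out += h.params()
        return out

    def n_params(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def encode(self, x: np.ndarray, train: bool = True):
        h = self.enc_body.forward(x, train=train)
        return self.fc_mu.forward(h, train=train), self.fc_logvar.forward(
            h, train=train
        )

    def decode(self, z: np.ndarray, train: bool = True) -> list[np.ndarray]:
        h = self.dec_trunk.forward(z, train=train)
        return [head.forward(h, train=train) for head in self.heads]

    def backward(
        self,
        ghead_outputs: list[np.ndarray],
        gmu_extra: np.ndarray,
        glogvar_extra: np.ndarray,
        eps: np.ndarray,
        logvar_enc: np.ndarray,
    ) -> None:
        """Backprop one training step: head gradients -> trunk -> latent ->
        reparameterization -> encoder (with KL gradients added at the latent)."""
        gh = None
        for head, g in zip(self.heads, ghead_outputs):
            gb = head.backward(g)
            gh = gb if gh is None else gh + gb
        gz = self.dec_trunk.backward(gh)
        gmu = gz + gmu_extra
        glv = gz * eps * 0.5 * np.exp(0.5 * logvar_enc) + glogvar_extra
        ghenc = self.fc_mu.backward(gmu) + self.fc_logvar.backward(glv)
        self.enc_body.backward(ghenc)

    # -- inference ---------------------------------------------------------

    def _decode_eval(self, x: np.ndarray) -> list[np.ndarray]:
        mu, _ = self.encode(x, train=False)
        return self.decode(mu, train=False)

    def predict_gaussian(self, x: np.ndarray) -> GaussianField:
        """Deterministic reconstruction at the posterior mean (z = mu)."""
        if self.kind != "gaussian":
            raise ValueError("predict_gaussian requires a gaussian head")
        mean, logvar = self._decode_eval(x)
        sigma = np.maximum(np.exp(0.5 * np.clip(logvar, -30, 10)), self.sigma_floor)
        return GaussianField(mean=mean, sigma=sigma)

    def predict_quantiles(self, x: np.ndarray) -> QuantilePredictionField:
        if self.kind != "quantile":
            raise ValueError("predict_quantiles requires quantile heads")
        maps = self._decode_eval(x)
        return QuantilePredictionField(self.levels, np.stack(maps, axis=0))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Ancestral sampling: z from the standard-normal prior, then one draw
        from the decoded per-dimension Gaussian.

        Quantile models are converted to a Gaussian via the (low, median)
        quantile pair before sampling.
        """
        latent = self.fc_mu.b.value.shape[0]
        z = rng.standard_normal((n, latent))
        outs = self.decode(z, train=False)
        if self.kind == "gaussian":
            mean, logvar = outs
            sigma = np.maximum(
                np.exp(0.5 * np.clip(logvar, -30, 10)), self.sigma_floor
            )
        else:
            from lesionqr.detection import quantiles_to_gaussian

            if len(self.levels) != 2 or self.levels[1] != 0.5:
                raise ValueError(
                    "sampling a quantile model needs levels (low, 0.5)"
                )
            gf = quantiles_to_gaussian(
                q_mid=outs[1],
                q_low=outs[0],
                low_level=self.levels[0],
                sigma_floor=self.sigma_floor,
            )
            mean, sigma = gf.mean, gf.sigma
        return mean + sigma * rng.standard_normal(mean.shape)


def _conv_block(c_in: int, c_out: int, stride: int, rng) -> list[nn.Layer]:
    return [
        nn.Conv2d(c_in, c_out, k=3, stride=stride, pad=1, rng=rng),
        nn.BatchNorm2d(c_out),
        nn.ReLU(),
    ]


def build_conv_vae(
    config: TrainConfig,
    head: str = "gaussian",
    levels=None,
) -> VAE:
    """Convolutional VAE for images of shape ``config.image_shape``.

    ``head``: ``"gaussian"`` or ``"quantile"`` (with ``levels``). The spatial
    dimensions must survive three stride-2 downsamplings (divisible by 8).
    """
    c, h, w = config.image_shape
    if h % 8 or w % 8 or h < 8 or w < 8:
        raise ValueError(
            f"image shape {(c, h, w)} incompatible with three stride-2 stages"
        )
    rng = np.random.default_rng(config.seed)
    w1, w2, w3 = config.widths
    enc_body = nn.Sequential(
        *_conv_block(c, w1, 2, rng),
        *_conv_block(w1, w2, 2, rng),
        *_conv_block(w2, w3, 2, rng),
        nn.Flatten(),
    )
    feat = w3 * (h // 8) * (w // 8)
    fc_mu = nn.Dense(feat, config.latent_dim, rng)
    fc_logvar = nn.Dense(feat, config.latent_dim, rng)
    dec_trunk = nn.Sequential(
        nn.Dense(config.latent_dim, feat, rng),
        nn.Reshape((w3, h // 8, w // 8)),
        nn.UpsampleNearest2(),
        *_conv_block(w3, w2, 1, rng),
        nn.UpsampleNearest2(),
        *_conv_block(w2, w1, 1, rng),
        nn.UpsampleNearest2(),
        *_conv_block(w1, w1, 1, rng),
    )

    def image_head(activation: bool) -> nn.Sequential:
        layers: list[nn.Layer] = [nn.Conv2d(w1, c, k=3, stride=1, pad=1, rng=rng)]
        if activation:
            layers.append(nn.Sigmoid())
        return nn.Sequential(*layers)

    if head == "gaussian":
        heads = [image_head(True), image_head(False)]  # mean (sigmoid), logvar
        return VAE(enc_body, fc_mu, fc_logvar, dec_trunk, heads, "gaussian",
                   sigma_floor=config.sigma_floor)
    if head == "quantile":
        levels = check_levels(levels)
        heads = [image_head(True) for _ in levels]
        return VAE(enc_body, fc_mu, fc_logvar, dec_trunk, heads, "quantile",
                   levels=levels, sigma_floor=config.sigma_floor)
    raise ValueError(f"unknown head kind {head!r}")


def build_mlp_vae(
    input_dim: int,
    config: TrainConfig,
    head: str = "gaussian",
    levels=None,
    hidden: tuple[int, int] = (64, 64),
) -> VAE:
    """Dense VAE for low-dimensional tabular data (unbounded outputs)."""
    rng = np.random.default_rng(config.seed)
    h1, h2 = hidden
    enc_body = nn.Sequential(
        nn.Dense(input_dim, h1, rng), nn.ReLU(), nn.Dense(h1, h2, rng), nn.ReLU()
    )
    fc_mu = nn.Dense(h2, config.latent_dim, rng)
    fc_logvar = nn.Dense(h2, config.latent_dim, rng)
    dec_trunk = nn.Sequential(
        nn.Dense(config.latent_dim, h2, rng),
        nn.ReLU(),
        nn.Dense(h2, h1, rng),
        nn.ReLU(),
    )
    if head == "gaussian":
        heads = [
            nn.Sequential(nn.Dense(h1, input_dim, rng)),
            nn.Sequential(nn.Dense(h1, input_dim, rng)),
        ]
        return VAE(enc_body, fc_mu, fc_logvar, dec_trunk, heads, "gaussian",
                   sigma_floor=config.sigma_floor)
    if head == "quantile":
        levels = check_levels(levels)
        heads = [nn.Sequential(nn.Dense(h1, input_dim, rng)) for _ in levels]
        return VAE(enc_body, fc_mu, fc_logvar, dec_trunk, heads, "quantile",
                   levels=levels, sigma_floor=config.sigma_floor)
    raise ValueError(f"unknown head kind {head!r}")


# ---------------------------------------------------------------------------
# VAE training
# ---------------------------------------------------------------------------


def _write_log(log: list[dict], log_path) -> None:
    if log_path is not None:
        with open(log_path, "w") as fh:
            for entry in log:
                fh.write(json.dumps(entry) + "\n")


def _sigma_stats(sigma: np.ndarray) -> dict:
    return {
        "sigma_median": float(np.median(sigma)),
        "sigma_min": float(sigma.min()),
        "sigma_max": float(sigma.max()),
    }


def train_vae(
    data: np.ndarray,
    config: TrainConfig,
    model: VAE | None = None,
    log_path=None,
) -> tuple[VAE, list[dict]]:
    """Train a Gaussian VAE on data in [0,1] (images) or unbounded tabular data.

    Returns the trained model and a per-epoch training log (loss, recon, KL,
    sigma statistics). Raises :class:`TrainingDivergedError` on a non-finite
    loss, reporting sigma statistics at failure — variance collapse is the
    documented failure mode of this objective.
    """
    data = np.asarray(data, dtype=float)
    if model is None:
        model = (
            build_conv_vae(config, head="gaussian")
            if data.ndim == 4
            else build_mlp_vae(data.shape[1], config, head="gaussian")
        )
    lv_floor = 2.0 * np.log(config.sigma_floor)

    def loss_and_grads(x, outs):
        mean, lv_raw = outs
        clamped = lv_raw < lv_floor
        lv = np.maximum(lv_raw, lv_floor)
        var = np.exp(lv)
        r = x - mean
        nll = 0.5 * lv + r**2 / (2.0 * var)
        npix = x.size
        gmean = (mean - x) / var / npix
        glv = 0.5 * (1.0 - r**2 / var) / npix
        glv[clamped] = 0.0
        extra = _sigma_stats(np.exp(0.5 * lv))
        return float(nll.mean()), [gmean, glv], extra

    return _run_vae_training(model, data, config, loss_and_grads, log_path)


def train_qrvae(
    data: np.ndarray,
    levels,
    config: TrainConfig,
    model: VAE | None = None,
    log_path=None,
) -> tuple[VAE, list[dict]]:
    """Train a QR-VAE: summed per-level pinball losses plus the latent KL.

    The per-epoch log records the quantile-crossing fraction of the final
    batch's predictions. Levels share the whole network except the heads, so
    no loss term couples different levels.
    """
    data = np.asarray(data, dtype=float)
    levels = check_levels(levels)
    if model is None:
        model = (
            build_conv_vae(config, head="quantile", levels=levels)
            if data.ndim == 4
            else build_mlp_vae(data.shape[1], config, head="quantile", levels=levels)
        )

    def loss_and_grads(x, outs):
        npix = x.size
        loss = 0.0
        grads = []
        for alpha, q in zip(levels, outs):
            r = x - q
            loss += pinball_loss(r, alpha, reduction="mean")
            grads.append(pinball_grad(r, alpha) / npix)
        stacked = np.stack(outs, axis=0)
        crossing = float((stacked[1:] < stacked[:-1]).mean()) if len(outs) > 1 else 0.0
        return float(loss), grads, {"crossing_fraction": crossing}

    return _run_vae_training(model, data, config, loss_and_grads, log_path)


def _collect_bn(layer) -> list[nn.BatchNorm2d]:
    if isinstance(layer, nn.BatchNorm2d):
        return [layer]
    if isinstance(layer, nn.Sequential):
        return [bn for sub in layer.layers for bn in _collect_bn(sub)]
    return []


def _recalibrate_bn(model: "VAE", data: np.ndarray, max_n: int = 256) -> None:
    """Refresh batch-norm running statistics on the deterministic inference
    path (z = posterior mean). During training the decoder sees sampled z, so
    its batch statistics differ from those of the z = mu path used at
    inference; without this pass the eval-mode reconstructions are biased."""
    bns = []
    for part in (model.enc_body, model.dec_trunk, *model.heads):
        bns += _collect_bn(part)
    saved = [bn.momentum for bn in bns]
    for bn in bns:
        bn.momentum = 1.0
    sel = data[: min(len(data), max_n)]
    mu, _ = model.encode(sel, train=True)
    model.decode(mu, train=True)
    for bn, m in zip(bns, saved):
        bn.momentum = m


def _run_vae_training(model, data, config, loss_and_grads, log_path):
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.params(), lr=config.learning_rate)
    n = data.shape[0]
    # reconstruction is a per-element mean, so the per-sample KL is scaled by
    # the per-sample data size to keep the standard ELBO term balance
    d_size = int(np.prod(data.shape[1:]))
    log: list[dict] = []
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        epoch_recon = epoch_kl = 0.0
        n_batches = 0
        extra: dict = {}
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            x = data[idx]
            mu, lv_enc = model.encode(x)
            eps = rng.standard_normal(mu.shape)
            z = mu + np.exp(0.5 * lv_enc) * eps
            outs = model.decode(z)
            recon, gouts, extra = loss_and_grads(x, outs)
            kl = kl_standard_normal(mu, lv_enc) / d_size
            loss = recon + config.kl_weight * kl
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch} "
                    f"(recon={recon}, kl={kl}, extra={extra})"
                )
            nb = x.shape[0]
            gmu_kl = config.kl_weight * mu / (nb * d_size)
            glv_kl = config.kl_weight * 0.5 * (np.exp(lv_enc) - 1.0) / (nb * d_size)
            opt.zero_grad()
            model.backward(gouts, gmu_kl, glv_kl, eps, lv_enc)
            opt.step()
            epoch_recon += recon
            epoch_kl += kl
            n_batches += 1
        entry = {
            "epoch": epoch,
            "loss": (epoch_recon + config.kl_weight * epoch_kl) / n_batches,
            "recon": epoch_recon / n_batches,
            "kl": epoch_kl / n_batches,
            **extra,
        }
        log.append(entry)
    _recalibrate_bn(model, data)
    _write_log(log, log_path)
    return model, log


# ---------------------------------------------------------------------------
# Multi-head U-Net for binary quantile regression
# ---------------------------------------------------------------------------


class MultiHeadUNet:
    """Two-scale U-Net with a shared body and one 1x1-conv head per quantile
    level (logit output; the sigmoid smoothing K is applied by the loss)."""

    def __init__(self, in_ch: int, n_heads: int, base: int, seed: int):
        rng = np.random.default_rng(seed)
        b = base

        def block(ci, co, stride=1):
            return nn.Sequential(*_conv_block(ci, co, stride, rng))

        self.enc1 = block(in_ch, b)
        self.down1 = block(b, 2 * b, stride=2)
        self.enc2 = block(2 * b, 2 * b)
        self.down2 = block(2 * b, 4 * b, stride=2)
        self.bott = block(4 * b, 4 * b)
        self.up2 = nn.Sequential(nn.UpsampleNearest2(), *_conv_block(4 * b, 2 * b, 1, rng))
        self.dec2 = block(4 * b, 2 * b)
        self.up1 = nn.Sequential(nn.UpsampleNearest2(), *_conv_block(2 * b, b, 1, rng))
        self.dec1 = block(2 * b, b)
        self.heads = [nn.Conv2d(b, 1, k=1, stride=1, pad=0, rng=rng) for _ in range(n_heads)]
        self.base = b

    def _bodies(self):
        return [
            self.enc1, self.down1, self.enc2, self.down2, self.bott,
            self.up2, self.dec2, self.up1, self.dec1,
        ]

    def params(self) -> list[nn.Param]:
        out = []
        for m in self._bodies():
            out += m.params()
        for h in self.heads:
            out += h.params()
        return out

    def n_params(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def forward(self, x: np.ndarray, train: bool = True) -> list[np.ndarray]:
        if x.shape[2] % 4 or x.shape[3] % 4:
            raise ValueError("spatial dimensions must be divisible by 4")
        e1 = self.enc1.forward(x, train)
        e2 = self.enc2.forward(self.down1.forward(e1, train), train)
        bt = self.bott.forward(self.down2.forward(e2, train), train)
        u2 = self.up2.forward(bt, train)
        d2 = self.dec2.forward(np.concatenate([u2, e2], axis=1), train)
        u1 = self.up1.forward(d2, train)
        d1 = self.dec1.forward(np.concatenate([u1, e1], axis=1), train)
        return [h.forward(d1, train) for h in self.heads]

    def backward(self, glogits: list[np.ndarray]) -> None:
        b2 = 2 * self.base
        gd1 = None
        for h, g in zip(self.heads, glogits):
            gb = h.backward(g)
            gd1 = gb if gd1 is None else gd1 + gb
        gc1 = self.dec1.backward(gd1)
        gu1, ge1_skip = gc1[:, : self.base], gc1[:, self.base :]
        gd2 = self.up1.backward(gu1)
        gc2 = self.dec2.backward(gd2)
        gu2, ge2_skip = gc2[:, :b2], gc2[:, b2:]
        gbt = self.up2.backward(gu2)
        ge2 = self.down2.backward(self.bott.backward(gbt)) + ge2_skip
        ge1 = self.down1.backward(self.enc2.backward(ge2)) + ge1_skip
        self.enc1.backward(ge1)

    def predict_logits(self, x: np.ndarray) -> np.ndarray:
        """(n_heads, N, H, W) logit maps in eval mode."""
        outs = self.forward(x, train=False)
        return np.stack([o[:, 0] for o in outs], axis=0)


def build_bqr_unet(config: TrainConfig, levels, base: int = 8) -> MultiHeadUNet:
    """Multi-head BQR network: one head per level, shared body."""
    levels = check_levels(levels)
    c = config.image_shape[0]
    model = MultiHeadUNet(c, len(levels), base=base, seed=config.seed)
    model.levels = levels
    return model


def _sigmoid(t):
    out = np.empty_like(t, dtype=float)
    pos = t >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-t[pos]))
    e = np.exp(t[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _rater_pairs(images: np.ndarray, rater_masks: np.ndarray):
    """Expand (image, k rater masks) into (image, single mask) samples: each
    rater's annotation is one realization of the binary label field."""
    n, k = rater_masks.shape[:2]
    x = np.repeat(images, k, axis=0)
    y = rater_masks.reshape(n * k, 1, *rater_masks.shape[2:]).astype(float)
    return x, y


def train_bqr_unet(
    images: np.ndarray,
    rater_masks: np.ndarray,
    levels,
    config: TrainConfig,
    model: MultiHeadUNet | None = None,
    warmup: bool = True,
    warmup_epochs: int = 1,
    log_path=None,
) -> tuple[MultiHeadUNet, list[dict]]:
    """Train the multi-head BQR U-Net on (image, k-rater-mask) data.

    A warm-up phase with the weighted cross-entropy (positive-class weight
    computed from the label imbalance) guards against collapse to the trivial
    all-background solution, then the smoothed BQR objective is minimized.
    ``warmup_epochs`` defaults to a single pass; with very small datasets an
    epoch is only a handful of optimizer steps, so experiments may lengthen
    the warm-up proportionally.
    The final log entry flags ``trivial_solution`` if every head predicts an
    empty mask on the training images.
    """
    levels = check_levels(levels)
    if model is None:
        model = build_bqr_unet(config, levels)
    x_all, y_all = _rater_pairs(np.asarray(images, float), np.asarray(rater_masks))
    pos_weight = pos_weight_from_labels(y_all)
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.params(), lr=config.learning_rate)
    log: list[dict] = []
    n = x_all.shape[0]

    def epoch_pass(phase: str, epoch: int):
        perm = rng.permutation(n)
        total = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            x, y = x_all[idx], y_all[idx]
            outs = model.forward(x, train=True)
            npix = y.size
            loss = 0.0
            grads = []
            for tau, f in zip(levels, outs):
                s = _sigmoid(f)
                if phase == "warmup":
                    loss += float(
                        np.mean(
                            pos_weight * y * _softplus(-f) + (1 - y) * _softplus(f)
                        )
                    )
                    grads.append(
                        (pos_weight * y * (s - 1.0) + (1 - y) * s) / npix
                    )
                else:
                    coeff = y - (1.0 - tau)
                    loss -= float(np.mean(coeff * s))
                    grads.append(-(coeff * s * (1.0 - s)) / npix)
            if not np.isfinite(loss):
                raise TrainingDivergedError(f"non-finite loss in {phase} epoch {epoch}")
            opt.zero_grad()
            model.backward(grads)
            opt.step()
            total += loss
            n_batches += 1
        log.append({"epoch": epoch, "phase": phase, "loss": total / n_batches})

    epoch = 0
    if warmup:
        for _ in range(warmup_epochs):
            epoch_pass("warmup", epoch)
            epoch += 1
    for _ in range(config.epochs):
        epoch_pass("bqr", epoch)
        epoch += 1

    logits = model.predict_logits(np.asarray(images, float))
    trivial = bool(np.all(logits < 0))
    log.append({"event": "final", "trivial_solution": trivial,
                "pos_weight": float(pos_weight)})
    _write_log(log, log_path)
    return model, log


def train_unet_bce(
    images: np.ndarray,
    rater_masks: np.ndarray,
    config: TrainConfig,
    model: MultiHeadUNet | None = None,
    warmup: bool = True,
    log_path=None,
) -> tuple[MultiHeadUNet, list[dict]]:
    """Baseline: single-head U-Net trained with (warm-up weighted, then plain)
    binary cross-entropy on the same (image, rater mask) pairs. Its sigmoid
    probability map is thresholded at the quantile levels for comparison."""
    if model is None:
        c = config.image_shape[0]
        model = MultiHeadUNet(c, 1, base=8, seed=config.seed)
    x_all, y_all = _rater_pairs(np.asarray(images, float), np.asarray(rater_masks))
    pos_weight = pos_weight_from_labels(y_all)
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.params(), lr=config.learning_rate)
    log: list[dict] = []
    n = x_all.shape[0]
    for epoch in range(config.epochs + (1 if warmup else 0)):
        w = pos_weight if (warmup and epoch == 0) else 1.0
        phase = "warmup" if (warmup and epoch == 0) else "bce"
        perm = rng.permutation(n)
        total = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            x, y = x_all[idx], y_all[idx]
            (f,) = model.forward(x, train=True)
            s = _sigmoid(f)
            loss = float(np.mean(w * y * _softplus(-f) + (1 - y) * _softplus(f)))
            if not np.isfinite(loss):
                raise TrainingDivergedError(f"non-finite loss in epoch {epoch}")
            grad = (w * y * (s - 1.0) + (1 - y) * s) / y.size
            opt.zero_grad()
            model.backward([grad])
            opt.step()
            total += loss
            n_batches += 1
        log.append({"epoch": epoch, "phase": phase, "loss": total / n_batches})
    logits = model.predict_logits(np.asarray(images, float))
    log.append({"event": "final", "trivial_solution": bool(np.all(logits < 0)),
                "pos_weight": float(pos_weight)})
    _write_log(log, log_path)
    return model, log


def _softplus(t):
    return np.maximum(t, 0.0) + np.log1p(np.exp(-np.abs(t)))


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------


def _model_bn_layers(model) -> list[nn.BatchNorm2d]:
    if isinstance(model, VAE):
        parts = (model.enc_body, model.dec_trunk, *model.heads)
    elif isinstance(model, MultiHeadUNet):
        parts = (*model._bodies(), *model.heads)
    else:
        return []
    return [bn for part in parts for bn in _collect_bn(part)]


def save_params(model, path) -> None:
    """Save all trainable parameters plus batch-norm running statistics
    (ordered) to an .npz checkpoint."""
    arrays = {f"p{i}": p.value for i, p in enumerate(model.params())}
    for i, bn in enumerate(_model_bn_layers(model)):
        arrays[f"bn{i}_mean"] = bn.running_mean
        arrays[f"bn{i}_var"] = bn.running_var
    np.savez(path, **arrays)


def load_params(model, path) -> None:
    """Load a checkpoint saved by :func:`save_params` into a same-shape model."""
    data = np.load(path)
    params = model.params()
    n_p = sum(1 for k in data.files if k.startswith("p"))
    if n_p != len(params):
        raise ValueError("checkpoint/model parameter count mismatch")
    for i, p in enumerate(params):
        val = data[f"p{i}"]
        if val.shape != p.value.shape:
            raise ValueError(f"parameter {i} shape mismatch")
        p.value[...] = val
    for i, bn in enumerate(_model_bn_layers(model)):
        if f"bn{i}_mean" in data.files:
            bn.running_mean = data[f"bn{i}_mean"].copy()
            bn.running_var = data[f"bn{i}_var"].copy()
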