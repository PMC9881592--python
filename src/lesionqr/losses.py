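"""Objective functions: pinball / multi-quantile losses, Gaussian VAE terms,
the smoothed binary-quantile objective, and weighted cross-entropy.

All losses are pure numpy functions of arrays; the training loops in
:mod:`lesionqr.models` differentiate them analytically. Reduction convention
throughout: mean over batch and pixels, sum over quantile levels (and, for the
KL term, sum over latent dimensions, mean over the batch).
"""

from __future__ import annotations

import logging

import numpy as np

from lesionqr.fields import GaussianField, QuantilePredictionField, check_levels

logger = logging.getLogger(__name__)

#: default relative floor on predicted sigma (fraction of the data range [0,1])
SIGMA_FLOOR = 1e-4


def _reduce(values: np.ndarray, reduction: str) -> float | np.ndarray:
    if reduction == "mean":
        return float(values.mean())
    if reduction == "sum":
        return float(values.sum())
    if reduction == "none":
        return values
    raise ValueError(f"unknown reduction {reduction!r}")


def pinball_loss(residual, alpha: float, reduction: str = "mean"):
    """Check (pinball) loss of a residual ``r = y - f(x)`` at level ``alpha``.

    ``alpha * r`` where ``r > 0``, else ``(1 - alpha) * (-r)``; elementwise
    non-negative, convex and piecewise linear in ``r``. The expected-risk
    minimizer over constants is the ``alpha``-quantile of ``y``.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    r = np.asarray(residual, dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValueError("pinball_loss: residual contains non-finite values")
    loss = np.where(r > 0, alpha * r, (alpha - 1.0) * r)
    return _reduce(loss, reduction)


def pinball_grad(residual, alpha: float) -> np.ndarray:
    """d pinball / d prediction for residual ``r = y - f``: ``-alpha`` on the
    positive branch, ``1 - alpha`` on the negative one, 0 at ``r == 0``."""
    r = np.asarray(residual, dtype=float)
    return np.where(r > 0, -alpha, np.where(r < 0, 1.0 - alpha, 0.0))


def multi_quantile_loss(
    target, predictions: QuantilePredictionField, reduction: str = "mean"
):
    """Joint reconstruction loss: sum over levels of the pinball loss between
    the target and each level's map. There is no cross-level interaction term;
    each level's map is penalized independently."""
    x = np.asarray(target, dtype=float)
    total = 0.0
    for alpha, qmap in zip(predictions.levels, predictions.maps):
        if qmap.shape != x.shape:
            raise ValueError(
                f"prediction shape {qmap.shape} != target shape {x.shape}"
            )
        total = total + pinball_loss(x - qmap, alpha, reduction=reduction)
    return total


def gaussian_nll(
    target,
    field: GaussianField,
    sigma_floor: float = SIGMA_FLOOR,
    reduction: str = "mean",
):
    """Per-pixel Gaussian negative log-likelihood, up to the additive
    ``log(2*pi)/2`` constant: ``log(sigma) + (x - mu)^2 / (2 sigma^2)``.

    ``sigma`` is clamped below at ``sigma_floor``; clamping events are counted
    and logged, since a collapsing sigma is the variance-shrinkage failure
    mode this package exists to expose.
    """
    x = np.asarray(target, dtype=float)
    if x.shape != field.mean.shape:
        raise ValueError("target/field shape mismatch")
    sigma = field.sigma
    n_clamped = int(np.sum(sigma < sigma_floor))
    if n_clamped:
        logger.warning("gaussian_nll: clamped %d sigma values to floor", n_clamped)
        sigma = np.maximum(sigma, sigma_floor)
    nll = np.log(sigma) + (x - field.mean) ** 2 / (2.0 * sigma**2)
    return _reduce(nll, reduction)


def kl_standard_normal(mu_enc, logvar_enc, reduction: str = "mean"):
    """KL divergence of a diagonal Gaussian posterior from N(0, I):
    ``0.5 * sum_d (mu^2 + sigma^2 - log sigma^2 - 1)``, summed over the latent
    dimension (last axis), then reduced over the batch."""
    mu = np.atleast_2d(np.asarray(mu_enc, dtype=float))
    lv = np.atleast_2d(np.asarray(logvar_enc, dtype=float))
    if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(lv))):
        raise ValueError("kl_standard_normal: non-finite input")
    per_sample = 0.5 * np.sum(mu**2 + np.exp(lv) - lv - 1.0, axis=-1)
    return _reduce(per_sample, reduction)


def bqr_objective(labels, logits, levels, reduction: str = "mean"):
    """Smoothed binary-quantile-regression loss (negated objective).

    For level ``tau`` the objective rewards ``sum_i [y_i - (1 - tau)] *
    K(f_tau(x_i))`` with ``K`` the sigmoid smoothing of the indicator; the
    returned value is its negation so that minimization trains the network.
    Levels are independent and summed.
    """
    levels = check_levels(levels)
    y = np.asarray(labels, dtype=float)
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("bqr_objective: labels must be binary {0,1}")
    logits = np.asarray(logits, dtype=float)
    if logits.shape[0] != len(levels):
        raise ValueError("one logit map per level required")
    total = 0.0
    for tau, f in zip(levels, logits):
        if f.shape != y.shape:
            raise ValueError("logit/label shape mismatch")
        k = _sigmoid(f)
        contrib = (y - (1.0 - tau)) * k
        total = total - _reduce(contrib, reduction)
    return total


def weighted_bce(labels, logits, pos_weight: float, reduction: str = "mean"):
    """Binary cross-entropy on logits with a positive-class weight.

    ``pos_weight * y * softplus(-f) + (1 - y) * softplus(f)``; with
    ``pos_weight = 1`` this is the plain BCE.
    """
    if pos_weight <= 0:
        raise ValueError("pos_weight must be positive")
    y = np.asarray(labels, dtype=float)
    f = np.asarray(logits, dtype=float)
    if y.shape != f.shape:
        raise ValueError("label/logit shape mismatch")
    loss = pos_weight * y * _softplus(-f) + (1.0 - y) * _softplus(f)
    return _reduce(loss, reduction)


def pos_weight_from_labels(labels) -> float:
    """Positive-class weight from a training label set: (#zeros + 1)/(#ones + 1).

    The additive smoothing keeps degenerate all-one / all-zero label sets
    usable. Computed from data rather than hard-coded because the class ratio
    is a property of the dataset, not of the method.
    """
    y = np.asarray(labels)
    n_ones = float(np.sum(y == 1))
    n_zeros = float(y.size - n_ones)
    return (n_zeros + 1.0) / (n_ones + 1.0)


def _sigmoid(t: np.ndarray) -> np.ndarray:
    out = np.empty_like(t, dtype=float)
    pos = t >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-t[pos]))
    e = np.exp(t[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _softplus(t: np.ndarray) -> np.ndarray:
    # log(1 + e^t), overflow-safe
    return np.maximum(t, 0.0) + np.log1p(np.exp(-np.abs(t)))
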