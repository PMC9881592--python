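"""From model outputs to lesion calls and metrics.

Two unsupervised detection routes:

* model-free — flag pixels whose intensity falls outside the predicted
  ``[Q_low, Q_high]`` interval (nominal per-pixel false-positive rate
  ``1 - (high - low)``);
* Gaussian — convert the (median, low-quantile) pair to a per-pixel
  (mean, sigma), z-score the image, median-filter, convert to two-sided
  p-values and threshold with Benjamini-Hochberg FDR control.

Plus the evaluation metrics (Dice, rank AUC) and the multi-rater agreement
machinery for the supervised task.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage, stats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

from lesionqr.fields import AgreementMap, AnomalyResult, GaussianField, check_levels
from lesionqr.losses import SIGMA_FLOOR, _sigmoid

logger = logging.getLogger(__name__)

#: |Phi^{-1}(0.15)|: number of standard deviations between the median and the
#: 0.15 quantile of a Gaussian (about 1.036; carried at double precision).
GAUSS_Q15_CONSTANT = float(-stats.norm.ppf(0.15))


def quantile_spread_constant(low_level: float) -> float:
    """|Phi^{-1}(low_level)|: sigma multiplier between median and low quantile."""
    if not (0.0 < low_level < 0.5):
        raise ValueError("low_level must be in (0, 0.5)")
    return float(-stats.norm.ppf(low_level))


def quantiles_to_gaussian(
    q_mid: np.ndarray,
    q_low: np.ndarray,
    low_level: float = 0.15,
    sigma_floor: float = SIGMA_FLOOR,
) -> GaussianField:
    """Convert (median, low-quantile) maps to a per-pixel Gaussian law.

    ``mu = Q_0.5`` and ``sigma = (Q_0.5 - Q_low) / |Phi^-1(low_level)|``.
    Pixels where the quantiles cross (``q_low > q_mid``) get the sigma floor;
    the crossing count is logged.
    """
    q_mid = np.asarray(q_mid, dtype=float)
    q_low = np.asarray(q_low, dtype=float)
    if q_mid.shape != q_low.shape:
        raise ValueError("quantile map shapes differ")
    c = quantile_spread_constant(low_level)
    spread = (q_mid - q_low) / c
    n_crossed = int(np.sum(spread <= 0))
    if n_crossed:
        logger.warning(
            "quantiles_to_gaussian: %d crossed/degenerate pixels floored", n_crossed
        )
    sigma = np.maximum(spread, sigma_floor)
    return GaussianField(mean=q_mid, sigma=sigma)


def zscore_map(x: np.ndarray, field: GaussianField) -> np.ndarray:
    """Standardize intensities against the per-pixel law: (x - mu) / sigma."""
    x = np.asarray(x, dtype=float)
    if x.shape != field.mean.shape:
        raise ValueError("image/field shape mismatch")
    return (x - field.mean) / field.sigma


def pvalue_map(z: np.ndarray) -> np.ndarray:
    """Two-sided standard-normal p-values: ``2 (1 - Phi(|z|))``, in (0, 1].

    Two-sided because lesions may be hypo- or hyper-intense depending on the
    imaging contrast.
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite z-scores")
    return np.minimum(2.0 * stats.norm.sf(np.abs(z)), 1.0)


def bh_fdr(p: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up at level ``alpha``.

    Returns ``(mask, cutoff)`` where ``mask`` rejects every ``p <= cutoff``
    with ``cutoff = p_(k)``, ``k = max{i : p_(i) <= i * alpha / m}``; the
    cutoff is 0.0 (empty mask) when no index qualifies.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value array")
    flat = p.ravel()
    reject, *_ = multipletests(flat, alpha=alpha, method="fdr_bh")
    cutoff = float(flat[reject].max()) if reject.any() else 0.0
    return reject.reshape(p.shape), cutoff


def model_free_detect(
    x: np.ndarray, q_low: np.ndarray, q_high: np.ndarray
) -> np.ndarray:
    """Flag pixels outside the predicted interval: ``(x < Q_L) | (x > Q_H)``."""
    x = np.asarray(x, dtype=float)
    q_low = np.asarray(q_low, dtype=float)
    q_high = np.asarray(q_high, dtype=float)
    n_crossed = int(np.sum(q_high < q_low))
    if n_crossed:
        logger.warning("model_free_detect: %d pixels with crossed quantiles", n_crossed)
    return (x < q_low) | (x > q_high)


def median_filter(z: np.ndarray, window: int = 7) -> np.ndarray:
    """Square median filter with reflect boundary handling."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    return ndimage.median_filter(np.asarray(z, dtype=float), size=window, mode="reflect")


def gaussian_detect(
    x: np.ndarray,
    field: GaussianField,
    alpha_fdr: float = 0.05,
    filter_window: int = 7,
    interval: tuple[np.ndarray, np.ndarray] | None = None,
) -> AnomalyResult:
    """Full Gaussian detection pipeline for one image: z-score, median filter,
    two-sided p-values, per-image BH thresholding."""
    z = zscore_map(x, field)
    if filter_window > 1:
        z = median_filter(z, filter_window)
    p = pvalue_map(z)
    mask, cutoff = bh_fdr(p, alpha_fdr)
    if interval is not None:
        imask = model_free_detect(x, interval[0], interval[1])
    else:
        imask = np.zeros_like(mask)
    return AnomalyResult(
        z=z, p=p, fdr_mask=mask, interval_mask=imask,
        alpha_fdr=alpha_fdr, bh_cutoff=cutoff,
    )


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap ``2|a & b| / (|a| + |b|)``; defined as 1.0 when both masks
    are empty (degenerate agreement; logged when triggered)."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    denom = a.sum() + b.sum()
    if denom == 0:
        logger.debug("dice: both masks empty, returning 1.0")
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def auc_score(score: np.ndarray, truth: np.ndarray) -> float:
    """Rank-based area under the ROC curve of a score map against binary truth."""
    truth = np.asarray(truth).astype(int).ravel()
    score = np.asarray(score, dtype=float).ravel()
    if truth.min() == truth.max():
        raise ValueError("truth must contain both classes")
    return float(roc_auc_score(truth, score))


def agreement_map(rater_masks) -> AgreementMap:
    """Per-pixel fraction of raters labeling lesion; k raters give values in
    multiples of 1/k, and regions {fraction >= t} are nested in t."""
    masks = [np.asarray(m).astype(bool) for m in rater_masks]
    if len(masks) < 1:
        raise ValueError("need at least one rater mask")
    shape = masks[0].shape
    if any(m.shape != shape for m in masks):
        raise ValueError("rater mask shapes differ")
    frac = np.mean(np.stack(masks, axis=0), axis=0)
    return AgreementMap(fraction=frac, n_raters=len(masks))


def quantile_regions(
    predictions: np.ndarray, levels, mode: str = "bqr"
) -> dict[float, np.ndarray]:
    """Per-level binary masks from network outputs.

    ``mode="bqr"``: ``predictions`` holds one logit map per level; each is
    binarized at sigmoid >= 0.5 (i.e. logit >= 0, boundary included).
    ``mode="baseline"``: ``predictions`` is a single probability map,
    thresholded (>=) at each level.
    """
    levels = check_levels(levels)
    preds = np.asarray(predictions, dtype=float)
    if mode == "bqr":
        if preds.shape[0] != len(levels):
            raise ValueError("one logit map per level required")
        return {tau: _sigmoid(f) >= 0.5 for tau, f in zip(levels, preds)}
    if mode == "baseline":
        return {tau: preds >= tau for tau in levels}
    raise ValueError(f"unknown mode {mode!r}")


def nesting_violation_fraction(
    regions: dict[float, np.ndarray], levels
) -> float:
    """Fraction of pixels violating region nesting across increasing levels.

    For binary-quantile heads the region at a higher level must contain the
    region at a lower one (the estimated quantile is monotone in the level);
    violations are reported, never silently repaired.
    """
    levels = check_levels(levels)
    violated = 0
    total = 0
    for lo, hi in zip(levels, levels[1:]):
        violated += int(np.sum(regions[lo] & ~regions[hi]))
        total += regions[lo].size
    return violated / total if total else 0.0


def level_agreement_threshold(tau: float, n_raters: int = 4) -> float:
    """Ground-truth agreement threshold matched to BQR level ``tau``.

    The tau-quantile of a binary label is 1 exactly where
    ``P(Y=1|X) > 1 - tau``; on a k-rater grid that is the smallest multiple of
    1/k strictly above ``1 - tau``.
    """
    grid = np.arange(1, n_raters + 1) / n_raters
    above = grid[grid > 1.0 - tau + 1e-12]
    if above.size == 0:
        return 1.0
    return float(above[0])


def per_level_dice(
    pred_regions: dict[float, np.ndarray],
    agreement: AgreementMap,
    levels,
) -> list[dict]:
    """Dice of each level's predicted region against the matched agreement
    region. Levels whose ground-truth region is empty are excluded from the
    Dice average and flagged (``excluded=True``)."""
    rows = []
    for tau in check_levels(levels):
        thr = level_agreement_threshold(tau, agreement.n_raters)
        truth = agreement.region(thr)
        excluded = not truth.any()
        rows.append(
            {
                "level": tau,
                "agreement_threshold": thr,
                "dice": float("nan") if excluded else dice(pred_regions[tau], truth),
                "excluded": excluded,
            }
        )
    return rows
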