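"""Conformalized quantile regression (CQR).

Split-conformal calibration of a predicted interval ``[Q_L, Q_H]``: on a
held-out calibration set, compute the two-sided conformity score
``E = max(Q_L - y, y - Q_H)`` and take its ``ceil((n+1)(1-miscoverage))``-th
order statistic as a single symmetric offset. The adjusted interval
``[Q_L - offset, Q_H + offset]`` has marginal coverage at least
``1 - miscoverage`` for exchangeable data, with no distributional assumption.
The offset may be negative: intervals that over-cover legitimately shrink.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np


@dataclass
class ConformalOffsets:
    """Calibrated interval adjustment.

    ``offset`` is a scalar in pooled mode or a per-pixel array in pixelwise
    mode; ``target_coverage = 1 - miscoverage``.
    """

    offset: float | np.ndarray
    target_coverage: float
    n_calibration: int

    def save(self, path) -> None:
        payload = {
            "target_coverage": self.target_coverage,
            "n_calibration": self.n_calibration,
            "offset": (
                self.offset.tolist()
                if isinstance(self.offset, np.ndarray)
                else float(self.offset)
            ),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "ConformalOffsets":
        with open(path) as fh:
            payload = json.load(fh)
        offset = payload["offset"]
        if isinstance(offset, list):
            offset = np.asarray(offset, dtype=float)
        return cls(
            offset=offset,
            target_coverage=payload["target_coverage"],
            n_calibration=payload["n_calibration"],
        )


def conformity_scores(
    q_low: np.ndarray, q_high: np.ndarray, targets: np.ndarray
) -> np.ndarray:
    """Two-sided CQR score ``E = max(Q_L - y, y - Q_H)`` per calibration pixel.

    Negative exactly where the target lies strictly inside the interval.
    """
    q_low = np.asarray(q_low, dtype=float)
    q_high = np.asarray(q_high, dtype=float)
    y = np.asarray(targets, dtype=float)
    if not (q_low.shape == q_high.shape == y.shape):
        raise ValueError("q_low, q_high and targets must share a shape")
    return np.maximum(q_low - y, y - q_high)


def min_calibration_size(miscoverage: float) -> int:
    """Smallest n for which the corrected empirical quantile exists."""
    return math.ceil(1.0 / miscoverage) - 1


def calibrate(
    scores: np.ndarray, miscoverage: float, axis: int | None = None
) -> ConformalOffsets:
    """Offset = the ``ceil((n+1)(1-miscoverage))``-th order statistic of the
    conformity scores (finite-sample corrected empirical quantile).

    ``axis=None`` pools all scores into one scalar offset (pixels treated as
    exchangeable); pass ``axis=0`` with a (n, ...) score stack for a per-pixel
    offset map.
    """
    if not (0.0 < miscoverage < 1.0):
        raise ValueError("miscoverage must be in (0,1)")
    scores = np.asarray(scores, dtype=float)
    if axis is None:
        scores = scores.ravel()
        axis = 0
    n = scores.shape[axis]
    n_min = min_calibration_size(miscoverage)
    if n < n_min:
        raise ValueError(
            f"need at least {n_min} calibration scores for "
            f"miscoverage={miscoverage}, got {n}"
        )
    k = math.ceil((n + 1) * (1.0 - miscoverage))
    if k > n:
        raise ValueError(
            f"corrected quantile index {k} exceeds n={n}; "
            f"need n >= {min_calibration_size(miscoverage)}"
        )
    ordered = np.sort(scores, axis=axis)
    offset = np.take(ordered, k - 1, axis=axis)
    if offset.ndim == 0:
        offset = float(offset)
    return ConformalOffsets(
        offset=offset,
        target_coverage=1.0 - miscoverage,
        n_calibration=int(n),
    )


def apply_offsets(
    q_low: np.ndarray,
    q_high: np.ndarray,
    offsets: ConformalOffsets,
    clip_range: tuple[float, float] | None = (0.0, 1.0),
) -> tuple[np.ndarray, np.ndarray, int]:
    """Widen (or shrink, if the offset is negative) the interval:
    ``[Q_L - offset, Q_H + offset]``.

    For image intensities the adjusted maps are clipped to ``clip_range``;
    the number of clipped pixels is returned (pass ``clip_range=None`` for
    unbounded targets).
    """
    q_low = np.asarray(q_low, dtype=float)
    q_high = np.asarray(q_high, dtype=float)
    lo = q_low - offsets.offset
    hi = q_high + offsets.offset
    n_clipped = 0
    if clip_range is not None:
        a, b = clip_range
        n_clipped = int(np.sum((lo < a) | (lo > b)) + np.sum((hi < a) | (hi > b)))
        lo = np.clip(lo, a, b)
        hi = np.clip(hi, a, b)
    return lo, hi, n_clipped
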