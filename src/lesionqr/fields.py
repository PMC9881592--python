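"""Shared array containers: quantile fields, Gaussian fields, detection results."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def check_levels(levels) -> tuple[float, ...]:
    """Validate a set of quantile levels: each in (0,1), strictly increasing."""
    levels = tuple(float(a) for a in levels)
    if len(levels) == 0:
        raise ValueError("need at least one quantile level")
    for a in levels:
        if not (0.0 < a < 1.0):
            raise ValueError(f"quantile level must be in (0,1), got {a}")
    if any(b <= a for a, b in zip(levels, levels[1:])):
        raise ValueError(f"quantile levels must be strictly increasing: {levels}")
    return levels


@dataclass
class QuantilePredictionField:
    """Per-pixel conditional-quantile maps for an ordered set of levels.

    ``maps`` has shape ``(n_levels, *image_shape)``; ``maps[i]`` estimates the
    ``levels[i]`` conditional quantile of the intensity at every pixel.
    """

    levels: tuple[float, ...]
    maps: np.ndarray

    def __post_init__(self) -> None:
        self.levels = check_levels(self.levels)
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.shape[0] != len(self.levels):
            raise ValueError(
                f"{self.maps.shape[0]} maps for {len(self.levels)} levels"
            )

    def __getitem__(self, level: float) -> np.ndarray:
        """Return the map for an exact level value."""
        for a, m in zip(self.levels, self.maps):
            if a == level:
                return m
        raise KeyError(level)

    def crossing_fraction(self) -> float:
        """Fraction of pixels where a higher level's map lies strictly below a
        lower level's map (quantile crossing)."""
        if len(self.levels) < 2:
            return 0.0
        crossed = self.maps[1:] < self.maps[:-1]
        return float(crossed.mean())

    def sorted(self) -> "QuantilePredictionField":
        """Monotone repair: sort the level values at each pixel (optional
        post-process; crossing is reported, not silently fixed, by default)."""
        return QuantilePredictionField(self.levels, np.sort(self.maps, axis=0))


@dataclass
class GaussianField:
    """Per-pixel Gaussian law: ``mean`` and strictly positive ``sigma``."""

    mean: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.mean.shape != self.sigma.shape:
            raise ValueError("mean and sigma shapes differ")
        if not np.all(self.sigma > 0):
            raise ValueError("sigma must be positive everywhere")


@dataclass
class AnomalyResult:
    """Outputs of the detection pipeline for one image."""

    z: np.ndarray
    p: np.ndarray
    fdr_mask: np.ndarray
    interval_mask: np.ndarray
    alpha_fdr: float
    bh_cutoff: float = float("nan")


@dataclass
class AgreementMap:
    """Per-pixel fraction of raters labeling a pixel as lesion."""

    fraction: np.ndarray
    n_raters: int = field(default=0)

    def region(self, threshold: float) -> np.ndarray:
        """Pixels with agreement fraction >= threshold; nested in threshold."""
        return self.fraction >= threshold
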