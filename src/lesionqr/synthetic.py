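"""Synthetic data generators with known ground truth.

Three families, each bit-reproducible under a fixed seed:

* the two-moon latent manifold mapped to four observed dimensions with
  heteroscedastic Gaussian noise — the density-estimation benchmark for
  comparing VAE and QR-VAE generative quality;
* lesion-free / lesioned multi-channel images drawn from a smooth, spatially
  varying per-pixel Gaussian law (a statistical stand-in for co-registered
  multi-contrast MRI slices), returning the exact law for oracle testing;
* k correlated rater masks per lesion, with disagreement concentrated at the
  lesion boundary, producing agreement fractions in multiples of 1/k.

Plus a k-nearest-neighbor KL-divergence estimator used to score generated
samples against the data distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import binary_dilation, binary_erosion, disk
from sklearn.datasets import make_moons
from sklearn.neighbors import NearestNeighbors

from lesionqr.fields import GaussianField

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Two-moon -> 4D heteroscedastic simulation
# ---------------------------------------------------------------------------


def two_moon_latents(
    n: int = 500, noise_sd: float = 0.05, seed: int = 0
) -> np.ndarray:
    """n points on two interleaved unit half-circles with Gaussian jitter."""
    if n < 1:
        raise ValueError("n must be >= 1")
    z, _ = make_moons(n_samples=n, noise=noise_sd or None, random_state=seed)
    return z


def _deterministic_4d(z: np.ndarray) -> np.ndarray:
    z1, z2 = z[:, 0], z[:, 1]
    return np.stack(
        [z1 - z2, z1**2 - 0.5 * z2, z1 * z2 - z1, z1 + z2], axis=1
    )


def noise_scales_4d(z: np.ndarray) -> np.ndarray:
    """Per-coordinate heteroscedastic noise standard deviations.

    Scales depend on the first latent coordinate only:
    ``(0.03 + 0.05(3 + z1), 0.03 + 0.03 z1^2, 0.03 + 0.05 z1^2,
    0.03 + 0.03 sqrt(0.02 + z1^2))``.
    """
    z1 = z[:, 0]
    return np.stack(
        [
            0.03 + 0.05 * (3.0 + z1),
            0.03 + 0.03 * z1**2,
            0.03 + 0.05 * z1**2,
            0.03 + 0.03 * np.sqrt(0.02 + z1**2),
        ],
        axis=1,
    )


def map_to_4d(z: np.ndarray, seed: int = 0, noise: bool = True) -> np.ndarray:
    """Map latent pairs to observed 4-vectors ``v = g(z) + eps * scale(z)``
    with ``eps`` standard normal, independently per coordinate."""
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite latents")
    v = _deterministic_4d(z)
    if noise:
        rng = np.random.default_rng(seed)
        v = v + rng.standard_normal(v.shape) * noise_scales_4d(z)
    return v


def two_moon_dataset(
    n: int = 500, noise_sd: float = 0.05, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Convenience wrapper: (latents (n,2), observations (n,4))."""
    z = two_moon_latents(n, noise_sd=noise_sd, seed=seed)
    return z, map_to_4d(z, seed=seed + 1)


# ---------------------------------------------------------------------------
# Synthetic images with a known per-pixel Gaussian law
# ---------------------------------------------------------------------------


@dataclass
class SyntheticImageLaw:
    """Exact generating law for an image batch.

    ``mean_field``/``sigma_field`` have shape (channels, H, W); each lesion in
    ``lesion_spec`` is ``(row, col, radius, intensity_shift)`` — a
    Gaussian-profile bump added to every channel inside the blob.
    """

    mean_field: np.ndarray
    sigma_field: np.ndarray
    lesion_spec: list[tuple[float, float, float, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        self.mean_field = np.asarray(self.mean_field, dtype=float)
        self.sigma_field = np.asarray(self.sigma_field, dtype=float)
        if self.mean_field.shape != self.sigma_field.shape:
            raise ValueError("mean/sigma field shapes differ")
        if not np.all(self.sigma_field > 0):
            raise ValueError("sigma_field must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mean_field.shape

    def truth_mask(self) -> np.ndarray:
        """(H, W) boolean mask of lesion support (distance <= radius)."""
        _, h, w = self.shape
        mask = np.zeros((h, w), dtype=bool)
        rr, cc = np.mgrid[0:h, 0:w]
        for row, col, radius, _ in self.lesion_spec:
            d2 = (rr - row) ** 2 + (cc - col) ** 2
            mask |= d2 <= radius**2
        return mask

    def lesion_profile(self) -> np.ndarray:
        """(H, W) additive intensity shift: Gaussian profile per blob."""
        _, h, w = self.shape
        bump = np.zeros((h, w))
        rr, cc = np.mgrid[0:h, 0:w]
        for row, col, radius, shift in self.lesion_spec:
            d2 = (rr - row) ** 2 + (cc - col) ** 2
            profile = shift * np.exp(-d2 / (2.0 * (radius / 2.0) ** 2))
            profile[d2 > (1.5 * radius) ** 2] = 0.0
            bump += profile
        return bump

    def field(self) -> GaussianField:
        """The exact lesioned per-pixel law (lesion shift folded into the mean)."""
        mean = self.mean_field + self.lesion_profile()[None]
        return GaussianField(mean=mean, sigma=self.sigma_field.copy())

    def quantile(self, level: float) -> np.ndarray:
        """Exact per-pixel quantile map of the lesion-free law."""
        from scipy.stats import norm

        return self.mean_field + norm.ppf(level) * self.sigma_field


def _smooth_field(shape, rng, low, high, smooth_sigma=6.0) -> np.ndarray:
    c, h, w = shape
    raw = rng.standard_normal((c, h, w))
    sm = np.stack([ndimage.gaussian_filter(r, smooth_sigma) for r in raw])
    sm -= sm.min()
    if sm.max() > 0:
        sm /= sm.max()
    return low + (high - low) * sm


def _random_lesion_spec(
    sigma_field: np.ndarray,
    n_lesions: int,
    rng: np.random.Generator,
    radius_range: tuple[float, float],
    shift_in_sigmas: float,
) -> list[tuple[float, float, float, float]]:
    lesions = []
    _, h, w = sigma_field.shape
    for _ in range(n_lesions):
        radius = rng.uniform(*radius_range)
        row = rng.uniform(radius + 1, h - radius - 1)
        col = rng.uniform(radius + 1, w - radius - 1)
        local_sigma = float(sigma_field[:, int(row), int(col)].mean())
        lesions.append((row, col, radius, shift_in_sigmas * local_sigma))
    return lesions


def default_image_law(
    shape: tuple[int, int, int] = (1, 32, 32),
    seed: int = 0,
    n_lesions: int = 0,
    mean_range: tuple[float, float] = (0.25, 0.75),
    sigma_range: tuple[float, float] = (0.04, 0.10),
    radius_range: tuple[float, float] = (3.0, 6.0),
    shift_in_sigmas: float = 4.0,
) -> SyntheticImageLaw:
    """Build a smooth random law: spatially varying mean and sigma fields,
    plus ``n_lesions`` randomly placed blobs with intensity shift
    ``shift_in_sigmas`` times the local sigma (hyper-intense; >= 3 sigma so
    detection operating points are meaningful)."""
    rng = np.random.default_rng(seed)
    mean_field = _smooth_field(shape, rng, *mean_range)
    sigma_field = _smooth_field(shape, rng, *sigma_range)
    lesions = _random_lesion_spec(
        sigma_field, n_lesions, rng, radius_range, shift_in_sigmas
    )
    return SyntheticImageLaw(mean_field, sigma_field, lesions, seed=seed)


def add_random_lesions(
    law: SyntheticImageLaw,
    n_lesions: int,
    seed: int,
    radius_range: tuple[float, float] = (3.0, 6.0),
    shift_in_sigmas: float = 4.0,
) -> SyntheticImageLaw:
    """A new law with the same mean/sigma fields but freshly placed lesion
    blobs — in-distribution anomalies on a trained model's data law."""
    rng = np.random.default_rng(seed)
    lesions = _random_lesion_spec(
        law.sigma_field, n_lesions, rng, radius_range, shift_in_sigmas
    )
    return SyntheticImageLaw(
        law.mean_field.copy(), law.sigma_field.copy(), lesions, seed=seed
    )


def generate_images(
    law: SyntheticImageLaw,
    n: int,
    seed: int | None = None,
    clip: bool = True,
) -> tuple[np.ndarray, np.ndarray, GaussianField]:
    """Draw n images from the law: ``mean + lesion_profile + sigma * noise``.

    Returns ``(images (n,C,H,W), truth_mask (H,W), lesion-free GaussianField)``.
    Images are clipped to [0,1] (clipping fraction logged) unless ``clip`` is
    False — tests that need the exact Gaussian law can disable it.
    """
    rng = np.random.default_rng(law.seed if seed is None else seed)
    mean = law.mean_field + law.lesion_profile()[None]
    noise = rng.standard_normal((n, *law.shape))
    images = mean[None] + law.sigma_field[None] * noise
    if clip:
        frac = float(np.mean((images < 0) | (images > 1)))
        if frac > 0:
            logger.info("generate_images: clipped %.4f of pixels to [0,1]", frac)
        images = np.clip(images, 0.0, 1.0)
    truth = law.truth_mask()
    return images, truth, GaussianField(law.mean_field.copy(), law.sigma_field.copy())


# ---------------------------------------------------------------------------
# Multi-rater annotation simulation
# ---------------------------------------------------------------------------


@dataclass
class RaterSimSpec:
    """Simulated annotator panel: k raters whose masks jitter the true lesion
    boundary by a per-rater morphological dilation/erosion of random radius
    (~|N(0, boundary_jitter)| pixels), and who miss the lesion entirely with
    probability ``miss_rate``."""

    k: int = 4
    boundary_jitter: float = 1.0
    miss_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not (0.0 <= self.miss_rate <= 1.0):
            raise ValueError("miss_rate must be in [0,1]")
        if self.boundary_jitter < 0:
            raise ValueError("boundary_jitter must be non-negative")


def simulate_raters(truth_mask: np.ndarray, spec: RaterSimSpec) -> list[np.ndarray]:
    """k rater masks around a true mask; agreement decays from core to
    boundary. A missing rater (probability ``miss_rate``) returns an empty
    mask; ``boundary_jitter = 0`` and ``miss_rate = 0`` reproduce the truth."""
    truth = np.asarray(truth_mask).astype(bool)
    rng = np.random.default_rng(spec.seed)
    masks = []
    for _ in range(spec.k):
        if rng.uniform() < spec.miss_rate:
            masks.append(np.zeros_like(truth))
            continue
        radius = int(round(abs(rng.normal(0.0, spec.boundary_jitter))))
        if radius == 0:
            masks.append(truth.copy())
            continue
        footprint = disk(radius)
        if rng.uniform() < 0.5:
            masks.append(binary_dilation(truth, footprint))
        else:
            masks.append(binary_erosion(truth, footprint))
    return masks


# ---------------------------------------------------------------------------
# k-NN KL-divergence estimator
# ---------------------------------------------------------------------------


def knn_kl_divergence(
    samples_p: np.ndarray,
    samples_q: np.ndarray,
    k: int = 1,
) -> float:
    """Sample-based KL(P || Q) from k-nearest-neighbor distances.

    ``(d/n) * sum_i log(nu_k(i) / rho_k(i)) + log(m / (n - 1))`` where
    ``rho_k`` is the k-NN radius of each P-sample within P (self excluded) and
    ``nu_k`` its k-NN radius within Q. Consistent as n, m grow; biased at
    finite n. Duplicate points yielding zero radii are tie-broken with a tiny
    jitter (logged).
    """
    p = np.atleast_2d(np.asarray(samples_p, dtype=float))
    q = np.atleast_2d(np.asarray(samples_q, dtype=float))
    if p.shape[1] != q.shape[1]:
        raise ValueError("sample sets must share a dimension")
    n, d = p.shape
    m = q.shape[0]
    if n <= k or m <= k:
        raise ValueError(f"need more than k={k} points in each set")
    rho = NearestNeighbors(n_neighbors=k + 1).fit(p).kneighbors(p)[0][:, k]
    nu = NearestNeighbors(n_neighbors=k).fit(q).kneighbors(p)[0][:, k - 1]
    zero = (rho == 0) | (nu == 0)
    if zero.any():
        logger.warning("knn_kl_divergence: %d zero radii jittered", int(zero.sum()))
        scale = 1e-10 * (1.0 + np.abs(p).max())
        rho = np.maximum(rho, scale)
        nu = np.maximum(nu, scale)
    return float(d * np.mean(np.log(nu / rho)) + np.log(m / (n - 1.0)))
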