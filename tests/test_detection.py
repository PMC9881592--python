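"""Detection-pipeline tests: quantile->Gaussian conversion, z/p maps, BH FDR,
model-free thresholding, filtering, metrics, agreement machinery."""

import numpy as np
import pytest
from scipy import stats

from lesionqr.detection import (
    GAUSS_Q15_CONSTANT,
    agreement_map,
    auc_score,
    bh_fdr,
    dice,
    gaussian_detect,
    level_agreement_threshold,
    median_filter,
    model_free_detect,
    per_level_dice,
    pvalue_map,
    quantile_regions,
    quantiles_to_gaussian,
    zscore_map,
)
from lesionqr.fields import GaussianField


class TestQuantilesToGaussian:
    def test_unit_sigma_from_printed_constant(self):
        """Median 0 and 0.15-quantile at -1.036 imply sigma = 1.000(1)."""
        gf = quantiles_to_gaussian(np.zeros((2, 2)), np.full((2, 2), -1.036))
        assert gf.mean == pytest.approx(np.zeros((2, 2)))
        assert gf.sigma == pytest.approx(np.ones((2, 2)), abs=1e-3)

    def test_degenerate_equal_quantiles_floored(self):
        q = np.full((3,), 0.4)
        gf = quantiles_to_gaussian(q, q, sigma_floor=1e-4)
        assert np.all(gf.sigma == 1e-4)

    def test_recovers_known_gaussian(self):
        """Exact quantiles of N(2, 0.5) invert to (mu, sigma) = (2, 0.5)."""
        mu, sigma = 2.0, 0.5
        q_mid = np.full((4,), stats.norm.ppf(0.5, mu, sigma))
        q_low = np.full((4,), stats.norm.ppf(0.15, mu, sigma))
        gf = quantiles_to_gaussian(q_mid, q_low)
        assert gf.mean == pytest.approx(np.full(4, mu))
        assert gf.sigma == pytest.approx(np.full(4, sigma), rel=1e-9)

    def test_constant_matches_normal_ppf(self):
        assert GAUSS_Q15_CONSTANT == pytest.approx(-stats.norm.ppf(0.15), abs=1e-12)


class TestZandP:
    def test_zscore_basics(self):
        field = GaussianField(np.full(3, 0.5), np.full(3, 0.1))
        assert zscore_map(np.full(3, 0.5), field) == pytest.approx(np.zeros(3))
        assert zscore_map(np.full(3, 0.6), field) == pytest.approx(np.ones(3))

    def test_zscore_toy_hand_arithmetic(self):
        field = GaussianField(np.array([0.0, 1.0, 2.0]), np.array([1.0, 2.0, 0.5]))
        x = np.array([1.0, 0.0, 3.0])
        assert zscore_map(x, field) == pytest.approx([1.0, -0.5, 2.0])

    def test_pvalues(self):
        assert pvalue_map(np.array([0.0])) == pytest.approx([1.0])
        assert pvalue_map(np.array([1.959964, -1.959964])) == pytest.approx(
            [0.05, 0.05], abs=1e-6
        )

    def test_pvalue_monotone_in_abs_z(self):
        z = np.array([0.1, -0.5, 1.0, -2.0, 3.0])
        p = pvalue_map(z)
        order = np.argsort(np.abs(z))
        assert np.all(np.diff(p[order]) <= 0)

    def test_affine_invariance_of_pipeline(self):
        """z (and hence p) is invariant to a joint affine rescaling of
        (x, mu, sigma)."""
        rng = np.random.default_rng(0)
        x = rng.uniform(size=(5, 5))
        mu = rng.uniform(size=(5, 5))
        sigma = rng.uniform(0.05, 0.2, size=(5, 5))
        a, b = 3.7, -1.2
        z1 = zscore_map(x, GaussianField(mu, sigma))
        z2 = zscore_map(a * x + b, GaussianField(a * mu + b, a * sigma))
        np.testing.assert_allclose(pvalue_map(z1), pvalue_map(z2), atol=1e-12)


def brute_force_bh(p, alpha):
    """Independent step-up oracle: max k with p_(k) <= k*alpha/m."""
    p = np.asarray(p, float).ravel()
    m = len(p)
    order = np.argsort(p)
    k_star = 0
    for i, idx in enumerate(order, start=1):
        if p[idx] <= i * alpha / m:
            k_star = i
    mask = np.zeros(m, bool)
    if k_star:
        mask[order[:k_star]] = True
    return mask


class TestBH:
    def test_all_ones_empty(self):
        mask, cutoff = bh_fdr(np.ones(10), 0.05)
        assert not mask.any() and cutoff == 0.0

    def test_hand_worked_stepup(self):
        """p = {.01,.02,.30,.04} at alpha=.05: thresholds i*.05/4; rejects
        exactly {.01,.02}."""
        mask, cutoff = bh_fdr(np.array([0.01, 0.02, 0.30, 0.04]), 0.05)
        np.testing.assert_array_equal(mask, [True, True, False, False])
        assert cutoff == pytest.approx(0.02)

    def test_matches_brute_force_on_small_inputs(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            m = rng.integers(1, 13)
            p = rng.uniform(size=m) ** rng.uniform(0.5, 3)
            mask, _ = bh_fdr(p, 0.05)
            np.testing.assert_array_equal(mask, brute_force_bh(p, 0.05))

    def test_superset_of_bonferroni(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            p = rng.uniform(size=40) ** 2
            bh_mask, _ = bh_fdr(p, 0.05)
            bonf = p <= 0.05 / p.size
            assert np.all(bh_mask[bonf])


class TestModelFree:
    def test_inside_and_single_pixel(self):
        x = np.full((3, 3), 0.5)
        lo, hi = np.full((3, 3), 0.2), np.full((3, 3), 0.8)
        assert not model_free_detect(x, lo, hi).any()
        x2 = x.copy()
        x2[1, 1] = 0.81
        mask = model_free_detect(x2, lo, hi)
        assert mask.sum() == 1 and mask[1, 1]

    def test_rate_matches_interval_on_exact_quantiles(self):
        """With the generator's exact (0.025, 0.975) quantiles the flagged
        fraction is 5% within 3 binomial standard errors."""
        rng = np.random.default_rng(3)
        n = 200_000
        mu, sigma = 0.5, 0.1
        x = rng.normal(mu, sigma, size=n)
        lo = np.full(n, stats.norm.ppf(0.025, mu, sigma))
        hi = np.full(n, stats.norm.ppf(0.975, mu, sigma))
        rate = model_free_detect(x, lo, hi).mean()
        se = np.sqrt(0.05 * 0.95 / n)
        assert abs(rate - 0.05) < 3 * se


class TestMedianFilter:
    def test_constant_unchanged(self):
        x = np.full((6, 6), 3.2)
        np.testing.assert_array_equal(median_filter(x, 3), x)

    def test_impulse_removed(self):
        x = np.zeros((7, 7))
        x[3, 3] = 10.0
        assert median_filter(x, 3).max() == 0.0

    def test_matches_brute_force_windows(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(5, 5))
        out = median_filter(x, 3)
        # scipy's "reflect" duplicates the edge sample (numpy's "symmetric")
        padded = np.pad(x, 1, mode="symmetric")
        for i in range(5):
            for j in range(5):
                window = padded[i : i + 3, j : j + 3]
                assert out[i, j] == pytest.approx(np.median(window))

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            median_filter(np.zeros((4, 4)), 4)


class TestMetrics:
    def test_dice_cases(self):
        a = np.zeros((4, 4), bool)
        a[:2] = True
        assert dice(a, a) == 1.0
        assert dice(a, ~a) == 0.0
        assert dice(np.zeros((2, 2), bool), np.zeros((2, 2), bool)) == 1.0

    def test_dice_counts(self):
        """|a|=4, |b|=6, overlap 3 -> 2*3/10 = 0.6."""
        a = np.zeros(12, bool)
        b = np.zeros(12, bool)
        a[:4] = True
        b[1:7] = True
        assert dice(a, b) == pytest.approx(0.6)

    def test_auc_extremes_and_null(self):
        truth = np.array([0, 0, 0, 1, 1])
        assert auc_score(np.array([0.1, 0.2, 0.3, 0.8, 0.9]), truth) == 1.0
        rng = np.random.default_rng(5)
        truth = rng.integers(0, 2, size=4000)
        score = rng.normal(size=4000)
        assert auc_score(score, truth) == pytest.approx(0.5, abs=0.05)

    def test_auc_matches_pair_counting_oracle(self):
        score = np.array([0.1, 0.4, 0.35, 0.8, 0.65, 0.2])
        truth = np.array([0, 0, 1, 1, 1, 0])
        conc = ties = 0
        pos = score[truth == 1]
        neg = score[truth == 0]
        for sp in pos:
            for sn in neg:
                conc += sp > sn
                ties += sp == sn
        expected = (conc + 0.5 * ties) / (len(pos) * len(neg))
        assert auc_score(score, truth) == pytest.approx(expected)

    def test_auc_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(6)
        score = rng.normal(size=100)
        truth = (rng.uniform(size=100) < 0.4).astype(int)
        assert auc_score(np.exp(score), truth) == pytest.approx(
            auc_score(score, truth)
        )

    def test_auc_single_class_errors(self):
        with pytest.raises(ValueError):
            auc_score(np.array([0.1, 0.2]), np.array([1, 1]))


class TestAgreement:
    def test_identical_raters(self):
        m = np.zeros((4, 4), bool)
        m[1:3, 1:3] = True
        am = agreement_map([m, m, m])
        assert set(np.unique(am.fraction)) <= {0.0, 1.0}

    def test_single_dissenter(self):
        base = np.zeros((3, 3), bool)
        solo = base.copy()
        solo[0, 0] = True
        am = agreement_map([solo, base, base, base])
        assert am.fraction[0, 0] == 0.25

    def test_region_nesting_on_random_masks(self):
        rng = np.random.default_rng(7)
        masks = [rng.uniform(size=(8, 8)) < 0.4 for _ in range(4)]
        am = agreement_map(masks)
        thresholds = [0.25, 0.5, 0.75, 1.0]
        regions = [am.region(t) for t in thresholds]
        for bigger, smaller in zip(regions, regions[1:]):
            assert np.all(bigger[smaller])  # higher threshold nested in lower


class TestQuantileRegions:
    def test_boundary_inclusion_convention(self):
        regions = quantile_regions(np.zeros((2, 3, 3)), (0.25, 0.75))
        assert regions[0.25].all() and regions[0.75].all()

    def test_baseline_thresholding(self):
        prob = np.full((2, 2), 0.4)
        regions = quantile_regions(prob, (0.125, 0.375, 0.625, 0.875), mode="baseline")
        assert regions[0.125].all() and regions[0.375].all()
        assert not regions[0.625].any() and not regions[0.875].any()

    def test_level_agreement_pairing(self):
        # tau-quantile of binary Y is 1 iff P(Y=1) > 1 - tau
        assert level_agreement_threshold(0.875) == 0.25
        assert level_agreement_threshold(0.625) == 0.5
        assert level_agreement_threshold(0.375) == 0.75
        assert level_agreement_threshold(0.125) == 1.0

    def test_nesting_violations_reported_not_fixed(self):
        from lesionqr.detection import nesting_violation_fraction

        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, 0] = True  # low-level region not contained in high-level one
        frac = nesting_violation_fraction({0.25: a, 0.75: b}, (0.25, 0.75))
        assert frac == pytest.approx(1 / 16)
        # nested regions -> zero violations
        b[0, 0] = True
        assert nesting_violation_fraction({0.25: a, 0.75: b}, (0.25, 0.75)) == 0.0

    def test_perfect_predictions_give_unit_dice(self):
        rng = np.random.default_rng(8)
        masks = [rng.uniform(size=(8, 8)) < 0.3 for _ in range(4)]
        am = agreement_map(masks)
        levels = (0.125, 0.375, 0.625, 0.875)
        preds = {
            tau: am.region(level_agreement_threshold(tau)) for tau in levels
        }
        rows = per_level_dice(preds, am, levels)
        for row in rows:
            if not row["excluded"]:
                assert row["dice"] == 1.0

    def test_empty_level_exclusion_bookkeeping(self):
        masks = [np.zeros((4, 4), bool) for _ in range(4)]
        masks[0][0, 0] = True  # agreement 0.25 at one pixel only
        am = agreement_map(masks)
        levels = (0.125, 0.375, 0.625, 0.875)
        preds = {tau: np.zeros((4, 4), bool) for tau in levels}
        rows = per_level_dice(preds, am, levels)
        by_level = {r["level"]: r for r in rows}
        assert not by_level[0.875]["excluded"]  # threshold 0.25 is non-empty
        for tau in (0.125, 0.375, 0.625):
            assert by_level[tau]["excluded"]
            assert np.isnan(by_level[tau]["dice"])


class TestGaussianDetectPipeline:
    def test_null_images_rarely_reject(self):
        """On in-distribution images BH at alpha=.05 keeps the mask empty with
        high probability (the null simulation property)."""
        rng = np.random.default_rng(9)
        field = GaussianField(np.full((32, 32), 0.5), np.full((32, 32), 0.08))
        n_reject = 0
        for _ in range(20):
            x = rng.normal(field.mean, field.sigma)
            res = gaussian_detect(x, field, alpha_fdr=0.05, filter_window=1)
            n_reject += res.fdr_mask.any()
        assert n_reject <= 3

    def test_fdr_mask_subset_of_cutoff(self):
        rng = np.random.default_rng(10)
        field = GaussianField(np.full((16, 16), 0.5), np.full((16, 16), 0.05))
        x = rng.normal(field.mean, field.sigma)
        x[:2, :2] += 0.5  # strong signal
        res = gaussian_detect(x, field, filter_window=1)
        if res.fdr_mask.any():
            assert np.all(res.p[res.fdr_mask] <= res.bh_cutoff)
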