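"""End-to-end experiment drivers.

Three reproducible experiments tie the modules together:

* ``run_simulation`` — two-moon 4D density estimation: train the Gaussian VAE
  and the QR-VAE on the same heteroscedastic data, ancestral-sample both, and
  score each against the data with the k-NN KL estimator;
* ``run_unsupervised`` — lesion detection on synthetic images: model-free
  interval thresholding and the Gaussian (z-score / median filter / BH-FDR)
  pipeline, each with and without conformal calibration, against the Gaussian
  VAE baseline;
* ``run_supervised`` — multi-rater lesion segmentation: BQR U-Net versus a
  cross-entropy U-Net, scored per quantile level against rater agreement maps
  with empty-level exclusion.

Every run writes its resolved configuration and seed next to its outputs and
never overwrites a previous run (a fresh ``run-NNN`` directory per call).
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from lesionqr import conformal, detection, models, synthetic
from lesionqr.fields import GaussianField

DEFAULT_LEVELS_BQR = (0.125, 0.375, 0.625, 0.875)


@dataclass
class ExperimentConfig:
    """Resolved configuration for one experiment run."""

    experiment: str = "simulation"
    outdir: str = "runs"
    seed: int = 0
    levels: tuple[float, ...] = DEFAULT_LEVELS_BQR
    miscoverage: float = 0.1
    fdr_alpha: float = 0.05
    # simulation scales
    n_points: int = 500
    n_generated: int = 1000
    # image-experiment scales (desk scale: 32x32 single-channel images)
    image_shape: tuple[int, int, int] = (1, 32, 32)
    n_train: int = 64
    n_calibration: int = 24
    n_test: int = 12
    warmup_epochs: int = 6
    train: models.TrainConfig = field(default_factory=models.TrainConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        train = d.pop("train", {})
        cfg = cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})
        if isinstance(train, dict):
            cfg.train = models.TrainConfig(**train)
        cfg.levels = tuple(cfg.levels)
        cfg.train.image_shape = tuple(cfg.train.image_shape)
        cfg.train.widths = tuple(cfg.train.widths)
        cfg.image_shape = tuple(cfg.image_shape)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def default_config(experiment: str, seed: int = 0, outdir: str = "runs") -> ExperimentConfig:
    """Desk-scale defaults tuned per experiment (the config file overrides)."""
    if experiment == "simulation":
        train = models.TrainConfig(
            latent_dim=2, epochs=400, learning_rate=3e-3, batch_size=64,
            seed=seed, kl_weight=0.1,
        )
        return ExperimentConfig(
            experiment=experiment, outdir=outdir, seed=seed, train=train
        )
    if experiment == "unsupervised":
        train = models.TrainConfig(
            latent_dim=16, epochs=60, learning_rate=2e-3, batch_size=16,
            seed=seed, image_shape=(1, 32, 32), widths=(16, 32, 64),
        )
        return ExperimentConfig(
            experiment=experiment, outdir=outdir, seed=seed, train=train
        )
    if experiment == "supervised":
        train = models.TrainConfig(
            epochs=30, learning_rate=3e-3, batch_size=8, seed=seed,
            image_shape=(1, 32, 32),
        )
        return ExperimentConfig(
            experiment=experiment, outdir=outdir, seed=seed,
            n_train=24, n_test=8, warmup_epochs=8, train=train,
        )
    raise ValueError(f"unknown experiment {experiment!r}")


def _new_run_dir(outdir) -> Path:
    """Create a fresh run-NNN directory; existing runs are never overwritten."""
    base = Path(outdir)
    base.mkdir(parents=True, exist_ok=True)
    for i in range(1, 10_000):
        candidate = base / f"run-{i:03d}"
        try:
            candidate.mkdir(exist_ok=False)
            return candidate
        except FileExistsError:
            continue
    raise RuntimeError("too many runs in output directory")


def _finalize(run_dir: Path, config: ExperimentConfig, report: dict) -> dict:
    report["run_dir"] = str(run_dir)
    report["seed"] = config.seed
    report["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    config.save(run_dir / "config.yaml")
    with open(run_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report


# ---------------------------------------------------------------------------
# Simulation: two-moon 4D density estimation
# ---------------------------------------------------------------------------


def run_simulation(config: ExperimentConfig, make_figures: bool = True) -> dict:
    """Train VAE and QR-VAE on the two-moon 4D data; compare generated-sample
    KL divergence against the data distribution."""
    run_dir = _new_run_dir(config.outdir)
    _, v = synthetic.two_moon_dataset(config.n_points, seed=config.seed)
    tcfg = config.train.with_(latent_dim=2, seed=config.seed)
    vae, vae_log = models.train_vae(v, tcfg, log_path=run_dir / "vae_log.jsonl")
    qr, qr_log = models.train_qrvae(
        v, (0.15, 0.5), tcfg, log_path=run_dir / "qrvae_log.jsonl"
    )
    rng = np.random.default_rng(config.seed + 10_000)
    samples_vae = vae.sample(config.n_generated, rng)
    samples_qr = qr.sample(config.n_generated, rng)
    kl_vae = synthetic.knn_kl_divergence(v, samples_vae)
    kl_qr = synthetic.knn_kl_divergence(v, samples_qr)
    if make_figures:
        _pairwise_figure(
            run_dir / "pairwise.png",
            {"data": v, "VAE": samples_vae, "QR-VAE": samples_qr},
        )
    report = {
        "experiment": "simulation",
        "n_points": config.n_points,
        "n_generated": config.n_generated,
        "kl_vae": float(kl_vae),
        "kl_qrvae": float(kl_qr),
        "final_vae_loss": vae_log[-1]["loss"],
        "final_qrvae_loss": qr_log[-1]["loss"],
    }
    return _finalize(run_dir, config, report)


def _pairwise_figure(path, sample_sets: dict) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pairs = [(0, 1), (1, 2)]
    fig, axes = plt.subplots(
        len(pairs), len(sample_sets), figsize=(3 * len(sample_sets), 6)
    )
    axes = np.atleast_2d(axes)
    for col, (name, s) in enumerate(sample_sets.items()):
        for row, (i, j) in enumerate(pairs):
            ax = axes[row, col]
            ax.scatter(s[:, i], s[:, j], s=3, alpha=0.4)
            ax.set_xlabel(f"v{i + 1}")
            ax.set_ylabel(f"v{j + 1}")
            if row == 0:
                ax.set_title(name)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Unsupervised lesion detection
# ---------------------------------------------------------------------------

UNSUPERVISED_VARIANTS = (
    "VAE",
    "QR-VAE",
    "QR-VAE-conf",
    "QR-VAE-GS",
    "QR-VAE-GS-conf",
)


def _test_set(config: ExperimentConfig, law, base_seed: int):
    """Lesioned test images drawn from the training law (same mean/sigma
    fields; lesion placement varies per image)."""
    images, truths = [], []
    for i in range(config.n_test):
        lesioned = synthetic.add_random_lesions(
            law, n_lesions=1 + i % 2, seed=base_seed + i
        )
        img, truth, _ = synthetic.generate_images(
            lesioned, 1, seed=base_seed + 500 + i
        )
        images.append(img[0])
        truths.append(truth)
    return np.array(images), np.array(truths)


def _sigma_from_conformal_interval(
    gf: GaussianField, offset: float, interval_mass: float = 0.95
) -> GaussianField:
    """Fold a conformal widening of the implied central interval back into
    sigma: half-width grows by the offset, so sigma grows by offset/z_(a)."""
    from scipy.stats import norm

    zval = norm.ppf(0.5 + interval_mass / 2.0)
    return GaussianField(gf.mean, np.maximum(gf.sigma + offset / zval, 1e-6))


def run_unsupervised(config: ExperimentConfig, models_cache: dict | None = None) -> dict:
    """Synthetic unsupervised lesion-detection benchmark over the five method
    variants (Gaussian VAE; model-free QR-VAE with/without conformalization;
    Gaussian-converted QR-VAE with/without conformalization)."""
    run_dir = _new_run_dir(config.outdir)
    law = synthetic.default_image_law(config.image_shape, seed=config.seed)
    train_imgs, _, _ = synthetic.generate_images(law, config.n_train, seed=config.seed + 1)
    cal_imgs, _, _ = synthetic.generate_images(
        law, config.n_calibration, seed=config.seed + 2
    )
    test_imgs, test_truths = _test_set(config, law, config.seed + 1000)

    tcfg = config.train.with_(image_shape=config.image_shape, seed=config.seed)
    cache = models_cache if models_cache is not None else {}
    if "qr_mf" not in cache:
        cache["qr_mf"], _ = models.train_qrvae(
            train_imgs, (0.025, 0.975), tcfg, log_path=run_dir / "qr_mf_log.jsonl"
        )
    if "qr_gs" not in cache:
        cache["qr_gs"], _ = models.train_qrvae(
            train_imgs, (0.15, 0.5), tcfg, log_path=run_dir / "qr_gs_log.jsonl"
        )
    if "vae" not in cache:
        cache["vae"], _ = models.train_vae(
            train_imgs, tcfg, log_path=run_dir / "vae_log.jsonl"
        )
    qr_mf, qr_gs, vae = cache["qr_mf"], cache["qr_gs"], cache["vae"]

    # conformal calibration of the model-free interval
    qf_cal = qr_mf.predict_quantiles(cal_imgs)
    scores = conformal.conformity_scores(qf_cal[0.025], qf_cal[0.975], cal_imgs)
    offsets_mf = conformal.calibrate(scores, miscoverage=0.05)
    offsets_mf.save(run_dir / "conformal_mf.json")

    # conformal calibration of the Gaussian pipeline's implied 95% interval
    qf_cal_gs = qr_gs.predict_quantiles(cal_imgs)
    gf_cal = detection.quantiles_to_gaussian(qf_cal_gs[0.5], qf_cal_gs[0.15])
    lo = gf_cal.mean - 1.959964 * gf_cal.sigma
    hi = gf_cal.mean + 1.959964 * gf_cal.sigma
    offsets_gs = conformal.calibrate(
        conformal.conformity_scores(lo, hi, cal_imgs), miscoverage=0.05
    )
    offsets_gs.save(run_dir / "conformal_gs.json")

    rows = []
    for i, (x, truth) in enumerate(zip(test_imgs, test_truths)):
        x1 = x[None]
        truth_any = bool(truth.any())
        qf = qr_mf.predict_quantiles(x1)
        # model-free (masks are reduced over channels: any channel flags)
        mask = detection.model_free_detect(x1, qf[0.025], qf[0.975])[0].any(axis=0)
        rows.append(_unsup_row(i, "QR-VAE", mask, None, truth, truth_any))
        lo_i, hi_i, _ = conformal.apply_offsets(qf[0.025], qf[0.975], offsets_mf)
        mask_c = detection.model_free_detect(x1, lo_i, hi_i)[0].any(axis=0)
        rows.append(_unsup_row(i, "QR-VAE-conf", mask_c, None, truth, truth_any))
        # gaussian from quantiles
        qfg = qr_gs.predict_quantiles(x1)
        gf = detection.quantiles_to_gaussian(qfg[0.5], qfg[0.15])
        res = detection.gaussian_detect(x1, gf, alpha_fdr=config.fdr_alpha)
        rows.append(
            _unsup_row(i, "QR-VAE-GS", res.fdr_mask[0].any(axis=0),
                       np.abs(res.z[0]).max(axis=0), truth, truth_any)
        )
        gf_c = _sigma_from_conformal_interval(gf, offsets_gs.offset)
        res_c = detection.gaussian_detect(x1, gf_c, alpha_fdr=config.fdr_alpha)
        rows.append(
            _unsup_row(i, "QR-VAE-GS-conf", res_c.fdr_mask[0].any(axis=0),
                       np.abs(res_c.z[0]).max(axis=0), truth, truth_any)
        )
        # Gaussian VAE baseline
        gfv = vae.predict_gaussian(x1)
        res_v = detection.gaussian_detect(x1, gfv, alpha_fdr=config.fdr_alpha)
        rows.append(
            _unsup_row(i, "VAE", res_v.fdr_mask[0].any(axis=0),
                       np.abs(res_v.z[0]).max(axis=0), truth, truth_any)
        )

    df = pd.DataFrame(rows)
    df.to_csv(run_dir / "per_image_metrics.csv", index=False)
    summary = (
        df.groupby("method")[["dice", "auc"]].mean(numeric_only=True).reset_index()
    )
    summary.to_csv(run_dir / "summary.csv", index=False)
    _write_table_markdown(run_dir / "report.md", summary)
    report = {
        "experiment": "unsupervised",
        "summary": {
            r["method"]: {"dice": r["dice"], "auc": r["auc"]}
            for r in summary.to_dict("records")
        },
        "conformal_offset_model_free": float(offsets_mf.offset),
        "conformal_offset_gaussian": float(offsets_gs.offset),
    }
    return _finalize(run_dir, config, report)


def _unsup_row(i, method, mask, z, truth, truth_any):
    row = {
        "image_id": i,
        "method": method,
        "dice": detection.dice(mask, truth),
        "auc": np.nan,
        "mask_fraction": float(np.mean(mask)),
    }
    if z is not None and truth_any:
        row["auc"] = detection.auc_score(z, truth)
    return row


def _write_table_markdown(path, summary: pd.DataFrame) -> None:
    lines = ["| method | dice | auc |", "|---|---|---|"]
    for r in summary.to_dict("records"):
        auc = "n/a" if np.isnan(r["auc"]) else f"{r['auc']:.3f}"
        lines.append(f"| {r['method']} | {r['dice']:.3f} | {auc} |")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Supervised multi-rater segmentation
# ---------------------------------------------------------------------------


def make_rater_dataset(
    config: ExperimentConfig,
    n_images: int,
    seed: int,
    rater_spec: synthetic.RaterSimSpec | None = None,
):
    """(images (n,C,H,W), rater masks (n,k,H,W)) with per-image lesions."""
    spec = rater_spec or synthetic.RaterSimSpec(
        k=4, boundary_jitter=1.5, miss_rate=0.1, seed=seed
    )
    images, mask_sets = [], []
    for i in range(n_images):
        law = synthetic.default_image_law(
            config.image_shape, seed=seed + i, n_lesions=1
        )
        img, truth, _ = synthetic.generate_images(law, 1, seed=seed + 700 + i)
        images.append(img[0])
        spec_i = synthetic.RaterSimSpec(
            k=spec.k,
            boundary_jitter=spec.boundary_jitter,
            miss_rate=spec.miss_rate,
            seed=seed + 900 + i,
        )
        mask_sets.append(np.stack(synthetic.simulate_raters(truth, spec_i)))
    return np.array(images), np.array(mask_sets)


def run_supervised(config: ExperimentConfig, models_cache: dict | None = None) -> dict:
    """BQR U-Net vs cross-entropy U-Net on synthetic multi-rater data,
    scored per level against rater agreement maps (Dice with empty-level
    exclusion), plus the BQR-vs-baseline agreement."""
    run_dir = _new_run_dir(config.outdir)
    levels = tuple(config.levels)
    tcfg = config.train.with_(image_shape=config.image_shape, seed=config.seed)
    train_x, train_m = make_rater_dataset(config, config.n_train, config.seed + 1)
    test_x, test_m = make_rater_dataset(config, config.n_test, config.seed + 5000)

    cache = models_cache if models_cache is not None else {}
    if "bqr" not in cache:
        cache["bqr"], _ = models.train_bqr_unet(
            train_x, train_m, levels, tcfg,
            warmup_epochs=config.warmup_epochs,
            log_path=run_dir / "bqr_log.jsonl",
        )
    if "baseline" not in cache:
        cache["baseline"], _ = models.train_unet_bce(
            train_x, train_m, tcfg, log_path=run_dir / "baseline_log.jsonl"
        )
    bqr, baseline = cache["bqr"], cache["baseline"]

    rows = []
    nesting_fracs = []
    for i in range(len(test_x)):
        x1 = test_x[i][None]
        am = detection.agreement_map(list(test_m[i]))
        bqr_regions = detection.quantile_regions(
            bqr.predict_logits(x1)[:, 0], levels, mode="bqr"
        )
        nesting_fracs.append(
            detection.nesting_violation_fraction(bqr_regions, levels)
        )
        prob = 1.0 / (1.0 + np.exp(-baseline.predict_logits(x1)[0, 0]))
        base_regions = detection.quantile_regions(prob, levels, mode="baseline")
        for row in detection.per_level_dice(bqr_regions, am, levels):
            rows.append({"image_id": i, "comparison": "BQR-vs-GT", **row})
        for row in detection.per_level_dice(base_regions, am, levels):
            rows.append({"image_id": i, "comparison": "DT-vs-GT", **row})
        for tau in levels:
            rows.append(
                {
                    "image_id": i,
                    "comparison": "DT-vs-BQR",
                    "level": tau,
                    "agreement_threshold": np.nan,
                    "dice": detection.dice(base_regions[tau], bqr_regions[tau]),
                    "excluded": False,
                }
            )

    df = pd.DataFrame(rows)
    df.to_csv(run_dir / "per_image_dice.csv", index=False)
    summary_rows = []
    for (comparison, level), group in df.groupby(["comparison", "level"]):
        valid = group[~group["excluded"]]
        summary_rows.append(
            {
                "comparison": comparison,
                "level": level,
                "dice_mean": float(valid["dice"].mean()) if len(valid) else np.nan,
                "dice_sd": float(valid["dice"].std(ddof=0)) if len(valid) else np.nan,
                "excluded_fraction": float(group["excluded"].mean()),
            }
        )
    summary = pd.DataFrame(summary_rows)
    summary.to_csv(run_dir / "summary.csv", index=False)
    report = {
        "experiment": "supervised",
        "levels": list(levels),
        "bqr_nesting_violation_fraction": float(np.mean(nesting_fracs)),
        "summary": summary.to_dict("records"),
    }
    return _finalize(run_dir, config, report)
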