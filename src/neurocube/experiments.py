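"""Desk-scale reference experiments on the synthetic phantom.

These recipes fix the problem sizes used for CPU-budget validation runs: a
12-subject 64^3 cohort for segmentation (patch 32^3, reduced channel
schedule), an 8-subject 48^3 cohort for the label-merge comparison, and a
60-subject 48^3 cohort with 20^3 bounding cubes for score regression.  They
are shared by the test suite and the acceptance script so both measure the
same protocol.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np

from .phantom import PhantomSpec, generate_cohort
from .pipeline import (RunConfig, compare_merge_modes, run_regression_stage,
                       run_segmentation_stage)
from .regressor import RegressorConfig
from .segnet import SegNetConfig

__all__ = ["desk_segmentation_experiment", "merge_mode_comparison",
           "desk_regression_experiment"]


def _desk_segnet(n_classes: int, seed: int) -> SegNetConfig:
    return SegNetConfig(n_classes=n_classes, stem_channels=4,
                        channel_schedule=(8, 16, 24, 32), expansion=2,
                        seed=seed)


def desk_segmentation_experiment(seed: int, work_dir: str | Path | None = None
                                 ) -> dict:
    """Train the 6-class net on a 12-subject 64^3 cohort (9 train / 3 test),
    patch 32^3, and evaluate held-out Dice / directed ASD.

    Runs in roughly five minutes on one CPU core.
    """
    work = Path(work_dir) if work_dir else Path(tempfile.mkdtemp())
    manifest = generate_cohort(PhantomSpec(grid_edge=64, seed=seed), 12,
                               work / "seg_cohort")
    cfg = RunConfig(manifest=manifest, merge_mode="symmetric_5", crop_edge=64,
                    patch_edge=32, batch_size=2, iterations_per_epoch=100,
                    epochs=5, lr=1e-2, seed=seed,
                    segnet=_desk_segnet(6, seed))
    _, metrics = run_segmentation_stage(cfg)
    return metrics


def merge_mode_comparison(seed: int, n_seeds: int = 5,
                          work_dir: str | Path | None = None) -> dict:
    """Symmetric-merge vs per-ROI training on one 8-subject 48^3 cohort under
    ``n_seeds`` training seeds; reports per-seed Dice and the number of seeds
    where the symmetric merge does at least as well."""
    work = Path(work_dir) if work_dir else Path(tempfile.mkdtemp())
    manifest = generate_cohort(PhantomSpec(grid_edge=48, seed=seed), 8,
                               work / "cmp_cohort")
    rng = np.random.default_rng(seed)
    seeds = [int(s) for s in rng.integers(0, 2 ** 31 - 1, size=n_seeds)]
    records = compare_merge_modes(manifest, seeds)
    wins = sum(r["dice_symmetric"] >= r["dice_per_roi"] for r in records)
    return {"records": records, "symmetric_wins": wins, "n_seeds": n_seeds}


def desk_regression_experiment(seed: int, work_dir: str | Path | None = None,
                               n_subjects: int = 60) -> dict:
    """Regression recovery on a 60-subject cohort with ground-truth ROIs:
    20^3 bounding cubes, mirror-flip augmentation, 60 epochs.

    Reports held-out MSE, the cohort score variance (the mean predictor's
    in-sample MSE) and the generator's score noise floor sigma_s^2.
    """
    work = Path(work_dir) if work_dir else Path(tempfile.mkdtemp())
    spec = PhantomSpec(grid_edge=48, seed=seed)
    manifest = generate_cohort(spec, n_subjects, work / "reg_cohort")
    scores = np.loadtxt(manifest, delimiter=",", skiprows=1, usecols=3)
    cfg = RunConfig(manifest=manifest, crop_edge=48, patch_edge=16,
                    mbc_target_edge=20, use_ground_truth_rois=True,
                    val_fraction=0.0, test_fraction=0.25, seed=seed,
                    regressor_epochs=60,
                    regressor=RegressorConfig.scaled(20, fc_hidden=(128, 16),
                                                     seed=seed))
    _, metrics = run_regression_stage(cfg)
    metrics["cohort_score_variance"] = float(np.var(scores))
    metrics["sigma_s_squared"] = float(spec.score_sigma ** 2)
    return metrics
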