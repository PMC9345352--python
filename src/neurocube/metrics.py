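"""Segmentation and regression evaluation: Dice, average surface distance, MSE,
and a seeded resampling harness with normal-approximation confidence intervals.

Conventions
-----------
* Dice is the exact set overlap ``2|A∩B| / (|A|+|B|)``.
* A surface voxel is a foreground voxel with at least one six-connected
  background neighbour (voxels on the array border count as surface).
* ASD is directed by default: the mean over surface voxels of A of the minimum
  Euclidean distance (in mm, via the voxel spacing) to the surface of B; the
  symmetric variant averages both directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import ndimage, stats
from scipy.spatial import cKDTree

__all__ = ["dice", "average_surface_distance", "mse", "surface_voxels",
           "EvalReport", "resampled_eval", "rank_sum_test"]


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        raise ValueError("Dice undefined: both masks empty")
    inter = int(np.logical_and(a, b).sum())
    return 2.0 * inter / (na + nb)


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Coordinates (k,3) of foreground voxels with a six-connected background
    neighbour; border voxels count as surface."""
    mask = np.asarray(mask, dtype=bool)
    struct = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    interior = ndimage.binary_erosion(mask, structure=struct, border_value=0)
    surf = mask & ~interior
    return np.argwhere(surf)


def average_surface_distance(a: np.ndarray, b: np.ndarray,
                             spacing: Sequence[float] = (1.0, 1.0, 1.0),
                             symmetric: bool = False) -> float:
    """Mean minimum Euclidean surface distance (mm) from A to B per the
    directed definition; ``symmetric=True`` averages both directions."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    if not a.any() or not b.any():
        raise ValueError("ASD undefined for an empty mask")
    sp = np.asarray(spacing, dtype=float)
    if (sp <= 0).any():
        raise ValueError("spacing must be positive")
    sa = surface_voxels(a) * sp
    sb = surface_voxels(b) * sp
    d_ab = cKDTree(sb).query(sa)[0].mean()
    if not symmetric:
        return float(d_ab)
    d_ba = cKDTree(sa).query(sb)[0].mean()
    return float(0.5 * (d_ab + d_ba))


def mse(y: Sequence[float], y_star: Sequence[float]) -> float:
    """Mean squared error between true scores y and predictions y*."""
    y = np.asarray(y, dtype=float)
    y_star = np.asarray(y_star, dtype=float)
    if y.shape != y_star.shape:
        raise ValueError("score vectors have different lengths")
    if y.size == 0:
        raise ValueError("need at least one score")
    return float(np.mean((y - y_star) ** 2))


@dataclass
class EvalReport:
    """Aggregate of repeated train/test cycles.

    ``records`` holds one metric dict per resample; summary fields are the
    across-resample mean, standard deviation and 95% normal-approximation
    confidence interval of the primary metric.
    """

    records: list[dict] = field(default_factory=list)
    primary_metric: str = "mean_dice"
    asd_symmetric: bool = False

    @property
    def n_resamples(self) -> int:
        return len(self.records)

    def values(self, key: str | None = None) -> np.ndarray:
        key = key or self.primary_metric
        return np.asarray([r[key] for r in self.records], dtype=float)

    def mean(self, key: str | None = None) -> float:
        return float(self.values(key).mean())

    def sd(self, key: str | None = None) -> float:
        return float(self.values(key).std(ddof=1)) if self.n_resamples > 1 else 0.0

    def ci95(self, key: str | None = None) -> tuple[float, float]:
        m, s = self.mean(key), self.sd(key)
        half = 1.96 * s / np.sqrt(max(self.n_resamples, 1))
        return (m - half, m + half)

    def summary(self) -> dict:
        keys = [k for k in self.records[0] if isinstance(self.records[0][k], (int, float))]
        out: dict = {"n_resamples": self.n_resamples}
        for k in keys:
            lo, hi = self.ci95(k)
            out[k] = {"mean": self.mean(k), "sd": self.sd(k), "ci95": [lo, hi]}
        return out

    def format_table(self) -> str:
        """Human-readable 'a ± b' and '(low, high)' lines per metric."""
        lines = [f"n_resamples = {self.n_resamples}"]
        s = self.summary()
        for k, v in s.items():
            if k == "n_resamples":
                continue
            lo, hi = v["ci95"]
            lines.append(f"{k}: {v['mean']:.4f} ± {v['sd']:.4f}  ({lo:.4f}, {hi:.4f})")
        return "\n".join(lines)


def resampled_eval(runner: Callable[[int], Mapping[str, float]],
                   n_resamples: int, seed: int,
                   primary_metric: str = "mean_dice") -> EvalReport:
    """Run ``runner(resample_seed)`` for each of ``n_resamples`` seeded splits
    and aggregate its metric dicts into an :class:`EvalReport`.

    Resample seeds are drawn from one parent generator so the whole harness is
    reproducible under ``seed``.
    """
    if n_resamples < 2:
        raise ValueError("need at least 2 resamples")
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2 ** 31 - 1, size=n_resamples)
    report = EvalReport(primary_metric=primary_metric)
    for i, s in enumerate(sub_seeds):
        try:
            rec = dict(runner(int(s)))
        except Exception as exc:
            raise RuntimeError(f"runner failed on resample {i}") from exc
        report.records.append(rec)
    return report


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U p-value comparing per-resample metrics."""
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
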