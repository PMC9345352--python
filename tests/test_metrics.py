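"""Dice, average surface distance, MSE, and the resampling harness."""

import numpy as np
import pytest
from scipy import ndimage

from neurocube.metrics import (EvalReport, average_surface_distance, dice, mse,
                               rank_sum_test, resampled_eval, surface_voxels)


# -- brute-force oracles (shared surface definition) -------------------------

def brute_surface(mask):
    struct = ndimage.generate_binary_structure(3, 1)
    interior = ndimage.binary_erosion(mask, structure=struct, border_value=0)
    return np.argwhere(mask & ~interior)


def brute_asd(a, b, spacing=(1.0, 1.0, 1.0)):
    sa = brute_surface(a) * np.asarray(spacing)
    sb = brute_surface(b) * np.asarray(spacing)
    d = np.sqrt(((sa[:, None, :] - sb[None, :, :]) ** 2).sum(-1))
    return d.min(axis=1).mean()


def brute_dice(a, b):
    return 2 * np.logical_and(a, b).sum() / (a.sum() + b.sum())


# -- dice ---------------------------------------------------------------------

def test_dice_identical_and_disjoint():
    a = np.zeros((4, 4, 4), bool)
    a[1:3, 1:3, 1:3] = True
    assert dice(a, a) == 1.0
    b = np.zeros_like(a)
    b[0, 0, 0] = True
    assert dice(a, b) == 0.0


def test_dice_half_overlap():
    a = np.zeros((4, 4, 4), bool)
    b = np.zeros_like(a)
    a[0, 0, :4] = True          # |A| = 4
    b[0, 0, 2:], b[0, 1, :2] = True, True   # |B| = 4, overlap 2
    assert dice(a, b) == pytest.approx(0.5)


def test_dice_errors():
    e = np.zeros((3, 3, 3), bool)
    with pytest.raises(ValueError):
        dice(e, e)
    with pytest.raises(ValueError):
        dice(e, np.zeros((2, 2, 2), bool))


def test_dice_symmetry_and_axis_permutation(rng):
    a = rng.random((6, 6, 6)) > 0.6
    b = rng.random((6, 6, 6)) > 0.6
    assert dice(a, b) == pytest.approx(dice(b, a))
    perm = (2, 0, 1)
    assert dice(a.transpose(perm), b.transpose(perm)) == pytest.approx(dice(a, b))


# -- average surface distance -------------------------------------------------

def test_asd_identical_zero():
    a = np.zeros((5, 5, 5), bool)
    a[1:4, 1:4, 1:4] = True
    assert average_surface_distance(a, a) == 0.0


def test_asd_two_voxels_three_apart():
    a = np.zeros((8, 8, 8), bool)
    b = np.zeros_like(a)
    a[2, 4, 4] = True
    b[5, 4, 4] = True
    assert average_surface_distance(a, b) == pytest.approx(3.0)


def test_asd_scales_with_spacing():
    a = np.zeros((8, 8, 8), bool)
    b = np.zeros_like(a)
    a[2, 4, 4] = True
    b[5, 4, 4] = True
    assert average_surface_distance(a, b, spacing=(2.0, 2.0, 2.0)) \
        == pytest.approx(6.0)


def test_asd_empty_mask_raises():
    a = np.zeros((3, 3, 3), bool)
    b = a.copy()
    b[1, 1, 1] = True
    with pytest.raises(ValueError):
        average_surface_distance(a, b)


@pytest.mark.parametrize("seed", range(10))
def test_asd_and_dice_match_bruteforce_on_random_masks(seed):
    rng = np.random.default_rng(seed)
    a = rng.random((8, 8, 8)) > 0.7
    b = rng.random((8, 8, 8)) > 0.7
    if not a.any() or not b.any():
        pytest.skip("degenerate draw")
    assert dice(a, b) == pytest.approx(brute_dice(a, b), abs=1e-12)
    assert average_surface_distance(a, b) == pytest.approx(brute_asd(a, b),
                                                           abs=1e-9)
    sym = average_surface_distance(a, b, symmetric=True)
    assert sym == pytest.approx(0.5 * (brute_asd(a, b) + brute_asd(b, a)),
                                abs=1e-9)


def test_surface_voxels_of_solid_block():
    m = np.zeros((6, 6, 6), bool)
    m[1:5, 1:5, 1:5] = True
    surf = surface_voxels(m)
    # 4^3 block minus 2^3 interior
    assert len(surf) == 64 - 8


# -- mse ----------------------------------------------------------------------

def test_mse_values():
    assert mse([1, 2, 3], [1, 2, 3]) == 0.0
    assert mse([0, 2], [1, 1]) == pytest.approx(1.0)
    y = np.arange(5.0)
    assert mse(y, y + 2.5) == pytest.approx(2.5 ** 2)


def test_mse_joint_permutation_invariance(rng):
    y = rng.normal(size=20)
    p = rng.normal(size=20)
    perm = rng.permutation(20)
    assert mse(y, p) == pytest.approx(mse(y[perm], p[perm]))


def test_mse_errors():
    with pytest.raises(ValueError):
        mse([1, 2], [1])
    with pytest.raises(ValueError):
        mse([], [])


# -- resampling harness ---------------------------------------------------------

def test_resampled_eval_constant_runner():
    report = resampled_eval(lambda s: {"mean_dice": 0.9}, n_resamples=5, seed=0)
    assert report.n_resamples == 5
    assert report.sd() == 0.0
    lo, hi = report.ci95()
    assert lo == pytest.approx(0.9) and hi == pytest.approx(0.9)


def test_resampled_eval_ci_matches_closed_form():
    def runner(s):
        return {"mean_dice": np.random.default_rng(s).normal(0.8, 0.05)}
    report = resampled_eval(runner, n_resamples=5, seed=7)
    vals = report.values()
    m, sd = vals.mean(), vals.std(ddof=1)
    lo, hi = report.ci95()
    assert lo == pytest.approx(m - 1.96 * sd / np.sqrt(5))
    assert hi == pytest.approx(m + 1.96 * sd / np.sqrt(5))
    assert "0." in report.format_table()


def test_resampled_eval_propagates_failure():
    def runner(s):
        raise RuntimeError("boom")
    with pytest.raises(RuntimeError, match="resample 0"):
        resampled_eval(runner, n_resamples=2, seed=0)


def test_rank_sum_test_detects_difference():
    a = [0.9, 0.91, 0.92, 0.89, 0.9]
    b = [0.5, 0.52, 0.51, 0.49, 0.5]
    assert rank_sum_test(a, b) < 0.05
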