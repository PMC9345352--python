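"""Minimum bounding boxes and the two-interpolation bounding cube."""

import numpy as np
import pytest

from neurocube.mbc import (EmptyRoiError, MBCube, extract_mbc, load_mbc,
                           minimum_bounding_box, resize_direct, save_mbc)
from neurocube.volume_io import LabeledVolume


def _vol_with_block(shape=(32, 32, 32), lo=(4, 6, 8), size=(4, 6, 2),
                    code=37, value=1.0):
    labels = np.zeros(shape, dtype=np.int32)
    sl = tuple(slice(a, a + s) for a, s in zip(lo, size))
    labels[sl] = code
    inten = np.zeros(shape, dtype=np.float32)
    inten[sl] = value
    return LabeledVolume(intensity=inten, labels=labels)


def test_bbox_single_voxel():
    labels = np.zeros((8, 8, 8), dtype=np.int32)
    labels[3, 4, 5] = 37
    assert minimum_bounding_box(labels, 37) == ((3, 4), (4, 5), (5, 6))


def test_bbox_filled_block_edges():
    vol = _vol_with_block(size=(4, 6, 2))
    box = minimum_bounding_box(vol.labels, 37)
    assert [hi - lo for lo, hi in box] == [4, 6, 2]


def test_bbox_absent_class_raises():
    with pytest.raises(EmptyRoiError):
        minimum_bounding_box(np.zeros((4, 4, 4), dtype=np.int32), 37)


def test_extract_mbc_shapes_and_provenance():
    vol = _vol_with_block(size=(3, 6, 9))
    cube = extract_mbc(vol, 37, target_edge=16)
    assert cube.values.shape == (16, 16, 16)
    assert cube.l_max == 9
    assert cube.source_class == 37
    assert [hi - lo for lo, hi in cube.source_bbox] == [3, 6, 9]


def test_intermediate_edge_is_longest_box_edge():
    """A 10 x 20 x 30 box first becomes a 30^3 cube, then the target size."""
    vol = _vol_with_block(shape=(40, 40, 40), lo=(2, 3, 4), size=(10, 20, 30))
    cube = extract_mbc(vol, 37, target_edge=16)
    assert cube.l_max == 30


def test_cubic_box_two_paths_coincide():
    """When the box is already a cube the first resize is the identity, so
    the MBC equals the single-interpolation baseline exactly."""
    vol = _vol_with_block(size=(6, 6, 6))
    a = extract_mbc(vol, 37, target_edge=12)
    b = resize_direct(vol, 37, target_edge=12)
    np.testing.assert_array_equal(a.values, b.values)


def test_anisotropic_box_paths_differ(rng):
    """A seeded ellipsoid with unequal axes goes through different
    intermediate grids, so the two-step and one-step resizes disagree."""
    g = 32
    ax = np.arange(g)
    xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
    mask = (((xx - 16) / 4.0) ** 2 + ((yy - 16) / 9.0) ** 2
            + ((zz - 16) / 6.0) ** 2) <= 1.0
    labels = np.where(mask, 41, 0).astype(np.int32)
    inten = (rng.random((g, g, g)).astype(np.float32) + 0.5) * mask
    vol = LabeledVolume(intensity=inten, labels=labels)
    a = extract_mbc(vol, 41, target_edge=16)
    b = resize_direct(vol, 41, target_edge=16)
    assert not np.allclose(a.values, b.values)


@pytest.mark.parametrize("fn", [extract_mbc, resize_direct],
                         ids=["mbc", "direct"])
def test_constant_roi_maps_to_constant_cube(fn):
    vol = _vol_with_block(size=(5, 7, 3), value=2.5)
    cube = fn(vol, 37, target_edge=8, content="intensity")
    # unmasked intensity of the box crop is constant 2.5 inside the block
    region = cube.values
    assert region.min() >= 0.0
    cube2 = fn(vol, 37, target_edge=8, content="binary")
    assert set(np.unique(cube2.values)) <= {0.0, 1.0}
    # a crop that is entirely ROI is constant under either path
    sub = LabeledVolume(intensity=np.full((6, 6, 6), 2.5, dtype=np.float32),
                        labels=np.full((6, 6, 6), 37, dtype=np.int32))
    c = fn(sub, 37, target_edge=9, content="intensity")
    np.testing.assert_allclose(c.values, 2.5, rtol=1e-5)


def test_interpolation_respects_value_bounds(rng):
    vol = _vol_with_block(size=(5, 9, 13))
    vol.intensity[vol.labels == 37] = rng.random(
        int((vol.labels == 37).sum())).astype(np.float32)
    cube = extract_mbc(vol, 37, target_edge=16, content="masked_intensity")
    assert cube.values.min() >= vol.intensity.min() - 1e-5
    assert cube.values.max() <= vol.intensity.max() + 1e-5


def test_translation_equivariance():
    """Shifting the ROI by whole voxels does not change its cube."""
    a = _vol_with_block(lo=(4, 6, 8), size=(5, 8, 3))
    b = _vol_with_block(lo=(10, 2, 14), size=(5, 8, 3))
    ca = extract_mbc(a, 37, target_edge=12)
    cb = extract_mbc(b, 37, target_edge=12)
    np.testing.assert_allclose(ca.values, cb.values, atol=1e-6)
    assert ca.l_max == cb.l_max


def test_masked_content_zeroes_background():
    vol = _vol_with_block(size=(4, 4, 8))
    vol.intensity[:] = 3.0  # background bright everywhere
    cube = extract_mbc(vol, 37, target_edge=8, content="masked_intensity")
    # the box is exactly the ROI here, so nothing is masked away
    assert cube.values.max() <= 3.0 + 1e-5
    with pytest.raises(ValueError):
        extract_mbc(vol, 37, target_edge=8, content="unknown")


def test_mbcube_invariants():
    with pytest.raises(ValueError):
        MBCube(values=np.zeros((4, 4, 4), dtype=np.float32), source_class=1,
               source_bbox=((0, 2), (0, 2), (0, 2)), l_max=5)
    with pytest.raises(ValueError):
        MBCube(values=np.zeros((4, 5, 4), dtype=np.float32), source_class=1,
               source_bbox=((0, 4), (0, 5), (0, 4)), l_max=5)


def test_save_load_roundtrip(tmp_path):
    vol = _vol_with_block()
    cube = extract_mbc(vol, 37, target_edge=8)
    save_mbc(cube, tmp_path / "fg")
    back = load_mbc(tmp_path / "fg")
    np.testing.assert_array_equal(back.values, cube.values)
    assert back.source_bbox == cube.source_bbox
    assert back.l_max == cube.l_max
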