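"""Minimum bounding boxes and the two-interpolation minimum bounding cube.

For each segmented structure the tightest axis-aligned box (MBB) is cut out,
resized first to ``L_max^3`` (``L_max`` = the box's longest edge) and then to
the regression input size ``target_edge^3``.  The two-step resize is the
minimum-bounding-cube (MBC) normalization; ``resize_direct`` is the
single-interpolation baseline that maps the box crop straight to the target
cube.  Interpolation is trilinear for real-valued content (with a Gaussian
anti-aliasing prefilter when downscaling) and nearest-neighbour for binary
content.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.transform import resize as _sk_resize

from .volume_io import LabeledVolume

__all__ = ["MBCube", "minimum_bounding_box", "extract_mbc", "resize_direct",
           "EmptyRoiError", "save_mbc", "load_mbc"]

BBox = tuple[tuple[int, int], tuple[int, int], tuple[int, int]]


class EmptyRoiError(ValueError):
    """Requested class has no voxels in the label map."""


@dataclass
class MBCube:
    values: np.ndarray            # (target_edge,)*3 float32
    source_class: int
    source_bbox: BBox             # half-open voxel ranges
    l_max: int

    def __post_init__(self) -> None:
        s = self.values.shape
        if not (len(s) == 3 and s[0] == s[1] == s[2]):
            raise ValueError(f"MBC values must be a cube, got {s}")
        edges = [hi - lo for lo, hi in self.source_bbox]
        if self.l_max != max(edges):
            raise ValueError("l_max must equal the longest bbox edge")


def minimum_bounding_box(labels: np.ndarray, class_code: int) -> BBox:
    """Tightest axis-aligned half-open box containing all voxels of a class."""
    mask = np.asarray(labels) == class_code
    if not mask.any():
        raise EmptyRoiError(f"class {class_code} absent from label volume")
    coords = np.argwhere(mask)
    lo = coords.min(axis=0)
    hi = coords.max(axis=0) + 1
    return tuple((int(a), int(b)) for a, b in zip(lo, hi))  # type: ignore[return-value]


def _crop_content(vol: LabeledVolume, class_code: int, bbox: BBox,
                  content: str) -> tuple[np.ndarray, bool]:
    """Returns (crop, is_binary)."""
    sls = tuple(slice(lo, hi) for lo, hi in bbox)
    if vol.labels is None:
        raise ValueError("volume has no label map")
    mask = (vol.labels[sls] == class_code)
    if content == "binary":
        return mask.astype(np.float32), True
    inten = np.asarray(vol.intensity[sls], dtype=np.float32)
    if content == "masked_intensity":
        return np.where(mask, inten, 0.0).astype(np.float32), False
    if content == "intensity":
        return inten, False
    raise ValueError(f"unknown content mode {content!r}")


def _resize(block: np.ndarray, out_shape: tuple[int, int, int],
            binary: bool) -> np.ndarray:
    if block.shape == tuple(out_shape):
        return block.astype(np.float32)
    if binary:
        out = _sk_resize(block, out_shape, order=0, preserve_range=True,
                         anti_aliasing=False)
    else:
        down = any(o < i for o, i in zip(out_shape, block.shape))
        out = _sk_resize(block, out_shape, order=1, preserve_range=True,
                         anti_aliasing=down)
    return out.astype(np.float32)


def extract_mbc(vol: LabeledVolume, class_code: int, target_edge: int,
                content: str = "masked_intensity") -> MBCube:
    """Two-interpolation MBC: box crop -> L_max^3 -> target_edge^3."""
    if target_edge < 2:
        raise ValueError("target_edge must be >= 2")
    bbox = minimum_bounding_box(vol.labels, class_code)
    crop, binary = _crop_content(vol, class_code, bbox, content)
    l_max = max(hi - lo for lo, hi in bbox)
    step1 = _resize(crop, (l_max, l_max, l_max), binary)
    step2 = _resize(step1, (target_edge, target_edge, target_edge), binary)
    return MBCube(values=step2, source_class=int(class_code),
                  source_bbox=bbox, l_max=int(l_max))


def resize_direct(vol: LabeledVolume, class_code: int, target_edge: int,
                  content: str = "masked_intensity") -> MBCube:
    """Single-interpolation baseline: box crop resized straight to the cube."""
    if target_edge < 2:
        raise ValueError("target_edge must be >= 2")
    bbox = minimum_bounding_box(vol.labels, class_code)
    crop, binary = _crop_content(vol, class_code, bbox, content)
    l_max = max(hi - lo for lo, hi in bbox)
    out = _resize(crop, (target_edge, target_edge, target_edge), binary)
    return MBCube(values=out, source_class=int(class_code),
                  source_bbox=bbox, l_max=int(l_max))


def save_mbc(cube: MBCube, prefix: str | Path) -> None:
    """Serialize as ``<prefix>.npz`` plus a JSON provenance sidecar."""
    prefix = Path(prefix)
    np.savez_compressed(str(prefix) + ".npz", values=cube.values)
    meta = {"source_class": cube.source_class,
            "source_bbox": [list(r) for r in cube.source_bbox],
            "l_max": cube.l_max}
    Path(str(prefix) + ".json").write_text(json.dumps(meta))


def load_mbc(prefix: str | Path) -> MBCube:
    prefix = Path(prefix)
    values = np.load(str(prefix) + ".npz")["values"]
    meta = json.loads(Path(str(prefix) + ".json").read_text())
    bbox = tuple(tuple(r) for r in meta["source_bbox"])
    return MBCube(values=values, source_class=meta["source_class"],
                  source_bbox=bbox, l_max=meta["l_max"])
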