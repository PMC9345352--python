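"""NIfTI volume I/O, the fixed center crop, and random patch sampling.

Arrays are indexed ``(x, y, z)`` in NIfTI voxel order, 0-based with half-open
slices.  A :class:`LabeledVolume` carries an intensity volume, an optional
voxel-aligned integer label map and the voxel spacing in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = ["LabeledVolume", "read_volume", "write_volume", "center_crop",
           "sample_patches", "zscore_normalize", "read_manifest", "write_manifest"]


@dataclass
class LabeledVolume:
    intensity: np.ndarray
    labels: np.ndarray | None = None
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity)
        if self.intensity.ndim != 3:
            raise ValueError(f"intensity must be 3D, got shape {self.intensity.shape}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != self.intensity.shape:
                raise ValueError("labels and intensity shapes differ")
            if not np.issubdtype(self.labels.dtype, np.integer):
                raise TypeError("labels must be integer-valued")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensity.shape  # type: ignore[return-value]


def _affine_from_spacing(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_volume(vol: LabeledVolume, image_path: str | Path,
                 label_path: str | Path | None = None) -> None:
    """Write the intensity (and labels, if given a path) as 3D NIfTI files."""
    aff = _affine_from_spacing(vol.spacing)
    nib.save(nib.Nifti1Image(vol.intensity.astype(np.float32), aff), str(image_path))
    if label_path is not None:
        if vol.labels is None:
            raise ValueError("volume has no labels to write")
        nib.save(nib.Nifti1Image(vol.labels.astype(np.int16), aff), str(label_path))


def read_volume(image_path: str | Path, label_path: str | Path | None = None,
                subject_id: str = "") -> LabeledVolume:
    """Read a 3D NIfTI intensity image and optionally its label map."""
    img = nib.load(str(image_path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D image, got {data.ndim}D in {image_path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    labels = None
    if label_path is not None:
        limg = nib.load(str(label_path))
        labels = np.asanyarray(limg.dataobj)
        if labels.ndim != 3:
            raise ValueError(f"expected a 3D label map in {label_path}")
        labels = np.rint(labels).astype(np.int32)
    return LabeledVolume(intensity=data.astype(np.float32), labels=labels,
                         spacing=spacing, subject_id=subject_id)


def _center_slices(shape: tuple[int, ...], out_edge: int) -> tuple[slice, ...]:
    sls = []
    for dim in shape:
        if out_edge > dim:
            raise ValueError(f"crop edge {out_edge} exceeds input dimension {dim}")
        margin = dim - out_edge
        lo = margin // 2  # odd margins put the extra voxel on the high side
        sls.append(slice(lo, lo + out_edge))
    return tuple(sls)


def center_crop(vol: LabeledVolume, out_edge: int) -> LabeledVolume:
    """Centered ``out_edge``^3 subvolume of intensity and labels.

    Removes the outermost background shell, e.g. a 240^3 volume cropped to
    224^3 before patch sampling.
    """
    sls = _center_slices(vol.shape, out_edge)
    labels = vol.labels[sls] if vol.labels is not None else None
    return replace(vol, intensity=vol.intensity[sls], labels=labels)


def sample_patches(vol: LabeledVolume, patch_edge: int, n: int, seed,
                   require_foreground: bool = False,
                   max_retries: int = 1000) -> list[LabeledVolume]:
    """Draw ``n`` random ``patch_edge``^3 patches with origins uniform over all
    valid positions; intensity and labels are cut coherently (pure slicing, no
    resampling).  ``require_foreground`` optionally re-draws until a patch holds
    at least one nonzero label voxel.
    """
    for dim in vol.shape:
        if patch_edge > dim:
            raise ValueError(f"patch edge {patch_edge} exceeds input dimension {dim}")
    rng = np.random.default_rng(seed)
    out: list[LabeledVolume] = []
    hi = [dim - patch_edge + 1 for dim in vol.shape]
    for _ in range(n):
        for attempt in range(max_retries):
            origin = [int(rng.integers(0, h)) for h in hi]
            sls = tuple(slice(o, o + patch_edge) for o in origin)
            labels = vol.labels[sls] if vol.labels is not None else None
            if require_foreground and labels is not None and not (labels != 0).any():
                continue
            out.append(replace(vol, intensity=vol.intensity[sls], labels=labels))
            break
        else:
            raise RuntimeError("could not draw a foreground patch within retry budget")
    return out


def zscore_normalize(intensity: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Per-volume z-score over mask voxels (fallback: whole volume)."""
    x = np.asarray(intensity, dtype=np.float32)
    vals = x[mask] if mask is not None and np.asarray(mask).any() else x
    sd = float(vals.std())
    if sd == 0.0:
        return x - float(vals.mean())
    return (x - float(vals.mean())) / sd


def write_manifest(rows: list[dict], path: str | Path) -> None:
    """Write a subject manifest CSV (subject_id, image_path, label_path, score)."""
    pd.DataFrame(rows, columns=["subject_id", "image_path", "label_path", "score"]
                 ).to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"subject_id", "image_path", "label_path", "score"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df
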