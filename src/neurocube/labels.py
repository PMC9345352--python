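"""The 14-ROI atlas table and the bilateral symmetry label merge.

Fourteen regions of interest drawn from the SRI24 adult-brain atlas are used:
three bilateral pairs of inferior frontal gyrus subdivisions plus one pair
each of hippocampus, amygdala, caudate nucleus and thalamus.  Because the two
hemispheres are close to mirror images of each other, segmentation can merge
every bilateral family into a single class ("symmetric" mode, 5 foreground
classes) instead of giving each ROI its own class ("per-ROI" mode, 14
foreground classes).  Background is always class 0 and takes part in the
segmentation softmax.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["RoiEntry", "AtlasScheme", "default_atlas", "load_atlas_table",
           "UnknownLabelError"]


class UnknownLabelError(ValueError):
    """A label volume contains a code outside the atlas scheme."""


@dataclass(frozen=True)
class RoiEntry:
    atlas_code: int
    side: str  # "L" or "R"
    family: str


# atlas code -> (side, family); the built-in default table
_DEFAULT_ROWS: tuple[tuple[int, str, str], ...] = (
    (11, "L", "frontal_gyrus"),   # inferior frontal gyrus, opercular
    (12, "R", "frontal_gyrus"),
    (13, "L", "frontal_gyrus"),   # triangular
    (14, "R", "frontal_gyrus"),
    (15, "L", "frontal_gyrus"),   # orbital
    (16, "R", "frontal_gyrus"),
    (37, "L", "hippocampus"),
    (38, "R", "hippocampus"),
    (41, "L", "amygdala"),
    (42, "R", "amygdala"),
    (71, "L", "caudate_nucleus"),
    (72, "R", "caudate_nucleus"),
    (77, "L", "thalamus"),
    (78, "R", "thalamus"),
)


@dataclass(frozen=True)
class AtlasScheme:
    """The ROI label table plus the merge mode used by the segmentation head.

    ``merge_mode`` is ``"symmetric_5"`` (one class per bilateral family) or
    ``"per_roi_14"`` (one class per atlas code).  Class indices are assigned
    deterministically: families ordered by their smallest atlas code, atlas
    codes ascending; class 0 is background.
    """

    roi_entries: tuple[RoiEntry, ...] = field(
        default_factory=lambda: tuple(RoiEntry(*r) for r in _DEFAULT_ROWS))
    background_code: int = 0
    merge_mode: str = "symmetric_5"

    def __post_init__(self) -> None:
        codes = [e.atlas_code for e in self.roi_entries]
        if len(codes) != len(set(codes)):
            raise ValueError("duplicate atlas codes in scheme")
        if self.background_code in codes:
            raise ValueError("background code collides with an ROI code")
        if self.merge_mode not in ("symmetric_5", "per_roi_14"):
            raise ValueError(f"unknown merge_mode {self.merge_mode!r}")
        for fam, entries in self._by_family().items():
            sides = sorted(e.side for e in entries)
            n_l = sides.count("L")
            n_r = sides.count("R")
            if n_l != n_r:
                raise ValueError(f"family {fam!r} has unbalanced sides")

    # -- derived tables ----------------------------------------------------
    def _by_family(self) -> dict[str, list[RoiEntry]]:
        fams: dict[str, list[RoiEntry]] = {}
        for e in self.roi_entries:
            fams.setdefault(e.family, []).append(e)
        return fams

    @property
    def atlas_codes(self) -> tuple[int, ...]:
        return tuple(sorted(e.atlas_code for e in self.roi_entries))

    @property
    def families(self) -> tuple[str, ...]:
        """Family names ordered by smallest atlas code."""
        fams = self._by_family()
        return tuple(sorted(fams, key=lambda f: min(e.atlas_code for e in fams[f])))

    @property
    def n_classes(self) -> int:
        """Number of softmax outputs (foreground classes + background)."""
        if self.merge_mode == "symmetric_5":
            return len(self.families) + 1
        return len(self.roi_entries) + 1

    def family_class_map(self) -> dict[int, int]:
        """atlas code -> merged family class index (1-based)."""
        fam_idx = {f: i + 1 for i, f in enumerate(self.families)}
        return {e.atlas_code: fam_idx[e.family] for e in self.roi_entries}

    def per_roi_class_map(self) -> dict[int, int]:
        """atlas code -> per-ROI class index (1-based, ascending code)."""
        return {c: i + 1 for i, c in enumerate(self.atlas_codes)}

    def class_map(self) -> dict[int, int]:
        if self.merge_mode == "symmetric_5":
            return self.family_class_map()
        return self.per_roi_class_map()

    def mirror_code_map(self) -> dict[int, int]:
        """atlas code -> the contralateral code of the same anatomical unit.

        Codes are paired within a family in ascending order: the i-th left
        code pairs with the i-th right code.
        """
        out: dict[int, int] = {}
        for entries in self._by_family().values():
            lefts = sorted((e.atlas_code for e in entries if e.side == "L"))
            rights = sorted((e.atlas_code for e in entries if e.side == "R"))
            for cl, cr in zip(lefts, rights):
                out[cl] = cr
                out[cr] = cl
        return out

    # -- volume relabeling -------------------------------------------------
    def _apply_map(self, label_volume: np.ndarray, cmap: dict[int, int]) -> np.ndarray:
        labels = np.asarray(label_volume)
        if not np.issubdtype(labels.dtype, np.integer):
            raise TypeError("label volume must be an integer array")
        present = np.unique(labels)
        allowed = set(cmap) | {self.background_code}
        unknown = [int(c) for c in present if int(c) not in allowed]
        if unknown:
            raise UnknownLabelError(f"unknown label code(s) {unknown} in volume")
        lut_size = max(allowed) + 1
        lut = np.zeros(lut_size, dtype=np.int64)
        for code, cls in cmap.items():
            lut[code] = cls
        return lut[labels]


def merge_symmetric(label_volume: np.ndarray, scheme: AtlasScheme) -> np.ndarray:
    """Relabel atlas codes so both hemispheres of a family share one class.

    Returns an integer volume over {0..n_families}; raises
    :class:`UnknownLabelError` on codes outside the scheme.
    """
    return scheme._apply_map(label_volume, scheme.family_class_map())


def per_roi_classes(label_volume: np.ndarray, scheme: AtlasScheme) -> np.ndarray:
    """Relabel atlas codes to one class per ROI (ascending code order)."""
    return scheme._apply_map(label_volume, scheme.per_roi_class_map())


def default_atlas(merge_mode: str = "symmetric_5") -> AtlasScheme:
    """The built-in 14-ROI table (codes 11-16, 37, 38, 41, 42, 71, 72, 77, 78)."""
    return AtlasScheme(merge_mode=merge_mode)


def load_atlas_table(path: str | Path, background_code: int = 0,
                     merge_mode: str = "symmetric_5") -> AtlasScheme:
    """Load an atlas scheme from a CSV/TSV with columns (code, side, family)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    cols = {c.lower(): c for c in df.columns}
    missing = {"code", "side", "family"} - set(cols)
    if missing:
        raise ValueError(f"atlas table missing columns: {sorted(missing)}")
    entries = tuple(
        RoiEntry(int(r[cols["code"]]), str(r[cols["side"]]).strip().upper(),
                 str(r[cols["family"]]).strip())
        for _, r in df.iterrows())
    return AtlasScheme(roi_entries=entries, background_code=background_code,
                       merge_mode=merge_mode)
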