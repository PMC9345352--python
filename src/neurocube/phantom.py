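"""Synthetic symmetric brain phantoms: mirrored ellipsoid ROIs plus a scalar
score driven by ROI morphology.

Each subject is a skull-stripped-looking intensity volume: a spherical brain
envelope containing 14 ellipsoidal ROIs — the three left/right inferior
frontal gyrus subdivisions and one bilateral pair each of hippocampus,
amygdala, caudate nucleus and thalamus, carrying the same atlas codes as the
real label maps.  Left and right instances are exact mirror images of each
other before per-subject jitter, mirroring the anatomy the symmetric label
merge exploits.  Every structure family gets a distinct mean intensity
(contrast between deep-grey structures is what makes them separable in a
T1-weighted image); voxel noise is additive Gaussian.

The score is generated from morphology alone: a linear combination of the
families' relative rendered volumes plus Gaussian noise, so the information
pathway segmentation -> bounding-cube -> regression is recoverable by
construction.  True per-family volumes are returned with each subject for
oracle checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .volume_io import LabeledVolume, write_manifest, write_volume

__all__ = ["StructureTemplate", "PhantomSpec", "generate_subject",
           "generate_cohort", "load_phantom_spec"]


@dataclass(frozen=True)
class StructureTemplate:
    """One left-hemisphere ellipsoid; the right twin is its mirror image.

    ``center``/``radii`` are fractions of the grid edge; ``code_l``/``code_r``
    are the atlas codes of the left and right instances.
    """

    family: str
    code_l: int
    code_r: int
    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    intensity: float


# Left-hemisphere layout (mirror plane: x = (g-1)/2).  Centers keep every
# structure inside the envelope and non-overlapping at the default jitter.
_DEFAULT_TEMPLATES: tuple[StructureTemplate, ...] = (
    StructureTemplate("frontal_gyrus", 11, 12, (0.28, 0.30, 0.70), (0.060, 0.050, 0.050), 0.55),
    StructureTemplate("frontal_gyrus", 13, 14, (0.28, 0.42, 0.70), (0.060, 0.050, 0.050), 0.55),
    StructureTemplate("frontal_gyrus", 15, 16, (0.28, 0.54, 0.70), (0.060, 0.050, 0.050), 0.55),
    StructureTemplate("hippocampus", 37, 38, (0.29, 0.62, 0.38), (0.065, 0.085, 0.055), 0.65),
    StructureTemplate("amygdala", 41, 42, (0.29, 0.36, 0.36), (0.050, 0.050, 0.045), 0.75),
    StructureTemplate("caudate_nucleus", 71, 72, (0.19, 0.48, 0.54), (0.050, 0.095, 0.060), 0.85),
    StructureTemplate("thalamus", 77, 78, (0.37, 0.50, 0.52), (0.065, 0.075, 0.060), 0.95),
)

_DEFAULT_WEIGHTS: dict[str, float] = {
    "frontal_gyrus": 10.0,
    "hippocampus": 10.0,
    "amygdala": 10.0,
    "caudate_nucleus": 10.0,
    "thalamus": 10.0,
}


@dataclass
class PhantomSpec:
    """Generator parameters.

    ``scale_jitter``: per-subject, per-family radius scale drawn uniformly from
    ``1 +/- scale_jitter`` and shared by both hemispheres (volume varies ~3x
    the radius variation).  ``translate_jitter``: per-instance center shift
    (fraction of grid edge), independent per side, which breaks exact mirror
    symmetry the way anatomy does.  ``score_weights`` act on each family's
    rendered volume relative to its analytic nominal volume, centred at 1, and
    ``score_sigma`` is the residual score noise — together they fix how much of
    the score variance is morphological signal.
    """

    grid_edge: int = 96
    templates: tuple[StructureTemplate, ...] = _DEFAULT_TEMPLATES
    mirror_axis: int = 0
    envelope_radius: float = 0.46
    envelope_intensity: float = 0.35
    scale_jitter: float = 0.15
    translate_jitter: float = 0.02
    noise_sd: float = 0.05
    score_weights: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_WEIGHTS))
    score_sigma: float = 6.0
    seed: int = 0
    max_retries: int = 20

    def __post_init__(self) -> None:
        if self.mirror_axis != 0:
            raise ValueError("mirror plane is implemented across axis 0")
        if self.grid_edge < 16:
            raise ValueError("grid_edge must be >= 16")
        fams = {t.family for t in self.templates}
        unknown = set(self.score_weights) - fams
        if unknown:
            raise ValueError(f"score weights for unknown families: {sorted(unknown)}")

    @property
    def families(self) -> tuple[str, ...]:
        seen: list[str] = []
        for t in self.templates:
            if t.family not in seen:
                seen.append(t.family)
        return tuple(seen)

    def nominal_family_volumes(self) -> dict[str, float]:
        """Analytic voxel volume per family (both hemispheres) at unit scale."""
        g = self.grid_edge
        out: dict[str, float] = {fam: 0.0 for fam in self.families}
        for t in self.templates:
            v = 4.0 / 3.0 * np.pi * np.prod([r * g for r in t.radii])
            out[t.family] += 2.0 * v
        return out

    def atlas_codes(self) -> tuple[int, ...]:
        codes: list[int] = []
        for t in self.templates:
            codes.extend((t.code_l, t.code_r))
        return tuple(sorted(codes))


def _ellipsoid_mask(grid: tuple[np.ndarray, np.ndarray, np.ndarray],
                    center: np.ndarray, radii: np.ndarray) -> np.ndarray:
    xx, yy, zz = grid
    q = (((xx - center[0]) / radii[0]) ** 2
         + ((yy - center[1]) / radii[1]) ** 2
         + ((zz - center[2]) / radii[2]) ** 2)
    return q <= 1.0


def _render(spec: PhantomSpec, rng: np.random.Generator
            ) -> tuple[np.ndarray, np.ndarray, dict[str, int]] | None:
    g = spec.grid_edge
    ax = np.arange(g, dtype=np.float64)
    grid = np.meshgrid(ax, ax, ax, indexing="ij")
    center_of_grid = np.array([(g - 1) / 2.0] * 3)

    envelope = _ellipsoid_mask(grid, center_of_grid,
                               np.array([spec.envelope_radius * g] * 3))
    labels = np.zeros((g, g, g), dtype=np.int32)
    intensity = np.where(envelope, spec.envelope_intensity, 0.0)

    scales = {fam: 1.0 + rng.uniform(-spec.scale_jitter, spec.scale_jitter)
              for fam in spec.families}
    fam_volumes = {fam: 0 for fam in spec.families}

    for t in spec.templates:
        s = scales[t.family]
        radii = np.array(t.radii) * g * s
        for side in ("L", "R"):
            center = np.array(t.center) * (g - 1)
            if side == "R":
                center[0] = (g - 1) - center[0]
            shift = rng.uniform(-spec.translate_jitter, spec.translate_jitter, size=3) * g \
                if spec.translate_jitter > 0 else np.zeros(3)
            center = center + shift
            mask = _ellipsoid_mask(grid, center, radii)
            if not mask.any():
                return None
            if not (mask <= envelope).all():  # structure escaped the brain
                return None
            if (labels[mask] != 0).any():     # collided with a previous ROI
                return None
            code = t.code_l if side == "L" else t.code_r
            labels[mask] = code
            intensity = np.where(mask, t.intensity, intensity)
            fam_volumes[t.family] += int(mask.sum())
    return intensity, labels, fam_volumes


def generate_subject(spec: PhantomSpec, subject_seed: int
                     ) -> tuple[LabeledVolume, float, dict[str, int]]:
    """Render one subject; returns (volume, score, per-family voxel volumes).

    Deterministic under ``(spec.seed, subject_seed)``.  Subjects whose jittered
    structures escape the envelope or collide are re-drawn with fresh jitter up
    to ``spec.max_retries`` times.
    """
    for attempt in range(spec.max_retries):
        rng = np.random.default_rng([spec.seed, subject_seed, attempt])
        rendered = _render(spec, rng)
        if rendered is not None:
            break
    else:
        raise RuntimeError(
            f"could not place structures after {spec.max_retries} retries "
            f"(jitter too large for the grid)")
    intensity, labels, fam_volumes = rendered

    noisy = intensity + rng.normal(0.0, spec.noise_sd, size=intensity.shape)
    nominal = spec.nominal_family_volumes()
    signal = sum(w * (fam_volumes[f] / nominal[f] - 1.0)
                 for f, w in spec.score_weights.items())
    score = float(signal + rng.normal(0.0, spec.score_sigma))
    vol = LabeledVolume(intensity=noisy.astype(np.float32), labels=labels,
                        spacing=(1.0, 1.0, 1.0), subject_id=f"s{subject_seed:04d}")
    return vol, score, fam_volumes


def generate_cohort(spec: PhantomSpec, n: int, out_dir: str | Path,
                    start_seed: int = 0) -> Path:
    """Write ``n`` subjects as NIfTI pairs plus a CSV manifest; returns the
    manifest path.  Ordering and content are stable for a fixed spec."""
    if n < 1:
        raise ValueError("need n >= 1 subjects")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n):
        vol, score, _ = generate_subject(spec, start_seed + i)
        img = out_dir / f"{vol.subject_id}_img.nii.gz"
        lab = out_dir / f"{vol.subject_id}_lab.nii.gz"
        write_volume(vol, img, lab)
        rows.append({"subject_id": vol.subject_id, "image_path": str(img),
                     "label_path": str(lab), "score": score})
    manifest = out_dir / "manifest.csv"
    write_manifest(rows, manifest)
    return manifest


def load_phantom_spec(path: str | Path) -> PhantomSpec:
    """Build a spec from a YAML file; structure templates may be overridden
    with a ``templates`` list of [family, code_l, code_r, center, radii,
    intensity] entries."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "templates" in raw:
        raw["templates"] = tuple(
            StructureTemplate(t[0], int(t[1]), int(t[2]), tuple(t[3]),
                              tuple(t[4]), float(t[5]))
            for t in raw["templates"])
    return PhantomSpec(**raw)
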