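"""Synthetic NIfTI cohorts with the geometry of the preprocessed study data.

Functional volumes are 45x54x45xT (T drawn per subject from a configurable
interval) and structural grey-matter maps are 91x109x91. Class-conditional
signal is a small set of smooth intensity foci at fixed per-class centers
added to a shared brain-shaped (ellipsoidal) baseline plus Gaussian noise;
voxels outside the ellipsoid are zero so that empty-slice filtering is
meaningful.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "LABELS",
    "FMRI_SHAPE",
    "SMRI_SHAPE",
    "CohortSpec",
    "SubjectVolume",
    "generate_cohort",
    "write_cohort",
    "load_cohort",
]

LABELS = ("AD", "HC", "MCI")
FMRI_SHAPE = (45, 54, 45)
SMRI_SHAPE = (91, 109, 91)

# Per-class focus centers in fractional (x, y, z) coordinates of the brain
# ellipsoid. Each class gets three foci spread along z so nearly every
# axial slice carries class signal; centers are disjoint between classes.
CLASS_FOCI = {
    "AD": ((0.32, 0.35, 0.22), (0.60, 0.62, 0.50), (0.38, 0.55, 0.78)),
    "HC": ((0.65, 0.40, 0.24), (0.35, 0.60, 0.52), (0.62, 0.45, 0.80)),
    "MCI": ((0.50, 0.68, 0.22), (0.68, 0.55, 0.55), (0.35, 0.38, 0.78)),
}
FOCUS_SIGMA = 0.14  # of the smallest spatial extent


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for one synthetic cohort."""

    n_per_class: dict = field(default_factory=lambda: {"AD": 3, "HC": 3, "MCI": 3})
    modality: str = "smri"
    fmri_T_range: tuple[int, int] = (124, 200)
    fmri_T_mode: int | None = 140
    effect_size: float = 1.0
    noise_sd: float = 0.05
    empty_slice_prob: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.modality not in ("fmri", "smri"):
            raise ValueError(f"invalid modality {self.modality!r}")
        for label, n in self.n_per_class.items():
            if label not in LABELS:
                raise ValueError(f"unknown class label {label!r}")
            if n < 0:
                raise ValueError("subject counts must be nonnegative")
        if sum(self.n_per_class.values()) == 0:
            raise ValueError("zero subjects requested for every class")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0.0 <= self.empty_slice_prob <= 1.0:
            raise ValueError("empty_slice_prob must be in [0, 1]")
        lo, hi = self.fmri_T_range
        if lo < 1 or hi < lo:
            raise ValueError("fmri_T_range must be a nonempty positive interval")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return FMRI_SHAPE if self.modality == "fmri" else SMRI_SHAPE


@dataclass
class SubjectVolume:
    """One subject's voxel grid with identity and class label."""

    subject_id: str
    label: str
    voxels: np.ndarray  # (X, Y, Z) for smri, (X, Y, Z, T) for fmri
    modality: str

    def __post_init__(self):
        if not np.isfinite(self.voxels).all():
            raise ValueError("voxel values must be finite")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.voxels.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return 1 if self.voxels.ndim == 3 else self.voxels.shape[3]


def _brain_mask(shape: tuple[int, int, int]) -> np.ndarray:
    """Ellipsoidal mask occupying ~80% of each axis."""
    axes = [np.linspace(-1, 1, s) for s in shape]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    return (xx / 0.82) ** 2 + (yy / 0.86) ** 2 + (zz / 0.82) ** 2 <= 1.0


def _class_signal(shape: tuple[int, int, int], label: str, amplitude: float) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape], indexing="ij")
    sigma = FOCUS_SIGMA * min(shape)
    signal = np.zeros(shape)
    for fx, fy, fz in CLASS_FOCI[label]:
        center = (fx * shape[0], fy * shape[1], fz * shape[2])
        d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
        signal += amplitude * np.exp(-d2 / (2 * sigma**2))
    return signal


def _subject_rng(seed: int, subject_id: str) -> np.random.Generator:
    """Independent per-subject stream derived from (seed, subject_id) so
    adding/removing a subject does not perturb the others."""
    return np.random.default_rng([seed, zlib.crc32(subject_id.encode())])


def _draw_T(spec: CohortSpec, rng: np.random.Generator) -> int:
    lo, hi = spec.fmri_T_range
    if spec.fmri_T_mode is not None:
        # mixture: half the mass on the mode, rest uniform over the interval
        if rng.random() < 0.5:
            return int(spec.fmri_T_mode)
    return int(rng.integers(lo, hi + 1))


def generate_cohort(spec: CohortSpec) -> list[SubjectVolume]:
    """Generate the cohort described by ``spec`` (reproducible from its seed)."""
    shape = spec.spatial_shape
    mask = _brain_mask(shape)
    baseline = np.where(mask, 1.0, 0.0) * (
        1.0 - 0.3 * np.linspace(-1, 1, shape[2])[None, None, :] ** 2
    )
    volumes: list[SubjectVolume] = []
    for label in LABELS:
        n = spec.n_per_class.get(label, 0)
        signal = _class_signal(shape, label, spec.effect_size) if spec.effect_size > 0 else 0.0
        for i in range(n):
            subject_id = f"{label}{i:03d}"
            rng = _subject_rng(spec.seed, subject_id)
            mean = baseline + signal
            if spec.modality == "fmri":
                T = _draw_T(spec, rng)
                vox = mean[..., None] + rng.normal(0.0, spec.noise_sd, size=shape + (T,))
            else:
                vox = mean + rng.normal(0.0, spec.noise_sd, size=shape)
            vox[~mask] = 0.0
            if spec.empty_slice_prob > 0:
                empty = rng.random(shape[2]) < spec.empty_slice_prob
                vox[:, :, empty] = 0.0
            volumes.append(SubjectVolume(subject_id=subject_id, label=label,
                                         voxels=vox, modality=spec.modality))
    return volumes


def write_cohort(volumes: list[SubjectVolume], out_dir: str | Path,
                 compress: bool = True) -> pd.DataFrame:
    """Write one NIfTI file per subject plus a cohort manifest table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for vol in volumes:
        ext = ".nii.gz" if compress else ".nii"
        path = out_dir / f"{vol.subject_id}{ext}"
        img = nib.Nifti1Image(np.asarray(vol.voxels, dtype=np.float32), affine=np.eye(4))
        nib.save(img, str(path))
        rows.append({
            "subject_id": vol.subject_id,
            "label": vol.label,
            "modality": vol.modality,
            "path": str(path),
            "T": vol.n_timepoints,
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "cohort.csv", index=False)
    return manifest


def load_cohort(manifest: str | Path | pd.DataFrame) -> list[SubjectVolume]:
    """Round-trip a written cohort back into memory."""
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(Path(manifest))
    volumes = []
    for row in manifest.itertuples():
        data = np.asarray(nib.load(row.path).dataobj, dtype=np.float64)
        volumes.append(SubjectVolume(subject_id=row.subject_id, label=row.label,
                                     voxels=data, modality=row.modality))
    return volumes
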