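"""Volume-to-slice decomposition with lossless PNG export.

A volume is swept along z (and t for 4-D data); the last ``drop_tail``
z-slices are never exported and a slice is exported only when the sum of
its raw voxel intensities is nonzero. Pixels are linearly mapped from a
per-volume intensity window to the integer PNG range, which makes the
stored images bit-exact on re-read.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .cohort import SubjectVolume

__all__ = [
    "DecomposeParams",
    "SliceRecord",
    "decompose_volume",
    "decompose_cohort",
    "write_slice_png",
    "read_slice_png",
    "build_manifest",
    "encode_slice_filename",
    "parse_slice_filename",
]


@dataclass(frozen=True)
class DecomposeParams:
    drop_tail: int = 10
    bit_depth: int = 8
    scaling: str = "per_volume"

    def __post_init__(self):
        if self.drop_tail < 0:
            raise ValueError("drop_tail must be >= 0")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.scaling != "per_volume":
            raise ValueError("only per_volume scaling is supported")


@dataclass(frozen=True)
class SliceRecord:
    """One exported 2-D slice image (the unit of training)."""

    subject_id: str
    label: str
    z: int
    t: int
    path: str
    sum_intensity: float


def encode_slice_filename(subject_id: str, z: int, t: int) -> str:
    if "__" in subject_id:
        raise ValueError("subject_id must not contain '__'")
    return f"{subject_id}__z{z:03d}__t{t:04d}.png"


_FILENAME_RE = re.compile(r"^(?P<sid>.+)__z(?P<z>\d+)__t(?P<t>\d+)\.png$")


def parse_slice_filename(name: str) -> tuple[str, int, int]:
    m = _FILENAME_RE.match(Path(name).name)
    if m is None:
        raise ValueError(f"not a slice filename: {name!r}")
    return m.group("sid"), int(m.group("z")), int(m.group("t"))


def write_slice_png(slice_pixels: np.ndarray, path: str | Path,
                    window: tuple[float, float], bit_depth: int = 8) -> None:
    """Quantize ``slice_pixels`` from ``window`` into PNG integers.

    Values are linearly mapped onto [0, 2^bit_depth - 1] and rounded
    half-up; a collapsed window yields an all-zero image.
    """
    pixels = np.asarray(slice_pixels, dtype=np.float64)
    if np.isnan(pixels).any():
        raise ValueError("NaN pixels cannot be exported")
    lo, hi = window
    if lo > hi:
        raise ValueError("window.min must be <= window.max")
    levels = 2**bit_depth - 1
    if hi == lo:
        q = np.zeros(pixels.shape, dtype=np.uint16)
    else:
        scaled = (pixels - lo) * (levels / (hi - lo))
        q = np.floor(scaled + 0.5).astype(np.int64)  # round half-up
        q = np.clip(q, 0, levels).astype(np.uint16)
    if bit_depth == 8:
        Image.fromarray(q.astype(np.uint8), mode="L").save(path)
    else:
        Image.fromarray(q).save(path)


def read_slice_png(path: str | Path) -> np.ndarray:
    """Return exactly the stored integer grid."""
    with Image.open(path) as img:
        arr = np.asarray(img)
    return arr.astype(np.int64)


def decompose_volume(volume: SubjectVolume, params: DecomposeParams,
                     out_dir: str | Path) -> list[SliceRecord]:
    """Export the nonzero-sum (x, y) slices of ``volume`` as PNG files.

    Iterates z from 0 to Z - drop_tail - 1 and t over the full time axis;
    records are returned in (z, t) lexicographic order.
    """
    vox = volume.voxels
    if vox.ndim == 3:
        vox = vox[..., None]
    Z, T = vox.shape[2], vox.shape[3]
    if params.drop_tail >= Z:
        raise ValueError(f"drop_tail {params.drop_tail} >= volume depth {Z}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    window = (float(vox.min()), float(vox.max()))
    records: list[SliceRecord] = []
    for z in range(Z - params.drop_tail):
        for t in range(T):
            plane = vox[:, :, z, t]
            si = float(plane.sum())
            if si == 0.0:
                continue
            path = out_dir / encode_slice_filename(volume.subject_id, z, t)
            write_slice_png(plane, path, window, params.bit_depth)
            records.append(SliceRecord(subject_id=volume.subject_id, label=volume.label,
                                       z=z, t=t, path=str(path), sum_intensity=si))
    return records


def decompose_cohort(volumes: list[SubjectVolume], params: DecomposeParams,
                     out_dir: str | Path) -> list[SliceRecord]:
    records: list[SliceRecord] = []
    for vol in volumes:
        records.extend(decompose_volume(vol, params, Path(out_dir) / vol.subject_id))
    return records


def build_manifest(records: list[SliceRecord],
                   split_assignment: dict[str, str]) -> pd.DataFrame:
    """One row per slice with its subject's split; filenames parse back
    losslessly to (subject_id, z, t)."""
    rows = []
    for rec in records:
        if rec.subject_id not in split_assignment:
            raise KeyError(f"subject {rec.subject_id!r} missing from split assignment")
        rows.append({
            "path": rec.path,
            "subject_id": rec.subject_id,
            "label": rec.label,
            "split": split_assignment[rec.subject_id],
            "z": rec.z,
            "t": rec.t,
        })
    columns = ["path", "subject_id", "label", "split", "z", "t"]
    if not rows:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(rows, columns=columns).sort_values(
        ["subject_id", "z", "t"], kind="stable").reset_index(drop=True)
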