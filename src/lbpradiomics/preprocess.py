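"""NIfTI reading, slice selection and resizing for the radiomics pipeline.

Volumes are loaded with nibabel and reoriented so the two in-plane axes come
first (a per-slice matrix transpose), optionally collapsed over time for
4-D resting-state scans, and sliced along the third axis. Selected slices
are resized bilinearly to a fixed 180x180 raster so histogram counts are
comparable across subjects. Slices whose native in-plane size is below
180x180 can be excluded, mirroring a cohort-curation rule for small scans.

The default slice window picks every 10th slice from index 100 to 150,
capped at five slices (100, 110, 120, 130, 140) — a central-brain band for
~205-slice T1 volumes. Short volumes (e.g. 27-slice resting scans) must be
given an explicit, modality-appropriate index list.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from skimage.transform import resize

__all__ = [
    "VolumeRecord",
    "SliceSet",
    "load_volume",
    "reduce_time",
    "select_slices",
    "keep_slice",
    "load_manifest",
    "TARGET_SIDE",
]

#: Fixed in-plane raster side after resizing.
TARGET_SIDE = 180


@dataclass
class VolumeRecord:
    """A loaded scan: axes ordered (row, col, slice[, time])."""

    subject_id: str
    modality: str  # "T1" | "rsfMRI"
    data: np.ndarray
    source_path: str | None = None

    @property
    def slice_count(self) -> int:
        return int(self.data.shape[2])

    @property
    def n_timepoints(self) -> int | None:
        return int(self.data.shape[3]) if self.data.ndim == 4 else None


@dataclass
class SliceSet:
    """Ordered, resized 2-D slices selected from one subject's volume."""

    subject_id: str
    slices: list[np.ndarray]
    slice_indices: list[int]


def load_volume(path, subject_id: str | None = None, modality: str = "T1") -> VolumeRecord:
    """Read a NIfTI file into a VolumeRecord.

    The in-plane matrix is transposed (axes 0 and 1 swapped) so slices are
    accessed as ``data[:, :, k]`` with rows first.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
        arr = np.asarray(img.dataobj)
    except Exception as exc:  # nibabel raises several error types
        raise IOError(f"cannot read NIfTI volume {path}: {exc}") from exc
    if arr.ndim == 3:
        arr = np.transpose(arr, (1, 0, 2))
    elif arr.ndim == 4:
        arr = np.transpose(arr, (1, 0, 2, 3))
    else:
        raise ValueError(
            f"{path}: expected a 3-D or 4-D volume, got {arr.ndim}-D"
        )
    sid = subject_id if subject_id is not None else path.name.split(".")[0]
    return VolumeRecord(
        subject_id=sid, modality=modality, data=arr, source_path=str(path)
    )


def reduce_time(volume: VolumeRecord, mode: str = "first") -> VolumeRecord:
    """Collapse a 4-D volume over time; 3-D volumes pass through unchanged."""
    if volume.data.ndim == 3:
        return volume
    if mode == "first":
        data = volume.data[..., 0]
    elif mode == "mean":
        data = volume.data.mean(axis=-1)
    else:
        raise ValueError(f"unknown time-reduction mode {mode!r}; use 'first' or 'mean'")
    return VolumeRecord(
        subject_id=volume.subject_id,
        modality=volume.modality,
        data=data,
        source_path=volume.source_path,
    )


def keep_slice(native_shape: tuple[int, int], min_side: int = TARGET_SIDE) -> bool:
    """Inclusion rule: drop a slice if either native dimension is < 180."""
    return native_shape[0] >= min_side and native_shape[1] >= min_side


def _resize_slice(img: np.ndarray, side: int) -> np.ndarray:
    if img.shape == (side, side):
        return np.asarray(img, dtype=float)
    return resize(
        np.asarray(img, dtype=float),
        (side, side),
        order=1,  # bilinear
        preserve_range=True,
        anti_aliasing=None,
    )


def select_slices(
    volume: VolumeRecord,
    start: int = 100,
    stop: int = 150,
    step: int = 10,
    max_slices: int = 5,
    indices: list[int] | None = None,
    out_side: int = TARGET_SIDE,
    strict_native_size: bool = False,
) -> SliceSet:
    """Extract, filter and resize the analysis slices of one volume.

    Without an explicit ``indices`` list, picks ``start, start+step, ...``
    up to ``stop`` inclusive, capped at ``max_slices`` (defaults give
    100, 110, 120, 130, 140). Raises a configuration error when the volume
    is too short for the requested indices, e.g. 27-slice resting scans
    under the default T1 window — supply a modality-appropriate list then.
    """
    data = volume.data
    if data.ndim != 3:
        raise ValueError("select_slices needs a 3-D volume; reduce_time first")
    if indices is None:
        indices = list(range(start, stop + 1, step))[:max_slices]
    if sorted(set(indices)) != list(indices):
        raise ValueError("slice indices must be strictly increasing")
    n = volume.slice_count
    bad = [i for i in indices if not 0 <= i < n]
    if bad:
        raise ValueError(
            f"subject {volume.subject_id}: slice indices {bad} out of range for a "
            f"{n}-slice volume; supply a modality-appropriate index list "
            f"(e.g. --slices for short resting-state volumes)"
        )
    kept_imgs, kept_idx = [], []
    for i in indices:
        sl = data[:, :, i]
        if strict_native_size and not keep_slice(sl.shape, out_side):
            continue
        kept_imgs.append(_resize_slice(sl, out_side))
        kept_idx.append(i)
    return SliceSet(subject_id=volume.subject_id, slices=kept_imgs, slice_indices=kept_idx)


def load_manifest(path) -> pd.DataFrame:
    """Read a cohort manifest CSV: subject_id, path, modality, label."""
    df = pd.read_csv(path)
    required = {"subject_id", "path", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    if "modality" not in df.columns:
        df["modality"] = "T1"
    if df["subject_id"].duplicated().any():
        raise ValueError("manifest contains duplicated subject_id values")
    return df
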