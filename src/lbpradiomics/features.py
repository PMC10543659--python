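"""Histogram feature assembly: code rasters -> region histograms -> vectors.

One slice coded with a variant of G groups yields G region histograms of
P + 2 bins each, concatenated into a per-slice joint histogram; the
per-slice vectors of a subject are concatenated (slices ascending, regions
ascending, codes ascending) into the subject feature vector. At 5 slices the
lengths are 150 / 300 / 270 / 260 for variants I-IV.

Feature names carry full provenance, ``s{slice}_g{region}_c{code}``, and
parse back to their (slice, region, code) triple.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lbp import CodeImage, encode_all_groups
from .neighborhoods import GroupedNeighborhood, build_grouping

__all__ = [
    "RegionHistogram",
    "FeatureVector",
    "histogram",
    "joint_histogram",
    "subject_vector",
    "feature_name",
    "parse_feature_name",
    "extract_slice_vector",
    "extract_subject_vector",
    "cohort_feature_table",
]

_NAME_RE = re.compile(r"^s(\d+)_g(\d+)_c(\d+)$")


@dataclass
class RegionHistogram:
    """Exact code counts for one group ("region") of one slice."""

    counts: np.ndarray  # int, length P + 2
    region_index: int
    slice_index: int
    variant_id: str
    bits_per_group: int
    n_masked: int = 0


@dataclass
class FeatureVector:
    """Concatenated histogram features with provenance-bearing names."""

    values: np.ndarray
    names: list[str]
    variant_id: str
    subject_id: str | None = None

    def __len__(self) -> int:
        return len(self.values)


def feature_name(slice_index: int, region_index: int, code: int) -> str:
    return f"s{slice_index}_g{region_index}_c{code}"


def parse_feature_name(name: str) -> tuple[int, int, int]:
    """Invert :func:`feature_name` -> (slice_index, region_index, code)."""
    m = _NAME_RE.match(name)
    if m is None:
        raise ValueError(f"not a feature name: {name!r}")
    return int(m.group(1)), int(m.group(2)), int(m.group(3))


def histogram(code_image: CodeImage, slice_index: int = 0) -> RegionHistogram:
    """Tally code occurrences over the valid (unmasked) centers.

    The counts vector has P + 2 bins; their sum equals the number of valid
    centers (raster size minus masked cells).
    """
    n_bins = code_image.bits_per_group + 2
    codes = code_image.codes[code_image.mask]
    if codes.size and (codes.min() < 0 or codes.max() >= n_bins):
        raise ValueError("codes out of range for the declared bit width")
    counts = np.bincount(codes.ravel(), minlength=n_bins).astype(np.int64)
    return RegionHistogram(
        counts=counts,
        region_index=code_image.group_index,
        slice_index=slice_index,
        variant_id=code_image.variant_id,
        bits_per_group=code_image.bits_per_group,
        n_masked=code_image.n_masked,
    )


def joint_histogram(
    histograms: list[RegionHistogram], normalize: bool = False
) -> FeatureVector:
    """Concatenate a slice's region histograms into one per-slice vector.

    Histograms must share variant and slice and be ordered by region. Length
    is ``n_groups * (P + 2)``: 30 / 60 / 54 / 52 for variants I-IV.
    """
    if not histograms:
        raise ValueError("no histograms to join")
    variant = histograms[0].variant_id
    sl = histograms[0].slice_index
    for h in histograms:
        if h.variant_id != variant:
            raise ValueError(
                f"mixed variants in joint histogram: {variant} vs {h.variant_id}"
            )
        if h.slice_index != sl:
            raise ValueError("joint histogram requires a single slice")
    regions = [h.region_index for h in histograms]
    if regions != sorted(regions):
        raise ValueError("histograms must be ordered by region_index")

    parts = []
    for h in histograms:
        part = h.counts.astype(float)
        if normalize and part.sum() > 0:
            part = part / part.sum()  # frequencies over this region's valid centers
        parts.append(part)
    values = np.concatenate(parts)
    names = [
        feature_name(sl, h.region_index, c)
        for h in histograms
        for c in range(h.bits_per_group + 2)
    ]
    return FeatureVector(values=values, names=names, variant_id=variant)


def subject_vector(
    slice_vectors: list[FeatureVector],
    subject_id: str | None = None,
    expected_slices: int | None = 5,
) -> FeatureVector:
    """Concatenate per-slice vectors (slices ascending) for one subject.

    With the default strict mode (``expected_slices=5``) a different slice
    count is rejected; pass ``None`` to accept any count.
    """
    if not slice_vectors:
        raise ValueError("no slice vectors given")
    if expected_slices is not None and len(slice_vectors) != expected_slices:
        raise ValueError(
            f"expected {expected_slices} slices per subject, got "
            f"{len(slice_vectors)} (pass expected_slices=None to allow)"
        )
    variant = slice_vectors[0].variant_id
    if any(v.variant_id != variant for v in slice_vectors):
        raise ValueError("mixed variants across slices")
    values = np.concatenate([v.values for v in slice_vectors])
    names = [n for v in slice_vectors for n in v.names]
    if len(set(names)) != len(names):
        raise ValueError("duplicate feature names; slice indices must differ")
    return FeatureVector(
        values=values, names=names, variant_id=variant, subject_id=subject_id
    )


def extract_slice_vector(
    image: np.ndarray,
    grouping: GroupedNeighborhood,
    slice_index: int = 0,
    normalize: bool = False,
) -> FeatureVector:
    """Full per-slice feature extraction: code all groups, join histograms."""
    code_images = encode_all_groups(image, grouping)
    hists = [histogram(ci, slice_index=slice_index) for ci in code_images]
    return joint_histogram(hists, normalize=normalize)


def extract_subject_vector(
    slices: list[np.ndarray],
    variant_id: str,
    slice_indices: list[int] | None = None,
    subject_id: str | None = None,
    normalize: bool = False,
    expected_slices: int | None = None,
) -> FeatureVector:
    """Per-subject vector from an ordered list of 2-D slices."""
    grouping = build_grouping(variant_id)
    if slice_indices is None:
        slice_indices = list(range(len(slices)))
    vecs = [
        extract_slice_vector(img, grouping, slice_index=si, normalize=normalize)
        for img, si in zip(slices, slice_indices, strict=True)
    ]
    return subject_vector(vecs, subject_id=subject_id, expected_slices=expected_slices)


def cohort_feature_table(
    vectors: list[FeatureVector], labels: list[int]
) -> pd.DataFrame:
    """Stack subject vectors into a table: one row per subject.

    Columns: ``subject_id``, ``label``, then the feature names (identical
    across subjects). Suitable for CSV round-tripping.
    """
    if len(vectors) != len(labels):
        raise ValueError("one label per subject vector required")
    if not vectors:
        raise ValueError("empty cohort")
    names = vectors[0].names
    for v in vectors:
        if v.names != names:
            raise ValueError("inconsistent feature names across subjects")
    df = pd.DataFrame(
        np.vstack([v.values for v in vectors]), columns=names
    )
    df.insert(0, "label", np.asarray(labels, dtype=int))
    df.insert(
        0,
        "subject_id",
        [v.subject_id if v.subject_id is not None else f"S{i:03d}"
         for i, v in enumerate(vectors)],
    )
    return df
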