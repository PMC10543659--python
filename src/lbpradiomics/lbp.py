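"""Rotation-invariant uniform (riu2) LBP coding over grouped neighborhoods.

For a center pixel and an ordered group of P neighbor offsets, each neighbor
contributes bit 1 if its intensity is >= the center intensity. The circular
bit string is then mapped by the riu2 rule:

    U(bits) = number of 0<->1 transitions around the circle
    code    = popcount(bits)  if U <= 2   (a "uniform" pattern)
            = P + 1           otherwise

yielding P + 2 possible codes (0..P+1). The mapping is invariant to circular
shifts of the bit string, hence to rotations of the neighborhood by one
sampling step. Because bits only depend on the *order* of intensities, the
codes are invariant under any strictly increasing intensity transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .neighborhoods import GroupedNeighborhood

__all__ = [
    "CodeImage",
    "riu2_code",
    "riu2_codes_from_bits",
    "riu2_codes_for_ints",
    "encode_group",
    "encode_all_groups",
    "export_code_png",
]


@dataclass
class CodeImage:
    """Raster of riu2 codes for one neighborhood group.

    ``codes[i, j]`` is the code at image position ``(i + m, j + m)`` where
    ``m = valid_margin``; only positions with a full window are coded.
    ``mask`` is False where a NaN fell inside the window — those cells hold
    code 0 but must be ignored (histograms skip them).
    """

    codes: np.ndarray
    variant_id: str
    group_index: int  # 1-based, matching the "region" numbering in reports
    bits_per_group: int
    valid_margin: int
    mask: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.ones(self.codes.shape, dtype=bool)

    @property
    def n_masked(self) -> int:
        return int((~self.mask).sum())


def riu2_code(bits) -> int:
    """riu2 code of one ordered binary sequence of length P in {8, 16, 24}.

    Returns the number of 1-bits if the circular sequence has at most two
    0<->1 transitions, else the non-uniform bucket P + 1.
    """
    arr = np.asarray(bits)
    if arr.ndim != 1 or arr.shape[0] not in (8, 16, 24):
        raise ValueError(
            f"expected a 1-D bit sequence of length 8, 16 or 24, got shape {arr.shape}"
        )
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("bit sequence must contain only 0s and 1s")
    return int(riu2_codes_from_bits(arr.astype(bool)[None, :])[0])


def riu2_codes_from_bits(bits: np.ndarray) -> np.ndarray:
    """Vectorized riu2 mapping.

    Parameters
    ----------
    bits : bool array, shape (..., P)
        Circular bit sequences along the last axis.

    Returns
    -------
    int array, shape (...)
        Codes in 0..P+1.
    """
    bits = np.asarray(bits, dtype=bool)
    p = bits.shape[-1]
    transitions = (bits != np.roll(bits, -1, axis=-1)).sum(axis=-1)
    ones = bits.sum(axis=-1)
    return np.where(transitions <= 2, ones, p + 1).astype(np.int64)


def riu2_codes_for_ints(patterns: np.ndarray, p: int) -> np.ndarray:
    """riu2 codes for integer-encoded patterns (bit k of n = k-th neighbor).

    Handy for exhaustive or sampled enumeration of the code alphabet.
    """
    patterns = np.asarray(patterns, dtype=np.int64)
    shifts = np.arange(p, dtype=np.int64)
    bits = ((patterns[..., None] >> shifts) & 1).astype(bool)
    return riu2_codes_from_bits(bits)


def encode_group(
    image: np.ndarray, grouping: GroupedNeighborhood, group_index: int
) -> CodeImage:
    """Code every interior pixel of ``image`` with one group of a variant.

    Parameters
    ----------
    image : 2-D array
        Grayscale raster, integer or float. Must be at least
        ``grouping.window_side`` on each side.
    grouping : GroupedNeighborhood
    group_index : int
        1-based group ("region") number.

    Returns
    -------
    CodeImage
        Shape ``(H - 2m, W - 2m)`` with ``m = grouping.valid_margin``.
        Centers whose window contains a NaN are masked out.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got {img.ndim}-D")
    side = grouping.window_side
    if img.shape[0] < side or img.shape[1] < side:
        raise ValueError(
            f"image {img.shape} smaller than the {side}x{side} window; "
            f"minimum size is {side}x{side}"
        )
    if not 1 <= group_index <= grouping.n_groups:
        raise ValueError(
            f"group_index must be in 1..{grouping.n_groups}, got {group_index}"
        )

    m = grouping.valid_margin
    h, w = img.shape
    center = img[m : h - m, m : w - m]
    offsets = grouping.groups[group_index - 1]

    bits = np.empty(center.shape + (len(offsets),), dtype=bool)
    for k, (dr, dc) in enumerate(offsets):
        neigh = img[m + dr : h - m + dr, m + dc : w - m + dc]
        bits[..., k] = neigh >= center

    # a NaN anywhere in the full window invalidates the center, even for
    # groups that do not sample the NaN pixel (window-level exclusion rule)
    if img.dtype.kind == "f" and not np.isfinite(img).all():
        from scipy.ndimage import minimum_filter

        finite = np.isfinite(img).astype(np.uint8)
        valid = minimum_filter(finite, size=side)[m : h - m, m : w - m].astype(bool)
    else:
        valid = np.ones(center.shape, dtype=bool)

    codes = riu2_codes_from_bits(bits)
    codes[~valid] = 0
    return CodeImage(
        codes=codes,
        variant_id=grouping.variant_id,
        group_index=group_index,
        bits_per_group=grouping.bits_per_group,
        valid_margin=m,
        mask=valid,
    )


def encode_all_groups(
    image: np.ndarray, grouping: GroupedNeighborhood
) -> list[CodeImage]:
    """Code an image with every group of a variant, in region order."""
    return [
        encode_group(image, grouping, g) for g in range(1, grouping.n_groups + 1)
    ]


def export_code_png(code_image: CodeImage, path) -> None:
    """Write a CodeImage as an 8-bit PNG, codes scaled linearly to 0..255."""
    import imageio.v3 as iio

    top = code_image.bits_per_group + 1
    scaled = np.round(code_image.codes * (255.0 / top)).astype(np.uint8)
    iio.imwrite(path, scaled)
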