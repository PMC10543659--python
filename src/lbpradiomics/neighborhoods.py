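"""Grouped lattice neighborhoods for the four multi-scale LBP variants.

Each variant partitions the pixels of a square window (5x5 or 7x7, center
excluded) into ordered groups ("regions") of equal size. Bits are read per
group in a fixed clockwise spiral order, so the riu2 mapping applied
downstream sees a consistent circular sequence.

Variant overview (window, groups x bits):

========  ======  ===============
variant   window  groups x bits
========  ======  ===============
I         5x5     3 x 8
II        7x7     6 x 8
III       7x7     3 x 16
IV        7x7     2 x 24
========  ======  ===============

The pixel-to-group assignment follows a concentric-ring spiral: rings are
traversed clockwise starting at the top-left corner, inner ring first, and
the resulting sequence is cut into consecutive chunks of the group size.
The grouping object is plain data, so alternative assignments can be swapped
in without touching the coder.
"""

from __future__ import annotations

from dataclasses import dataclass

Offset = tuple[int, int]

#: Valid variant identifiers.
VARIANTS = ("I", "II", "III", "IV")

_VARIANT_LAYOUT = {
    # variant: (window_side, n_groups, bits_per_group)
    "I": (5, 3, 8),
    "II": (7, 6, 8),
    "III": (7, 3, 16),
    "IV": (7, 2, 24),
}


@dataclass(frozen=True)
class GroupedNeighborhood:
    """Geometry of one variant: window size and ordered pixel groups.

    Attributes
    ----------
    variant_id : str
        One of ``"I"``, ``"II"``, ``"III"``, ``"IV"``.
    window_side : int
        Side of the square window (5 or 7).
    radius : int
        Maximum Chebyshev distance of any offset, ``(window_side - 1) // 2``.
    groups : tuple of tuple of (int, int)
        Ordered groups of (row, col) displacements from the center pixel;
        each group is read in this order when forming the bit string.
    bits_per_group : int
        Number of offsets per group (8, 16 or 24); the LBP code length P.
    """

    variant_id: str
    window_side: int
    radius: int
    groups: tuple[tuple[Offset, ...], ...]
    bits_per_group: int

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def valid_margin(self) -> int:
        """Border width (pixels) where no full window fits."""
        return self.radius

    def all_offsets(self) -> tuple[Offset, ...]:
        return tuple(off for g in self.groups for off in g)


def _ring(r: int) -> list[Offset]:
    """Offsets at Chebyshev distance r, clockwise from the top-left corner.

    With image convention (row grows downward), the traversal runs right
    along the top edge, down the right edge, left along the bottom edge and
    up the left edge: a clockwise circuit of 8*r pixels.
    """
    top = [(-r, c) for c in range(-r, r + 1)]
    right = [(rr, r) for rr in range(-r + 1, r + 1)]
    bottom = [(r, c) for c in range(r - 1, -r - 1, -1)]
    left = [(rr, -r) for rr in range(r - 1, -r, -1)]
    return top + right + bottom + left


def _spiral(window_side: int) -> list[Offset]:
    """All non-center window offsets, inner ring first, each ring clockwise."""
    radius = (window_side - 1) // 2
    out: list[Offset] = []
    for r in range(1, radius + 1):
        out.extend(_ring(r))
    return out


def build_grouping(variant_id: str) -> GroupedNeighborhood:
    """Return the canonical grouped neighborhood for a variant.

    Deterministic: repeated calls return equal objects.

    Raises
    ------
    ValueError
        If ``variant_id`` is not one of ``VARIANTS``.
    """
    if variant_id not in _VARIANT_LAYOUT:
        raise ValueError(
            f"unknown LBP variant {variant_id!r}; expected one of {VARIANTS}"
        )
    window_side, n_groups, bits = _VARIANT_LAYOUT[variant_id]
    spiral = _spiral(window_side)
    assert len(spiral) == n_groups * bits == window_side**2 - 1
    groups = tuple(
        tuple(spiral[k * bits : (k + 1) * bits]) for k in range(n_groups)
    )
    return GroupedNeighborhood(
        variant_id=variant_id,
        window_side=window_side,
        radius=(window_side - 1) // 2,
        groups=groups,
        bits_per_group=bits,
    )
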