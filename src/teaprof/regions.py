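"""Fixed measurement regions expressed as fractions of the frame.

The pose computation averages shoot depths inside two fixed rectangles: a
central one (near) and one at the left edge (far). Regions are stored as
fractional bounds so the same configuration works at any resolution;
fractions map to half-open pixel ranges via ``floor(frac * extent)``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ParameterError


@dataclass(frozen=True)
class RegionSpec:
    """Axis-aligned rectangle as fractions of image width/height."""

    col_lo: float
    col_hi: float
    row_lo: float
    row_hi: float

    def __post_init__(self) -> None:
        for name in ("col_lo", "col_hi", "row_lo", "row_hi"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} outside [0, 1]")
        if not (self.col_lo < self.col_hi and self.row_lo < self.row_hi):
            raise ParameterError("region bounds must satisfy lo < hi on both axes")

    def to_slices(self, shape: tuple[int, ...]) -> tuple[slice, slice]:
        """Half-open pixel slices (rows, cols) for a frame of given shape."""
        h, w = shape[:2]
        r0, r1 = int(self.row_lo * h), int(self.row_hi * h)
        c0, c1 = int(self.col_lo * w), int(self.col_hi * w)
        if r1 <= r0 or c1 <= c0:
            raise ParameterError(
                f"region empty at resolution {h}x{w}: rows {r0}:{r1} cols {c0}:{c1}"
            )
        return slice(r0, r1), slice(c0, c1)


#: Central region feeding l_near (columns 4/14-10/14, rows 3/8-5/8).
NEAR_REGION = RegionSpec(col_lo=4 / 14, col_hi=10 / 14, row_lo=3 / 8, row_hi=5 / 8)

#: Left-edge region feeding l_far (columns 1/14-2/14, rows 3/8-5/8).
FAR_REGION = RegionSpec(col_lo=1 / 14, col_hi=2 / 14, row_lo=3 / 8, row_hi=5 / 8)
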