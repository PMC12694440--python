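"""Cutting-pose computation and cutter motion logic.

Given the region-averaged shoot depths l_near (frame centre) and l_far
(left edge), the cutter must sit L cm below the canopy surface and parallel
to it. Two signed adjustments achieve that:

* height:  d = a_near - l_near - L        (positive = raise the cutter)
* angle:   alpha = (L - (a_far - l_far)) * 180 / (r * pi)  degrees
           (positive = rotate the cutter's left end down toward the canopy)

where a_near / a_far are the fixed camera-to-cutter vertical distances and
r is the distance from the bracket's rotation point to the cutter's left
end. The rotation is driven by a screw stepper whose extension Delta-x maps
to alpha through the law of cosines in the bracket-rod-cutter triangle
(sides b, r, and c + Delta-x); this module solves that linkage in closed
form and guards the mechanism limits.

A configurable decision table quantizes (l_near, l_far) into one of ten
motion types (rise / fall / hold x rotate up / down / hold, plus
out-of-range) mirroring the host computer's per-frame motion logic.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigError, MechanismLimitError, ParameterError


@dataclass(frozen=True)
class RigConfig:
    """Fixed machine geometry, all lengths in cm.

    ``r`` defaults to 114 cm, the rotation-point-to-cutter-left distance of
    the reference rig; ``b`` (bracket), ``m`` (rotation point to cutter
    middle) and ``c_zero`` (stepper-to-cutter-middle rod length at the zero
    point) are per-deployment measurements.
    """

    a_near: float = 55.0
    a_far: float = 61.0
    L: float = 10.0
    r: float = 114.0
    b: float = 40.0
    m: float = 10.0
    c_zero: float = 80.0

    def __post_init__(self) -> None:
        for name in ("a_near", "a_far", "L", "r", "b", "m", "c_zero"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"RigConfig.{name} must be positive")
        if not abs(self.b - self.r) < self.c_zero < self.b + self.r:
            raise ParameterError(
                "triangle inequality |b - r| < c_zero < b + r violated"
            )


class VerticalMotion(enum.Enum):
    RISE = "rise"
    FALL = "fall"
    HOLD = "hold"
    OUT_OF_RANGE = "out_of_range"


class RotationMotion(enum.Enum):
    ROTATE_UP = "rotate_up"
    ROTATE_DOWN = "rotate_down"
    HOLD = "hold"
    OUT_OF_RANGE = "out_of_range"


@dataclass(frozen=True)
class MotionDecision:
    vertical: VerticalMotion
    rotation: RotationMotion

    @property
    def is_noop(self) -> bool:
        return self.vertical is VerticalMotion.HOLD and self.rotation is RotationMotion.HOLD


@dataclass(frozen=True)
class CuttingPose:
    """Signed height/angle adjustment plus the actuator displacement."""

    d: float  # cm, positive = raise
    alpha: float  # degrees, positive = left end down
    delta_x: float  # cm of stepper travel
    noop: bool = False


def compute_d(rig: RigConfig, l_near: float) -> float:
    """Height adjustment d = a_near - l_near - L (cm, positive = raise)."""
    if l_near <= 0:
        raise ParameterError(f"l_near must be positive, got {l_near}")
    return rig.a_near - l_near - rig.L


def compute_alpha(rig: RigConfig, l_far: float) -> float:
    """Angle adjustment alpha = (L - (a_far - l_far)) * 180/(r*pi) degrees."""
    if l_far <= 0:
        raise ParameterError(f"l_far must be positive, got {l_far}")
    return (rig.L - (rig.a_far - l_far)) * 180.0 / (rig.r * math.pi)


def _linkage_angle(b: float, r: float, c: float) -> float:
    """Interior angle (radians) opposite the rod of length c, by law of cosines."""
    arg = (b * b + r * r - c * c) / (2.0 * b * r)
    if not -1.0 <= arg <= 1.0:
        raise MechanismLimitError(f"rod length {c} outside the linkage's reach")
    return math.acos(arg)


def forward_alpha(rig: RigConfig, delta_x: float, c_current: float | None = None) -> float:
    """Rotation (degrees) produced by extending the rod by ``delta_x`` cm.

    Direct law-of-cosines evaluation; serves as the forward model whose
    closed-form inverse is :func:`compute_delta_x`.
    """
    c0 = rig.c_zero if c_current is None else c_current
    theta0 = _linkage_angle(rig.b, rig.r, c0)
    theta1 = _linkage_angle(rig.b, rig.r, c0 + delta_x)
    return math.degrees(theta1 - theta0)


def compute_delta_x(rig: RigConfig, alpha: float, c_current: float | None = None) -> float:
    """Stepper travel (cm) that rotates the cutter by ``alpha`` degrees.

    Closed-form inversion of the linkage triangle: with theta0 the current
    interior angle, the target angle is theta1 = theta0 + alpha (radians) and
    the required rod length is ``sqrt(b^2 + r^2 - 2 b r cos(theta1))``.
    Raises :class:`MechanismLimitError` if theta1 leaves (0, pi).
    """
    c0 = rig.c_zero if c_current is None else c_current
    theta0 = _linkage_angle(rig.b, rig.r, c0)
    theta1 = theta0 + math.radians(alpha)
    if not 0.0 < theta1 < math.pi:
        raise MechanismLimitError(
            f"target rotation {alpha:.3f} deg drives the linkage angle out of (0, 180) deg"
        )
    c1 = math.sqrt(rig.b**2 + rig.r**2 - 2.0 * rig.b * rig.r * math.cos(theta1))
    return c1 - c0


# ---------------------------------------------------------------------------
# Motion decision table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Band:
    """Closed-open interval [lo, hi) in cm."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ConfigError(f"band [{self.lo}, {self.hi}) is empty")

    def __contains__(self, value: float) -> bool:
        return self.lo <= value < self.hi


def _validate_partition(bands: tuple[Band, ...], axis: str) -> None:
    if not bands:
        raise ConfigError(f"{axis} axis has no bands")
    for prev, nxt in zip(bands, bands[1:]):
        if nxt.lo < prev.hi:
            raise ConfigError(f"{axis} bands overlap at {nxt.lo}")
        if nxt.lo > prev.hi:
            raise ConfigError(f"{axis} bands leave a gap at {prev.hi}")


@dataclass(frozen=True)
class DecisionTable:
    """Grid of motion decisions over (l_near band, l_far band) cells.

    ``near_bands`` and ``far_bands`` must each partition their operating
    range (contiguous, non-overlapping, ascending). ``grid`` maps the band
    index pair to a :class:`MotionDecision`; every cell must be present so
    exactly one entry matches any in-range pair. Values outside an axis'
    coverage yield ``OUT_OF_RANGE`` on that axis.
    """

    near_bands: tuple[Band, ...]
    far_bands: tuple[Band, ...]
    grid: dict[tuple[int, int], MotionDecision] = field(repr=False)

    def __post_init__(self) -> None:
        _validate_partition(self.near_bands, "l_near")
        _validate_partition(self.far_bands, "l_far")
        want = {
            (i, j)
            for i in range(len(self.near_bands))
            for j in range(len(self.far_bands))
        }
        if set(self.grid) != want:
            raise ConfigError("decision grid must cover every (near, far) band cell")

    @staticmethod
    def _locate(bands: tuple[Band, ...], value: float) -> int | None:
        for idx, band in enumerate(bands):
            if value in band:
                return idx
        return None

    def lookup(self, l_near: float, l_far: float) -> MotionDecision:
        i = self._locate(self.near_bands, l_near)
        j = self._locate(self.far_bands, l_far)
        if i is not None and j is not None:
            return self.grid[(i, j)]
        vertical = VerticalMotion.OUT_OF_RANGE
        rotation = RotationMotion.OUT_OF_RANGE
        if i is not None:
            vertical = self._vertical_only(i)
        if j is not None:
            rotation = self._rotation_only(j, i)
        return MotionDecision(vertical=vertical, rotation=rotation)

    def _vertical_only(self, i: int) -> VerticalMotion:
        # vertical action is constant along a near band's row
        return self.grid[(i, 0)].vertical

    def _rotation_only(self, j: int, i: int | None) -> RotationMotion:
        # with the near axis unknown, read the rotation from the middle row
        mid = len(self.near_bands) // 2 if i is None else i
        return self.grid[(mid, j)].rotation

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "near_bands": [[b.lo, b.hi] for b in self.near_bands],
            "far_bands": [[b.lo, b.hi] for b in self.far_bands],
            "grid": [
                {
                    "near": i,
                    "far": j,
                    "vertical": dec.vertical.value,
                    "rotation": dec.rotation.value,
                }
                for (i, j), dec in sorted(self.grid.items())
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "DecisionTable":
        try:
            near = tuple(Band(lo, hi) for lo, hi in data["near_bands"])
            far = tuple(Band(lo, hi) for lo, hi in data["far_bands"])
            grid = {
                (e["near"], e["far"]): MotionDecision(
                    vertical=VerticalMotion(e["vertical"]),
                    rotation=RotationMotion(e["rotation"]),
                )
                for e in data["grid"]
            }
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"malformed decision table: {exc}") from exc
        return cls(near_bands=near, far_bands=far, grid=grid)

    @classmethod
    def load(cls, path: str | Path) -> "DecisionTable":
        return cls.from_dict(json.loads(Path(path).read_text()))


def default_decision_table() -> DecisionTable:
    """Default ten-type motion table for the reference rig.

    Near (l_near) bands: [35, 43) rise, [43, 47) hold, [47, 55) fall.
    Far (l_far) bands: [43, 51), [51, 55) ideal, [55, 63).
    The rotation in each cell follows the left end's deviation *relative to*
    the centre's: e.g. a low l_near (cutter too deep at centre, must rise)
    combined with an ideal absolute l_far means the left end will sit too
    high after the rise, so the cell is (rise, rotate_down).
    """
    near = (Band(35.0, 43.0), Band(43.0, 47.0), Band(47.0, 55.0))
    far = (Band(43.0, 51.0), Band(51.0, 55.0), Band(55.0, 63.0))
    vertical = {0: VerticalMotion.RISE, 1: VerticalMotion.HOLD, 2: VerticalMotion.FALL}
    grid = {}
    for i in range(3):
        for j in range(3):
            rel = (j - 1) - (i - 1)  # far deviation class minus near deviation class
            if rel > 0:
                rot = RotationMotion.ROTATE_DOWN
            elif rel < 0:
                rot = RotationMotion.ROTATE_UP
            else:
                rot = RotationMotion.HOLD
            grid[(i, j)] = MotionDecision(vertical=vertical[i], rotation=rot)
    return DecisionTable(near_bands=near, far_bands=far, grid=grid)


def decide_motion(table: DecisionTable, l_near: float, l_far: float) -> MotionDecision:
    """Motion type for a measured (l_near, l_far) pair."""
    return table.lookup(l_near, l_far)


def pose_pipeline(
    rig: RigConfig,
    table: DecisionTable,
    l_near: float,
    l_far: float,
) -> tuple[CuttingPose, MotionDecision]:
    """Compute (d, alpha, delta_x) and the motion decision in one call.

    The pose is always reported; when the decision is (hold, hold) it is
    flagged as a no-op so the controller can skip actuation.
    """
    d = compute_d(rig, l_near)
    alpha = compute_alpha(rig, l_far)
    delta_x = compute_delta_x(rig, alpha)
    decision = decide_motion(table, l_near, l_far)
    pose = CuttingPose(d=d, alpha=alpha, delta_x=delta_x, noop=decision.is_noop)
    return pose, decision


@dataclass
class VirtualCutter:
    """Minimal closed-loop model of the cutter/camera assembly.

    The camera rides on the cutter, so raising the cutter by d increases
    every measured depth by d, and rotating the left end down by alpha
    shortens the left-region depth by the arc length r * alpha (radians).
    Height moves are exact; the angle formula deliberately ignores the
    simultaneous height move (it is an approximation), so convergence is
    one-step only when the height error is small.
    """

    rig: RigConfig
    l_near: float
    l_far: float

    def apply(self, pose: CuttingPose) -> None:
        self.l_near += pose.d
        self.l_far += pose.d - self.rig.r * math.radians(pose.alpha)
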