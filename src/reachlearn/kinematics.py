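"""Arm kinematics, visuomotor distortion tasks, target geometry, and
error-augmentation feedback.

The experiment this package models displays a cursor whose x/y position is an
affine function of the subject's shoulder and elbow *joint angles* rather than
of the hand position.  Because the joint-angle-to-hand map of a two-link arm
is nonlinear, each of the eight axis/sign assignments defines a distinct
nonlinear hand-to-vision distortion.  Reaching targets sit at the vertices of
an equilateral triangle on the display; the six ordered vertex pairs define
the six movement directions used throughout the analysis.

All angles at module interfaces are in degrees; lengths are metres for arm
geometry and centimetres for display coordinates.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ArmGeometry",
    "JointPose",
    "DistortionTask",
    "EACondition",
    "TargetSet",
    "ReachabilityError",
    "CALIBRATION_CM_PER_DEG",
    "CENTER_POSE",
    "DISPLAY_CENTER_CM",
    "inverse_kinematics",
    "forward_kinematics",
    "joint_to_display",
    "make_distortion_tasks",
    "make_target_set",
    "enumerate_ea_coordinates",
    "apply_error_augmentation",
    "resample_path",
]

#: Display calibration: 11 degrees of joint angle span 5 cm of display.
CALIBRATION_CM_PER_DEG = 5.0 / 11.0

#: Display centre in the robot/display frame (cm).
DISPLAY_CENTER_CM = (0.0, 47.0)

#: Equilateral target triangle: side length (cm) and orientation of the
#: first circumradius from the +x axis (deg).
TRIANGLE_SIDE_CM = 15.0
TRIANGLE_ORIENTATION_DEG = 75.243


class ReachabilityError(ValueError):
    """Raised when a wrist position lies outside the two-link workspace."""


@dataclass(frozen=True)
class ArmGeometry:
    """Two-link planar arm: upper-arm and forearm lengths (m).

    ``shoulder_offset`` is the planar distance between the robot's shoulder
    and the subject's shoulder; positions handed to the kinematics routines
    are expected to already be in the subject's shoulder-centred frame, the
    offset is carried only so configurations round-trip.
    """

    L1: float
    L2: float
    shoulder_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.L1 <= 0 or self.L2 <= 0:
            raise ValueError("arm segment lengths must be positive")


@dataclass(frozen=True)
class JointPose:
    """Shoulder and elbow joint angles in degrees (elbow-up convention)."""

    theta_S: float
    theta_E: float


#: Joint pose pinned to the centre of the display.
CENTER_POSE = JointPose(theta_S=2.0, theta_E=111.0)


def forward_kinematics(pose: JointPose, geom: ArmGeometry) -> np.ndarray:
    """Wrist position (m) of the two-link arm for a joint pose.

    Standard planar forward map: the elbow angle is the interior deviation
    from full extension, so the forearm direction is ``theta_S + theta_E``.
    """
    ts = math.radians(pose.theta_S)
    te = math.radians(pose.theta_E)
    x = geom.L1 * math.cos(ts) + geom.L2 * math.cos(ts + te)
    y = geom.L1 * math.sin(ts) + geom.L2 * math.sin(ts + te)
    return np.array([x, y])


def inverse_kinematics(wrist_xy, geom: ArmGeometry) -> JointPose:
    """Joint angles (deg) for a wrist position, elbow-up branch.

    Uses the cosine-rule intermediate ``D`` and quadrant-aware two-argument
    arctangents throughout; the positive square root selects the elbow-up
    solution with ``theta_E`` in (0, 180) degrees.

    Raises
    ------
    ReachabilityError
        If the point lies outside the annulus ``|L1-L2| <= r <= L1+L2``.
    """
    x, y = float(wrist_xy[0]), float(wrist_xy[1])
    r = math.hypot(x, y)
    D = (x * x + y * y - geom.L1**2 - geom.L2**2) / (2.0 * geom.L1 * geom.L2)
    if abs(D) > 1.0 + 1e-12:
        raise ReachabilityError(
            f"wrist at distance {r:.4f} m is outside the reachable annulus "
            f"[{abs(geom.L1 - geom.L2):.4f}, {geom.L1 + geom.L2:.4f}] m"
        )
    D = min(1.0, max(-1.0, D))
    te = math.atan2(math.sqrt(1.0 - D * D), D)
    ts = math.atan2(y, x) - math.atan2(
        geom.L2 * math.sin(te), geom.L1 + geom.L2 * math.cos(te)
    )
    return JointPose(math.degrees(ts), math.degrees(te))


@dataclass(frozen=True)
class DistortionTask:
    """One of the eight joint-angle-to-display mappings (learning tasks).

    ``axis_assignment`` says which joint angle drives display-x
    (``"shoulder_x"`` maps the shoulder angle to x and the elbow angle to y,
    ``"elbow_x"`` the reverse); ``sign_x``/``sign_y`` mirror the axes.  The
    map is affine in joint angles around :data:`CENTER_POSE` but nonlinear in
    hand position.
    """

    task_id: int
    axis_assignment: str
    sign_x: int
    sign_y: int
    calibration: float = CALIBRATION_CM_PER_DEG
    center_pose: JointPose = CENTER_POSE

    def __post_init__(self) -> None:
        if self.axis_assignment not in ("shoulder_x", "elbow_x"):
            raise ValueError(f"unknown axis assignment {self.axis_assignment!r}")
        if self.sign_x not in (-1, 1) or self.sign_y not in (-1, 1):
            raise ValueError("axis signs must be +1 or -1")


def make_distortion_tasks() -> tuple[DistortionTask, ...]:
    """The eight distortion tasks, ids 1-8 in canonical order.

    The published task numbering is a figure-level convention; here task ids
    follow the lexicographic order over (axis assignment, sign_x, sign_y) so
    that task identity is configuration, not science.
    """
    combos = itertools.product(("elbow_x", "shoulder_x"), (-1, 1), (-1, 1))
    return tuple(
        DistortionTask(task_id=i + 1, axis_assignment=ax, sign_x=sx, sign_y=sy)
        for i, (ax, sx, sy) in enumerate(combos)
    )


def joint_to_display(pose: JointPose, task: DistortionTask) -> np.ndarray:
    """Display position (cm) of a joint pose under a distortion task.

    ``display = center + calibration * (sign_x * dtheta_x, sign_y * dtheta_y)``
    where the angle deviations are taken from the task's centre pose.
    """
    ds = pose.theta_S - task.center_pose.theta_S
    de = pose.theta_E - task.center_pose.theta_E
    if task.axis_assignment == "shoulder_x":
        dx, dy = ds, de
    else:
        dx, dy = de, ds
    return np.array(
        [
            DISPLAY_CENTER_CM[0] + task.calibration * task.sign_x * dx,
            DISPLAY_CENTER_CM[1] + task.calibration * task.sign_y * dy,
        ]
    )


@dataclass(frozen=True)
class TargetSet:
    """Reaching targets: vertices of an equilateral triangle on the display.

    ``directions`` are the six ordered vertex pairs (from-index, to-index)
    sorted by movement angle so that direction ids 1..6 step by 60 degrees;
    ``direction_angles_deg[d-1]`` is the movement angle of direction ``d``.
    """

    vertices: np.ndarray
    side_cm: float
    center: tuple[float, float]
    orientation_deg: float
    directions: tuple[tuple[int, int], ...] = field(default=())
    direction_angles_deg: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_directions(self) -> int:
        return len(self.directions)


def make_target_set(
    side_cm: float = TRIANGLE_SIDE_CM,
    center: tuple[float, float] = DISPLAY_CENTER_CM,
    orientation_deg: float = TRIANGLE_ORIENTATION_DEG,
) -> TargetSet:
    """Build the target triangle and the six ordered movement directions."""
    R = side_cm / math.sqrt(3.0)  # circumradius
    angles = orientation_deg + 120.0 * np.arange(3)
    verts = np.column_stack(
        [
            center[0] + R * np.cos(np.radians(angles)),
            center[1] + R * np.sin(np.radians(angles)),
        ]
    )
    pairs = [(i, j) for i in range(3) for j in range(3) if i != j]

    def move_angle(pair):
        v = verts[pair[1]] - verts[pair[0]]
        return math.degrees(math.atan2(v[1], v[0])) % 360.0

    pairs.sort(key=move_angle)
    ang = np.array([move_angle(p) for p in pairs])
    return TargetSet(
        vertices=verts,
        side_cm=side_cm,
        center=center,
        orientation_deg=orientation_deg,
        directions=tuple(pairs),
        direction_angles_deg=ang,
    )


@dataclass(frozen=True)
class EACondition:
    """Error-augmentation feedback condition.

    ``gain`` scales the current visual error; ``offset`` adds a replay of the
    initial-exposure error.  ``EA{gain 1, offset 0}`` is normal, unaugmented
    feedback.
    """

    gain: int
    offset: int

    def __post_init__(self) -> None:
        if self.gain not in (0, 1, 2, 3) or self.offset not in (0, 1, 2):
            raise ValueError(f"EA coordinate ({self.gain},{self.offset}) outside the 4x3 grid")

    @property
    def is_normal(self) -> bool:
        return self.gain == 1 and self.offset == 0


#: The normal-feedback coordinate.
EA_NORMAL = EACondition(1, 0)


def enumerate_ea_coordinates() -> tuple[EACondition, ...]:
    """Full 12-element product set of EA{gain 0..3, offset 0..2}."""
    return tuple(
        EACondition(g, o) for g in (0, 1, 2, 3) for o in (0, 1, 2)
    )


def resample_path(xy: np.ndarray, n: int = 100) -> np.ndarray:
    """Resample a planar path onto ``n`` equally spaced arc-length stations.

    Raises ``ValueError`` for paths of zero total length.
    """
    xy = np.asarray(xy, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2 or len(xy) < 2:
        raise ValueError("path must be an (n, 2) array with n >= 2")
    seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0.0:
        raise ValueError("cannot resample a zero-length path")
    grid = np.linspace(0.0, s[-1], n)
    return np.column_stack([np.interp(grid, s, xy[:, 0]), np.interp(grid, s, xy[:, 1])])


def apply_error_augmentation(
    cursor_path: np.ndarray,
    ideal_path: np.ndarray,
    ie_path: np.ndarray,
    ea: EACondition,
) -> np.ndarray:
    """Augmented cursor path under an EA condition.

    Pointwise, on a common path-length grid::

        augmented = ideal + gain * (cursor - ideal) + offset * (ie - ideal)

    All three paths must already be resampled onto the same number of
    arc-length stations (see :func:`resample_path`).
    """
    cursor = np.asarray(cursor_path, dtype=float)
    ideal = np.asarray(ideal_path, dtype=float)
    ie = np.asarray(ie_path, dtype=float)
    if not (cursor.shape == ideal.shape == ie.shape):
        raise ValueError(
            f"path grids differ: cursor {cursor.shape}, ideal {ideal.shape}, ie {ie.shape}"
        )
    return ideal + ea.gain * (cursor - ideal) + ea.offset * (ie - ideal)
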