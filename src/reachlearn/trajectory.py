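"""Per-trial movement metrics: submovement segmentation and the signed
maximum-error observation.

The analysis reduces each reach to a single scalar: the maximum pointwise
L2 distance between the first submovement of the cursor path and the ideal
straight (minimum-jerk) line, signed by which side of the line the launch
went relative to the subject's initial-exposure movement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, peak_prominences

from .kinematics import resample_path

__all__ = [
    "Trajectory",
    "Submovement",
    "SignedMaxError",
    "NoSubmovementError",
    "minimum_jerk_path",
    "detect_speed_humps",
    "first_submovement",
    "signed_max_error",
]

#: Speed-profile thresholds (cm/s): a hump must peak above PEAK_THRESH and
#: drop by more than DROP on either side; submovement boundaries are marked
#: at the lowest speed below BOUNDARY.
PEAK_THRESH_CM_S = 14.0
DROP_CM_S = 2.0
BOUNDARY_CM_S = 5.0


class NoSubmovementError(ValueError):
    """Raised when a trajectory contains no qualifying speed hump."""


@dataclass
class Trajectory:
    """Time-ordered planar samples in display centimetres."""

    t: np.ndarray
    xy: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.t.ndim != 1 or self.xy.shape != (len(self.t), 2):
            raise ValueError("trajectory needs matching t (n,) and xy (n, 2)")
        if len(self.t) < 3:
            raise ValueError("trajectory needs at least 3 samples")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time stamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    def speed(self, smooth_window: int = 5) -> np.ndarray:
        """Tangential speed (cm/s) by central differences, then a moving
        average of ``smooth_window`` samples (1 disables smoothing)."""
        vx = np.gradient(self.xy[:, 0], self.t)
        vy = np.gradient(self.xy[:, 1], self.t)
        sp = np.hypot(vx, vy)
        if smooth_window > 1:
            w = min(smooth_window, len(sp))
            pad = w // 2
            padded = np.pad(sp, pad, mode="edge")
            sp = np.convolve(padded, np.ones(w) / w, mode="same")[pad:pad + len(self.t)]
        return sp


@dataclass(frozen=True)
class Submovement:
    """A speed hump: onset/offset sample indices and peak speed (cm/s)."""

    onset_idx: int
    offset_idx: int
    peak_idx: int
    peak_speed: float


@dataclass(frozen=True)
class SignedMaxError:
    """Signed maximum L2 deviation (cm) and the grid index where it occurs."""

    value: float
    argmax_idx: int


def minimum_jerk_path(start, goal, duration: float = 1.0, n: int = 100) -> Trajectory:
    """Straight-line reach with the minimum-jerk speed profile.

    Progress along the line follows the quintic ``s(tau) = 10 tau^3 -
    15 tau^4 + 6 tau^5``; peak speed is ``1.875 * distance / duration`` at
    the midpoint.
    """
    if n < 2:
        raise ValueError("need at least 2 samples")
    if duration <= 0:
        raise ValueError("duration must be positive")
    start = np.asarray(start, dtype=float)
    goal = np.asarray(goal, dtype=float)
    if np.allclose(start, goal):
        raise ValueError("degenerate path: start and goal coincide")
    tau = np.linspace(0.0, 1.0, n)
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    xy = start[None, :] + s[:, None] * (goal - start)[None, :]
    return Trajectory(t=tau * duration, xy=xy)


def detect_speed_humps(
    traj: Trajectory,
    peak_thresh: float = PEAK_THRESH_CM_S,
    drop: float = DROP_CM_S,
    smooth_window: int = 5,
    speed: np.ndarray | None = None,
) -> list[Submovement]:
    """Prominent humps in the speed profile; their count approximates the
    number of segmented movements in a trial.

    A hump is a local maximum above ``peak_thresh`` whose speed drops by
    more than ``drop`` on both sides (peak prominence).  ``speed`` can be
    supplied directly to bypass differentiation/smoothing.
    """
    sp = traj.speed(smooth_window) if speed is None else np.asarray(speed, dtype=float)
    if len(sp) < 3:
        return []
    peaks, _ = find_peaks(sp)
    if len(peaks) == 0:
        return []
    prom, left_bases, right_bases = peak_prominences(sp, peaks)
    out = []
    for pk, pr, lb, rb in zip(peaks, prom, left_bases, right_bases):
        if sp[pk] > peak_thresh and pr > drop:
            out.append(Submovement(int(lb), int(rb), int(pk), float(sp[pk])))
    return out


def first_submovement(
    traj: Trajectory,
    peak_thresh: float = PEAK_THRESH_CM_S,
    drop: float = DROP_CM_S,
    boundary: float = BOUNDARY_CM_S,
    smooth_window: int = 5,
    speed: np.ndarray | None = None,
) -> Submovement:
    """Boundaries of the initial ballistic launch.

    Onset and termination are the lowest-speed samples below ``boundary``
    flanking the first qualifying hump (between trajectory start and the
    peak, and between the peak and the next hump's peak or trajectory end);
    if no sub-threshold sample exists on a side the trajectory end is used.
    Ties take the first occurrence.
    """
    sp = traj.speed(smooth_window) if speed is None else np.asarray(speed, dtype=float)
    humps = detect_speed_humps(traj, peak_thresh, drop, smooth_window, speed=sp)
    if not humps:
        raise NoSubmovementError(
            f"no speed hump above {peak_thresh} cm/s with >{drop} cm/s drops"
        )
    first = humps[0]
    pk = first.peak_idx
    right_stop = humps[1].peak_idx if len(humps) > 1 else len(sp) - 1

    left = sp[: pk + 1]
    below = np.flatnonzero(left < boundary)
    onset = int(below[np.argmin(left[below])]) if len(below) else 0

    right = sp[pk : right_stop + 1]
    below = np.flatnonzero(right < boundary)
    offset = int(pk + below[np.argmin(right[below])]) if len(below) else right_stop
    return Submovement(onset, offset, pk, first.peak_speed)


def signed_max_error(
    traj: Trajectory,
    ideal: Trajectory,
    ie_side: int = 1,
    n_grid: int = 100,
) -> SignedMaxError:
    """Signed maximum L2-norm error of a (sub)movement against the ideal line.

    Both paths are resampled onto a common arc-length grid (the ideal path's
    time parameterisation is unknown in general); the magnitude is the
    maximum pointwise distance, and the sign is positive iff the cursor at
    the maximum lies on the same side of the start->goal line as the
    initial-exposure launch (``ie_side`` is +1/-1 in the same cross-product
    convention).  Argmax ties take the first occurrence.
    """
    if ie_side not in (-1, 1):
        raise ValueError("ie_side must be +1 or -1")
    cursor = resample_path(traj.xy, n_grid)
    line = resample_path(ideal.xy, n_grid)
    dist = np.linalg.norm(cursor - line, axis=1)
    idx = int(np.argmax(dist))
    mag = float(dist[idx])
    start, goal = line[0], line[-1]
    chord = goal - start
    cross = chord[0] * (cursor[idx][1] - start[1]) - chord[1] * (cursor[idx][0] - start[0])
    side = 1 if cross >= 0 else -1
    value = mag if side == ie_side else -mag
    if mag == 0.0:
        value = 0.0
    return SignedMaxError(value=value, argmax_idx=idx)
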