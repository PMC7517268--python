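"""Binarize 2-D group trajectories into collective-state sequences.

Local setting: an individual is ON when it simultaneously (i) has a
neighbour closer than ``xi_D``, (ii) has a neighbour inside its visual
field of total width ``xi_VF`` around its velocity heading, and (iii)
turned by at least ``xi_TR`` radians since the previous step.

Global setting: an individual is ON when its heading deviates from the
group mean direction by at most ``Xi_AD`` and it sits within ``Xi_CM`` of
the centre of mass.

Timescales are realised by striding the 120-fps trajectory every
``dt_frames`` frames and smoothing with a centred three-point moving
average (ends truncated).  Comparison conventions (strict for distance
and visual field, inclusive for turning rate and both global criteria)
follow the threshold symbols exactly; two deliberately configurable
conventions are exposed as flags:

* ``vf_half_angle`` (default True): ``xi_VF`` is the TOTAL field width and
  a neighbour is seen when the bearing angle is < xi_VF / 2.  Setting it
  to False restores the literal reading (bearing < xi_VF), under which all
  widths above pi are equivalent.
* ``view_toward_neighbour`` (default True): bearings are measured to the
  vector from the focal fish toward its neighbour.  False uses the
  reversed (neighbour-to-self) vector.

Zero-velocity frames leave the heading undefined: the visual-field and
turning bits are set to 0 and the occurrences are counted on the returned
sequence.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Trajectory",
    "LocalThresholds",
    "GlobalThresholds",
    "CollectiveStateSequence",
    "resample",
    "velocities",
    "distance_state",
    "visual_field_state",
    "turning_state",
    "local_collective_state",
    "global_collective_state",
]

DEFAULT_FPS = 120.0
#: default frame strides (Delta t = stride / 120 s)
DEFAULT_STRIDES = (5, 10, 20, 40, 80, 120)


@dataclass(frozen=True)
class Trajectory:
    """Per-individual 2-D positions (mm) on a uniform time base.

    ``positions`` has shape (n_frames, n_individuals, 2).
    """

    positions: np.ndarray
    fps: float = DEFAULT_FPS
    ids: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 3 or pos.shape[2] != 2:
            raise ValueError("positions must have shape (time, individual, 2)")
        if not np.isfinite(pos).all():
            raise ValueError("positions contain non-finite values (missing frames?)")
        n = pos.shape[1]
        if not 2 <= n <= 6:
            raise ValueError(f"expected 2..6 individuals, got {n}")
        ids = tuple(self.ids) if self.ids else tuple(str(i) for i in range(n))
        if len(ids) != n:
            raise ValueError("ids length must match the number of individuals")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "ids", ids)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.positions.shape[1]

    def to_csv(self, path) -> None:
        """Long format: ``frame,id,x_mm,y_mm``."""
        t, n, _ = self.positions.shape
        frames = np.repeat(np.arange(t), n)
        ids = np.tile(np.asarray(self.ids, dtype=object), t)
        flat = self.positions.reshape(t * n, 2)
        pd.DataFrame(
            {"frame": frames, "id": ids, "x_mm": flat[:, 0], "y_mm": flat[:, 1]}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, fps: float = DEFAULT_FPS) -> "Trajectory":
        df = pd.read_csv(path)
        required = {"frame", "id", "x_mm", "y_mm"}
        if not required.issubset(df.columns):
            missing = sorted(required - set(df.columns))
            raise ValueError(f"trajectory CSV missing columns: {missing}")
        ids = sorted(df["id"].astype(str).unique())
        frames = np.sort(df["frame"].unique())
        if not np.array_equal(frames, np.arange(frames[0], frames[0] + len(frames))):
            raise ValueError("trajectory CSV has missing frames")
        pos = np.full((len(frames), len(ids), 2), np.nan)
        id_index = {k: i for i, k in enumerate(ids)}
        f0 = frames[0]
        for row in df.itertuples(index=False):
            pos[int(row.frame) - f0, id_index[str(row.id)]] = (row.x_mm, row.y_mm)
        if np.isnan(pos).any():
            bad = int(np.argwhere(np.isnan(pos[:, :, 0]))[0][0]) + f0
            raise ValueError(f"trajectory CSV incomplete near frame {bad}")
        return cls(positions=pos, fps=fps, ids=tuple(ids))


@dataclass(frozen=True)
class LocalThresholds:
    """Distance (mm), visual-field width (rad, total) and turning-rate
    (rad/step) thresholds of the local parameter setting."""

    xi_D: float
    xi_VF: float
    xi_TR: float

    def __post_init__(self) -> None:
        if self.xi_D <= 0:
            raise ValueError("xi_D must be > 0")
        if not 0 < self.xi_VF <= 2 * np.pi:
            raise ValueError("xi_VF must be in (0, 2*pi]")
        if self.xi_TR < 0:
            raise ValueError("xi_TR must be >= 0")

    def as_dict(self) -> dict:
        return {"setting": "local", "xi_D": self.xi_D, "xi_VF": self.xi_VF, "xi_TR": self.xi_TR}


@dataclass(frozen=True)
class GlobalThresholds:
    """Max angular deviation from the mean direction (rad) and max distance
    from the centre of mass (mm) of the global parameter setting."""

    Xi_AD: float
    Xi_CM: float

    def __post_init__(self) -> None:
        if self.Xi_AD <= 0 or self.Xi_CM <= 0:
            raise ValueError("global thresholds must be > 0")

    def as_dict(self) -> dict:
        return {"setting": "global", "Xi_AD": self.Xi_AD, "Xi_CM": self.Xi_CM}


@dataclass(frozen=True)
class CollectiveStateSequence:
    """Time series of N-bit collective states plus its provenance.

    ``states`` has shape (T, N) with entries in {0, 1}; individual ``i``
    maps to bit ``i`` (little-endian) of the state integer.  ``positions``
    and ``velocities`` are the kinematics aligned with each state row (used
    by the leadership metrics).
    """

    states: np.ndarray
    thresholds: Optional[Union[LocalThresholds, GlobalThresholds]]
    dt_frames: int
    fps: float = DEFAULT_FPS
    positions: Optional[np.ndarray] = field(default=None, repr=False)
    velocities: Optional[np.ndarray] = field(default=None, repr=False)
    n_zero_velocity: int = 0
    convention_flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        states = np.asarray(self.states)
        if states.ndim != 2:
            raise ValueError("states must have shape (time, individual)")
        if not np.isin(states, (0, 1)).all():
            raise ValueError("states must be binary")
        object.__setattr__(self, "states", states.astype(np.uint8))

    @property
    def n_individuals(self) -> int:
        return self.states.shape[1]

    @property
    def timescale_seconds(self) -> float:
        return self.dt_frames / self.fps

    def state_ints(self) -> np.ndarray:
        """Little-endian integer encoding of each collective state."""
        weights = 1 << np.arange(self.n_individuals)
        return (self.states.astype(np.int64) * weights).sum(axis=1)

    def to_csv(self, path) -> None:
        cols = {"t": np.arange(len(self.states))}
        for i in range(self.n_individuals):
            cols[f"bit_{i}"] = self.states[:, i]
        pd.DataFrame(cols).to_csv(path, index=False)

    def sidecar(self) -> dict:
        return {
            "thresholds": None if self.thresholds is None else self.thresholds.as_dict(),
            "dt_frames": self.dt_frames,
            "timescale_seconds": self.timescale_seconds,
            "fps": self.fps,
            "n_zero_velocity": self.n_zero_velocity,
            "convention_flags": self.convention_flags,
        }

    def write_sidecar(self, path) -> None:
        Path(path).write_text(json.dumps(self.sidecar(), indent=2))


# ----------------------------------------------------------------------
# kinematics
# ----------------------------------------------------------------------
def resample(traj: Trajectory, dt_frames: int, smooth_before_stride: bool = False) -> Trajectory:
    """Stride every ``dt_frames``-th frame, then smooth each coordinate with
    a centred 3-point moving average (ends truncated).

    ``smooth_before_stride`` reverses the order of the two operations.
    """
    if dt_frames < 1:
        raise ValueError("dt_frames must be a positive integer")

    def smooth(pos: np.ndarray) -> np.ndarray:
        if pos.shape[0] < 3:
            raise ValueError("need at least 3 samples after striding to smooth")
        return (pos[:-2] + pos[1:-1] + pos[2:]) / 3.0

    pos = traj.positions
    if smooth_before_stride:
        pos = smooth(pos)[::dt_frames]
        if pos.shape[0] < 3:
            raise ValueError("sequence too short for this stride")
    else:
        pos = smooth(pos[::dt_frames])
    return Trajectory(positions=pos, fps=traj.fps / dt_frames, ids=traj.ids)


def velocities(traj: Trajectory) -> np.ndarray:
    """Per-step displacement vectors v(t) = x(t) - x(t-1); length T-1."""
    return np.diff(traj.positions, axis=0)


def _angles_between(u: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Unsigned angle in [0, pi] between paired 2-D vectors; NaN where
    either vector is zero."""
    nu = np.linalg.norm(u, axis=-1)
    nw = np.linalg.norm(w, axis=-1)
    denom = nu * nw
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.where(denom > 0, (u * w).sum(axis=-1) / np.where(denom > 0, denom, 1.0), np.nan)
    return np.arccos(np.clip(cosang, -1.0, 1.0))


# ----------------------------------------------------------------------
# single-frame state functions
# ----------------------------------------------------------------------
def distance_state(positions: np.ndarray, i: int, xi_D: float) -> int:
    """1 iff some other individual is strictly closer than ``xi_D``."""
    d = np.linalg.norm(positions - positions[i], axis=-1)
    d[i] = np.inf
    return int((d < xi_D).any())


def visual_field_state(
    positions: np.ndarray,
    velocity_i: np.ndarray,
    i: int,
    xi_VF: float,
    vf_half_angle: bool = True,
    view_toward_neighbour: bool = True,
) -> int:
    """1 iff some other individual lies inside the focal visual field."""
    if np.linalg.norm(velocity_i) == 0:
        return 0
    others = np.array([j for j in range(len(positions)) if j != i])
    offsets = positions[others] - positions[i]
    if not view_toward_neighbour:
        offsets = -offsets
    ang = _angles_between(np.broadcast_to(velocity_i, offsets.shape), offsets)
    finite = ang[np.isfinite(ang)]
    limit = xi_VF / 2.0 if vf_half_angle else xi_VF
    if limit >= np.pi - 1e-12:  # complete visual field
        return int(finite.size > 0)
    return int(np.any(finite < limit))


def turning_state(velocity_now: np.ndarray, velocity_prev: np.ndarray, xi_TR: float) -> int:
    """1 iff the heading rotated by at least ``xi_TR`` radians this step."""
    if np.linalg.norm(velocity_now) == 0 or np.linalg.norm(velocity_prev) == 0:
        return 0
    ang = float(_angles_between(velocity_now, velocity_prev))
    return int(ang >= xi_TR)


# ----------------------------------------------------------------------
# sequence encoders (vectorized)
# ----------------------------------------------------------------------
def _prepare(traj: Trajectory, dt_frames: int, smooth_before_stride: bool):
    r = resample(traj, dt_frames, smooth_before_stride=smooth_before_stride)
    pos = r.positions
    vel = np.diff(pos, axis=0)  # vel[k] = v at time index k+1
    return pos[1:], vel  # aligned: row k <-> time index k+1


def local_collective_state(
    traj: Trajectory,
    thresholds: LocalThresholds,
    dt_frames: int = 1,
    *,
    vf_half_angle: bool = True,
    view_toward_neighbour: bool = True,
    smooth_before_stride: bool = False,
) -> CollectiveStateSequence:
    """Conjunction of the distance, visual-field and turning-rate bits.

    One state row per velocity step; the first row's turning angle is taken
    as zero (no previous heading to compare against).
    """
    pos, vel = _prepare(traj, dt_frames, smooth_before_stride)
    t_len, n, _ = pos.shape

    diffs = pos[:, None, :, :] - pos[:, :, None, :]  # (T, i, j, 2): j - i
    dists = np.linalg.norm(diffs, axis=-1)
    eye = np.eye(n, dtype=bool)
    dists[:, eye] = np.inf
    d_bit = (dists < thresholds.xi_D).any(axis=2)

    speed = np.linalg.norm(vel, axis=-1)
    moving = speed > 0
    view = diffs if view_toward_neighbour else -diffs
    ang = _angles_between(vel[:, :, None, :], view)  # (T, i, j); NaN on diag/zero-vel
    ang[:, eye] = np.nan
    limit = thresholds.xi_VF / 2.0 if vf_half_angle else thresholds.xi_VF
    with np.errstate(invalid="ignore"):
        if limit >= np.pi - 1e-12:  # complete visual field: any neighbour seen
            b_bit = np.isfinite(ang).any(axis=2)
        else:
            b_bit = np.nansum(ang < limit, axis=2) > 0
    b_bit &= moving

    turn = np.full((t_len, n), 0.0)
    turn[1:] = _angles_between(vel[1:], vel[:-1])
    both_moving = np.ones((t_len, n), dtype=bool)
    both_moving[1:] = moving[1:] & moving[:-1]
    t_bit = np.where(both_moving, turn >= thresholds.xi_TR, False)
    # first step: no previous heading, turning angle treated as zero
    t_bit[0] = moving[0] & (0.0 >= thresholds.xi_TR)

    n_zero = int((~moving).sum())
    if n_zero:
        logger.warning("%d zero-velocity samples: visual-field/turning bits set OFF", n_zero)

    states = (d_bit & b_bit & t_bit).astype(np.uint8)
    return CollectiveStateSequence(
        states=states,
        thresholds=thresholds,
        dt_frames=dt_frames,
        fps=traj.fps,
        positions=pos,
        velocities=vel,
        n_zero_velocity=n_zero,
        convention_flags={
            "vf_half_angle": vf_half_angle,
            "view_toward_neighbour": view_toward_neighbour,
            "smooth_before_stride": smooth_before_stride,
        },
    )


def global_collective_state(
    traj: Trajectory,
    thresholds: GlobalThresholds,
    dt_frames: int = 1,
    *,
    smooth_before_stride: bool = False,
) -> CollectiveStateSequence:
    """Conjunction of mean-direction alignment and centre-of-mass proximity
    (both comparisons inclusive)."""
    pos, vel = _prepare(traj, dt_frames, smooth_before_stride)
    t_len, n, _ = pos.shape

    centroid = pos.mean(axis=1, keepdims=True)
    com_bit = np.linalg.norm(pos - centroid, axis=-1) <= thresholds.Xi_CM

    mean_vel = vel.mean(axis=1, keepdims=True)
    ang = _angles_between(np.broadcast_to(mean_vel, vel.shape), vel)
    with np.errstate(invalid="ignore"):
        avd_bit = np.where(np.isfinite(ang), ang <= thresholds.Xi_AD, False)

    n_zero = int((np.linalg.norm(vel, axis=-1) == 0).sum())
    states = (avd_bit & com_bit).astype(np.uint8)
    return CollectiveStateSequence(
        states=states,
        thresholds=thresholds,
        dt_frames=dt_frames,
        fps=traj.fps,
        positions=pos,
        velocities=vel,
        n_zero_velocity=n_zero,
        convention_flags={"smooth_before_stride": smooth_before_stride},
    )
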