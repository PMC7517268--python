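"""Single-OFF-state leadership statistics and cohesion.

Individual indices in this module are 1-based, matching the convention of
the match-rate definitions (``single_off_index`` returns 0 when the state
is not a single-OFF state).  The system cut used at a timestep is the one
attached to the collective state observed then: cuts are computed once per
state, not per timestep.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .iit_core.types import PhiResult
from .state_encoding import CollectiveStateSequence, Trajectory

__all__ = [
    "MatchReport",
    "single_off_index",
    "positional_leader",
    "pl_match_rate",
    "mip_cut_match_rate",
    "cohesion_rate",
    "match_report",
]


@dataclass(frozen=True)
class MatchReport:
    """Leadership/integrity summary for one encoded dataset.

    Rates are percentages in [0, 100]; ``None`` marks an undefined rate
    (empty denominator).
    """

    n_single_off_events: int
    pl_match_rate: Optional[float]
    mip_cut_match_rate: Optional[float]
    cohesion_rate: float
    cohesion_rate_secondary: float
    cohesion_threshold_mm: float = 400.0
    cohesion_threshold_secondary_mm: float = 700.0
    n_undefined_leader: int = 0

    def __post_init__(self) -> None:
        for r in (self.pl_match_rate, self.mip_cut_match_rate):
            if r is not None and not 0.0 <= r <= 100.0:
                raise ValueError("rates must lie in [0, 100]")

    def to_dict(self) -> dict:
        return {
            "n_single_off_events": self.n_single_off_events,
            "pl_match_rate_percent": self.pl_match_rate,
            "mip_cut_match_rate_percent": self.mip_cut_match_rate,
            "cohesion_rate_percent": self.cohesion_rate,
            "cohesion_rate_secondary_percent": self.cohesion_rate_secondary,
            "cohesion_threshold_mm": self.cohesion_threshold_mm,
            "cohesion_threshold_secondary_mm": self.cohesion_threshold_secondary_mm,
            "n_undefined_leader": self.n_undefined_leader,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.to_dict()])


def single_off_index(state: Sequence[int]) -> int:
    """1-based index of the unique OFF individual, else 0."""
    state = np.asarray(state)
    off = np.flatnonzero(state == 0)
    if off.size == 1:
        return int(off[0]) + 1
    return 0


def positional_leader(
    positions: np.ndarray, velocities: np.ndarray, tol: float = 1e-12
) -> Optional[int]:
    """1-based index of the individual furthest forward along the mean
    velocity direction; ``None`` when the mean velocity vanishes.

    Ties (e.g. coincident fish) go to the lowest index.
    """
    v = np.asarray(velocities, float).mean(axis=0)
    norm = np.linalg.norm(v)
    if norm <= tol:
        return None
    proj = np.asarray(positions, float) @ (v / norm)
    return int(np.argmax(proj)) + 1


def _kinematics(seq: CollectiveStateSequence, traj: Optional[Trajectory]):
    if seq.positions is not None and seq.velocities is not None:
        return seq.positions, seq.velocities
    if traj is None:
        raise ValueError("sequence lacks kinematics; pass the source trajectory")
    from .state_encoding import resample

    r = resample(traj, seq.dt_frames)
    pos = r.positions
    vel = np.diff(pos, axis=0)
    return pos[1:], vel


def _single_off_series(seq: CollectiveStateSequence) -> np.ndarray:
    states = seq.states
    n_off = (states == 0).sum(axis=1)
    off_pos = np.argmin(states, axis=1) + 1  # position of first OFF bit
    return np.where(n_off == 1, off_pos, 0)


def pl_match_rate(
    seq: CollectiveStateSequence, traj: Optional[Trajectory] = None
) -> Optional[float]:
    """Percentage of single-OFF timesteps whose OFF individual is the
    positional leader.

    Timesteps with an undefined leader (zero mean velocity) are dropped
    from numerator and denominator; returns ``None`` when no single-OFF
    event remains.
    """
    pos, vel = _kinematics(seq, traj)
    offs = _single_off_series(seq)
    matches = 0
    denom = 0
    for t in np.flatnonzero(offs):
        leader = positional_leader(pos[t], vel[t])
        if leader is None:
            continue
        denom += 1
        if leader == offs[t]:
            matches += 1
    if denom == 0:
        return None
    return 100.0 * matches / denom


def mip_cut_match_rate(
    phi_results: Mapping[int, PhiResult], seq: CollectiveStateSequence
) -> Optional[float]:
    """Percentage of single-OFF timesteps where the state's MIP cut
    bipartition is exactly {OFF individual} vs {rest} (either direction)."""
    offs = _single_off_series(seq)
    ints = seq.state_ints()
    matches = 0
    denom = 0
    for t in np.flatnonzero(offs):
        res = phi_results.get(int(ints[t]))
        if res is None or res.mip_cut is None:
            continue
        denom += 1
        node = int(offs[t]) - 1  # cut parts use 0-based node labels
        cut = res.mip_cut
        if (
            set(cut.from_part) | set(cut.to_part) == set(res.subsystem)
            and cut.severs_exactly(node)
        ):
            matches += 1
    if denom == 0:
        return None
    return 100.0 * matches / denom


def cohesion_rate(traj_or_positions, threshold_mm: float = 400.0) -> float:
    """Percentage of timesteps in which every pairwise distance is within
    (<=) ``threshold_mm``."""
    pos = (
        traj_or_positions.positions
        if isinstance(traj_or_positions, Trajectory)
        else np.asarray(traj_or_positions, float)
    )
    diffs = pos[:, :, None, :] - pos[:, None, :, :]
    dists = np.linalg.norm(diffs, axis=-1)
    cohesive = (dists <= threshold_mm).all(axis=(1, 2))
    return 100.0 * float(cohesive.mean())


def match_report(
    seq: CollectiveStateSequence,
    phi_results: Mapping[int, PhiResult],
    traj: Optional[Trajectory] = None,
    cohesion_threshold_mm: float = 400.0,
    cohesion_threshold_secondary_mm: float = 700.0,
) -> MatchReport:
    """Assemble the per-dataset leadership/cohesion summary row."""
    pos, vel = _kinematics(seq, traj)
    offs = _single_off_series(seq)
    n_events = int((offs > 0).sum())
    n_undef = 0
    for t in np.flatnonzero(offs):
        if positional_leader(pos[t], vel[t]) is None:
            n_undef += 1
    return MatchReport(
        n_single_off_events=n_events,
        pl_match_rate=pl_match_rate(seq, traj),
        mip_cut_match_rate=mip_cut_match_rate(phi_results, seq),
        cohesion_rate=cohesion_rate(pos, cohesion_threshold_mm),
        cohesion_rate_secondary=cohesion_rate(pos, cohesion_threshold_secondary_mm),
        cohesion_threshold_mm=cohesion_threshold_mm,
        cohesion_threshold_secondary_mm=cohesion_threshold_secondary_mm,
        n_undefined_leader=n_undef,
    )
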