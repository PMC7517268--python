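"""Seeded generators for trajectories and abstract TPMs.

The trajectory generators emulate the recording regime the analysis
expects: 120 fps, a bounded 3 x 3 m arena with soft wall repulsion, and
cruising speeds of order 150-350 mm/s.  All generators are deterministic
per seed and emit the standard :class:`~swarmphi.state_encoding.Trajectory`
object (or :class:`~swarmphi.iit_core.types.StateByNodeTPM`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .iit_core.types import StateByNodeTPM
from .state_encoding import DEFAULT_FPS, Trajectory

__all__ = [
    "GeneratorConfig",
    "boids_school",
    "leader_follower_chain",
    "independent_walkers",
    "random_markov_tpm",
]

ARENA_MM = 3000.0  # square arena side
WALL_MARGIN_MM = 300.0  # distance over which the wall repulsion ramps up


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs shared by the trajectory generators."""

    n_fish: int = 3
    n_steps: int = 2000
    fps: float = DEFAULT_FPS
    speed_mm_s: float = 250.0
    noise_sd: float = 0.08  # heading noise per frame, rad
    cohesion: float = 0.02
    alignment: float = 0.25
    separation: float = 0.6
    separation_radius_mm: float = 60.0
    leader_bias: float = 0.25  # follower steering gain toward its target
    seed: int = 0

    def __post_init__(self) -> None:
        if not 2 <= self.n_fish <= 6:
            raise ValueError("n_fish must be 2..6")
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")


def _wall_steer(pos: np.ndarray, heading: np.ndarray) -> np.ndarray:
    """Soft repulsion: steer toward the arena centre when near a wall."""
    centre = np.array([ARENA_MM / 2, ARENA_MM / 2])
    margin = np.minimum(pos, ARENA_MM - pos).min(axis=1)
    push = np.clip((WALL_MARGIN_MM - margin) / WALL_MARGIN_MM, 0.0, 1.0)
    to_centre = np.arctan2(centre[1] - pos[:, 1], centre[0] - pos[:, 0])
    delta = _wrap(to_centre - heading)
    return 0.3 * push * delta


def _wrap(a: np.ndarray) -> np.ndarray:
    return (a + np.pi) % (2 * np.pi) - np.pi


def _finalize(pos_hist: np.ndarray, config: GeneratorConfig) -> Trajectory:
    return Trajectory(
        positions=pos_hist,
        fps=config.fps,
        ids=tuple(f"fish{i+1}" for i in range(config.n_fish)),
    )


def boids_school(config: GeneratorConfig) -> Trajectory:
    """Cohesion/alignment/separation school with heading noise.

    With zero interaction weights this reduces to independent correlated
    walkers.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_fish
    step = config.speed_mm_s / config.fps
    centre = ARENA_MM / 2
    pos = centre + rng.uniform(-100.0, 100.0, size=(n, 2))
    heading = rng.uniform(-np.pi, np.pi, size=n)
    hist = np.empty((config.n_steps, n, 2))
    for t in range(config.n_steps):
        hist[t] = pos
        centroid = pos.mean(axis=0)
        delta = np.zeros(n)
        # cohesion: steer toward the centroid of the others
        others_centroid = (centroid * n - pos) / (n - 1)
        coh_vec = others_centroid - pos
        coh_angle = np.arctan2(coh_vec[:, 1], coh_vec[:, 0])
        delta += config.cohesion * _wrap(coh_angle - heading)
        # alignment: steer toward the mean heading of the others
        sin_sum, cos_sum = np.sin(heading).sum(), np.cos(heading).sum()
        mean_others = np.arctan2(sin_sum - np.sin(heading), cos_sum - np.cos(heading))
        delta += config.alignment * _wrap(mean_others - heading)
        # separation: steer away from too-close neighbours
        diffs = pos[:, None, :] - pos[None, :, :]
        dists = np.linalg.norm(diffs, axis=-1)
        np.fill_diagonal(dists, np.inf)
        close = dists < config.separation_radius_mm
        if close.any():
            away = np.zeros((n, 2))
            for i in range(n):
                if close[i].any():
                    away[i] = diffs[i][close[i]].sum(axis=0)
            sep_angle = np.arctan2(away[:, 1], away[:, 0])
            has_sep = close.any(axis=1)
            delta += np.where(
                has_sep, config.separation * _wrap(sep_angle - heading), 0.0
            )
        delta += _wall_steer(pos, heading)
        heading = _wrap(heading + delta + rng.normal(0.0, config.noise_sd, size=n))
        pos = pos + step * np.column_stack([np.cos(heading), np.sin(heading)])
        pos = np.clip(pos, 1.0, ARENA_MM - 1.0)
    return _finalize(hist, config)


def leader_follower_chain(config: GeneratorConfig) -> Trajectory:
    """Fish 1 walks persistently; fish k > 1 chases fish k-1.

    Followers start behind the leader and modulate their speed with the
    gap, so the chain keeps a persistent positional leader.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_fish
    if n < 2:
        raise ValueError("a chain needs at least 2 fish")
    step = config.speed_mm_s / config.fps
    target_gap = 80.0  # mm, preferred follower distance
    heading0 = rng.uniform(-np.pi, np.pi)
    pos = np.empty((n, 2))
    pos[0] = (ARENA_MM / 2, ARENA_MM / 2)
    back = np.array([np.cos(heading0 + np.pi), np.sin(heading0 + np.pi)])
    for k in range(1, n):
        pos[k] = pos[0] + back * target_gap * k + rng.normal(0, 5.0, 2)
    heading = np.full(n, heading0) + rng.normal(0, 0.05, n)
    hist = np.empty((config.n_steps, n, 2))
    for t in range(config.n_steps):
        hist[t] = pos
        new_heading = heading.copy()
        # leader: smooth persistent walk with wall avoidance
        new_heading[0] = _wrap(
            heading[0]
            + _wall_steer(pos[:1], heading[:1])[0]
            + rng.normal(0.0, config.noise_sd)
        )
        speeds = np.full(n, step)
        for k in range(1, n):
            gap_vec = pos[k - 1] - pos[k]
            gap = np.linalg.norm(gap_vec)
            aim = np.arctan2(gap_vec[1], gap_vec[0])
            new_heading[k] = _wrap(
                heading[k]
                + config.leader_bias * _wrap(aim - heading[k])
                + rng.normal(0.0, 0.5 * config.noise_sd)
            )
            # close the gap when trailing, ease off when crowding
            speeds[k] = step * float(np.clip(gap / target_gap, 0.6, 1.3))
        heading = new_heading
        pos = pos + speeds[:, None] * np.column_stack([np.cos(heading), np.sin(heading)])
        pos = np.clip(pos, 1.0, ARENA_MM - 1.0)
    return _finalize(hist, config)


def independent_walkers(config: GeneratorConfig) -> Trajectory:
    """Independent correlated random walks: no interaction at all."""
    rng = np.random.default_rng(config.seed)
    n = config.n_fish
    step = config.speed_mm_s / config.fps
    pos = rng.uniform(WALL_MARGIN_MM, ARENA_MM - WALL_MARGIN_MM, size=(n, 2))
    heading = rng.uniform(-np.pi, np.pi, size=n)
    hist = np.empty((config.n_steps, n, 2))
    for t in range(config.n_steps):
        hist[t] = pos
        heading = _wrap(
            heading + _wall_steer(pos, heading) + rng.normal(0.0, config.noise_sd, size=n)
        )
        pos = pos + step * np.column_stack([np.cos(heading), np.sin(heading)])
        pos = np.clip(pos, 1.0, ARENA_MM - 1.0)
    return _finalize(hist, config)


def random_markov_tpm(n_nodes: int, seed: int) -> StateByNodeTPM:
    """Homogeneous random Markov model: every conditional ON-probability
    i.i.d. uniform on [0, 1]."""
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    rng = np.random.default_rng(seed)
    return StateByNodeTPM(rng.uniform(0.0, 1.0, size=(2**n_nodes, n_nodes)))
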