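"""Trajectory binarization: state functions, conventions, invariances."""

import numpy as np
import pytest

from swarmphi.state_encoding import (
    CollectiveStateSequence,
    GlobalThresholds,
    LocalThresholds,
    Trajectory,
    distance_state,
    global_collective_state,
    local_collective_state,
    resample,
    turning_state,
    velocities,
    visual_field_state,
)


def _traj(pos, fps=120.0):
    return Trajectory(positions=np.asarray(pos, float), fps=fps)


def straight_pair(n=200, gap=50.0, step=2.0):
    """Two fish moving in +x, fish 1 ahead of fish 0 by ``gap`` mm."""
    t = np.arange(n)[:, None] * step
    a = np.concatenate([t, np.zeros((n, 1))], axis=1)
    b = a + [gap, 0.0]
    return _traj(np.stack([a, b], axis=1) + 1000.0)


# ----------------------------------------------------------------------
# resample / velocities
# ----------------------------------------------------------------------
def test_resample_timescale():
    traj = straight_pair(n=480)
    r = resample(traj, 20)
    assert r.fps == pytest.approx(120.0 / 20)
    assert r.positions.shape[0] == len(range(0, 480, 20)) - 2


def test_resample_constant_unchanged():
    pos = np.tile(np.array([[[5.0, 5.0], [9.0, 9.0]]]), (30, 1, 1))
    r = resample(_traj(pos), 3)
    np.testing.assert_allclose(r.positions, pos[: r.positions.shape[0]])


def test_resample_linear_motion_affine_invariant():
    traj = straight_pair(n=60)
    r = resample(traj, 5)
    steps = np.diff(r.positions, axis=0)
    np.testing.assert_allclose(steps, np.broadcast_to(steps[0], steps.shape), atol=1e-9)


def test_resample_too_short():
    with pytest.raises(ValueError):
        resample(straight_pair(n=40), 20)


def test_velocities_stationary_and_linear():
    pos = np.tile(np.array([[[5.0, 5.0], [9.0, 9.0]]]), (10, 1, 1))
    np.testing.assert_allclose(velocities(_traj(pos)), 0.0)
    traj = straight_pair(n=10, step=1.0)
    v = velocities(traj)
    np.testing.assert_allclose(v[:, 0], [[1.0, 0.0]] * 9)


def test_velocities_circular_motion_chord_length():
    r, theta = 100.0, 0.2
    t = np.arange(50) * theta
    one = r * np.column_stack([np.cos(t), np.sin(t)])
    two = one + [500.0, 0.0]
    v = velocities(_traj(np.stack([one, two], axis=1)))
    speed = np.linalg.norm(v[:, 0], axis=-1)
    np.testing.assert_allclose(speed, 2 * r * np.sin(theta / 2), rtol=1e-12)


# ----------------------------------------------------------------------
# single-frame bits
# ----------------------------------------------------------------------
def test_distance_state_examples():
    pos = np.array([[0.0, 0.0], [50.0, 0.0]])
    assert distance_state(pos, 0, 100.0) == 1
    assert distance_state(pos, 1, 100.0) == 1
    assert distance_state(pos, 0, 50.0) == 0  # strict inequality
    pos3 = np.array([[0.0, 0.0], [500.0, 0.0], [1000.0, 0.0]])
    assert all(distance_state(pos3, i, 450.0) == 0 for i in range(3))


def test_visual_field_examples():
    pos = np.array([[0.0, 0.0], [10.0, 0.0]])
    ahead = np.array([1.0, 0.0])
    assert visual_field_state(pos, ahead, 0, 0.1) == 1  # dead ahead
    # complete field: any neighbour is seen, even dead astern
    behind = np.array([-1.0, 0.0])
    assert visual_field_state(pos, behind, 0, 2 * np.pi) == 1
    # neighbour at bearing pi/2, field width pi/2 -> half-angle pi/4 -> OFF
    side = np.array([0.0, 1.0])
    pos_side = np.array([[0.0, 0.0], [10.0, 0.0]])
    assert visual_field_state(pos_side, side, 0, np.pi / 2) == 0
    # literal convention: bearing pi/2 < xi_VF=2 -> ON
    assert visual_field_state(pos_side, side, 0, 2.0, vf_half_angle=False) == 1
    # zero velocity -> heading undefined -> OFF
    assert visual_field_state(pos, np.zeros(2), 0, 2 * np.pi) == 0


def test_turning_state_examples():
    v = np.array([1.0, 0.0])
    assert turning_state(v, v, 0.0) == 1  # angle >= 0 always
    rot = np.array([np.cos(0.1), np.sin(0.1)])
    assert turning_state(rot, v, 0.05) == 1
    assert turning_state(v, v, 0.001) == 0  # straight line
    assert turning_state(np.zeros(2), v, 0.0) == 0  # undefined heading


# ----------------------------------------------------------------------
# sequence encoders
# ----------------------------------------------------------------------
def test_local_conjunction_requires_all_three():
    traj = straight_pair(gap=50.0)
    # distance ON, but visual field narrow and sideways neighbour -> OFF
    thr = LocalThresholds(xi_D=100.0, xi_VF=0.1, xi_TR=1.0)
    seq = local_collective_state(traj, thr, 1)
    assert (seq.states[:, 0] == 0).all()  # turning never exceeds 1 rad


def test_local_zero_turning_threshold_reduces_to_distance_and_vision():
    traj = straight_pair(gap=50.0)
    thr_t0 = LocalThresholds(xi_D=100.0, xi_VF=2 * np.pi, xi_TR=0.0)
    seq = local_collective_state(traj, thr_t0, 1)
    # straight-line pair within range and full field: everything ON
    assert (seq.states == 1).all()
    # with complete field and zero turning, the state equals the pure
    # distance state
    thr_far = LocalThresholds(xi_D=10.0, xi_VF=2 * np.pi, xi_TR=0.0)
    seq_far = local_collective_state(traj, thr_far, 1)
    assert (seq_far.states == 0).all()


def test_local_sequence_length_contract():
    traj = straight_pair(n=487)
    seq = local_collective_state(traj, LocalThresholds(100.0, np.pi, 0.0), 20)
    n_strided = len(range(0, 487, 20))
    assert len(seq.states) == n_strided - 3  # smoothing (2) + velocity (1)


def test_global_examples():
    n = 50
    t = np.arange(n)[:, None] * 2.0
    a = np.concatenate([t, np.zeros((n, 1))], axis=1) + 1000.0
    b = a + [0.0, 40.0]
    traj = _traj(np.stack([a, b], axis=1))
    seq = global_collective_state(traj, GlobalThresholds(Xi_AD=np.pi / 4, Xi_CM=100.0), 1)
    assert (seq.states == 1).all()  # aligned and near the centroid
    seq2 = global_collective_state(traj, GlobalThresholds(Xi_AD=np.pi / 4, Xi_CM=10.0), 1)
    assert (seq2.states == 0).all()  # both 20 mm from the centroid


def test_global_anti_aligned_fish_off():
    n = 50
    t = np.arange(n)[:, None] * 2.0
    a = np.concatenate([t, np.zeros((n, 1))], axis=1) + 1000.0
    b0 = np.concatenate([-t, np.zeros((n, 1))], axis=1) + 1060.0
    c = a + [0.0, 30.0]
    traj = _traj(np.stack([a, b0, c], axis=1))
    seq = global_collective_state(traj, GlobalThresholds(Xi_AD=np.pi / 4, Xi_CM=500.0), 1)
    assert (seq.states[:, 1] == 0).all()  # anti-aligned fish
    assert (seq.states[:, 0] == 1).all()


# ----------------------------------------------------------------------
# invariances
# ----------------------------------------------------------------------
def _random_walk_traj(seed, n_fish=3, n=300):
    rng = np.random.default_rng(seed)
    steps = rng.normal(0, 2.0, size=(n, n_fish, 2))
    pos = 2000.0 + np.cumsum(steps, axis=0)
    return _traj(pos)


@pytest.mark.parametrize("setting", ["local", "global"])
def test_rigid_motion_invariance(setting):
    traj = _random_walk_traj(3)
    theta = 0.7
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    moved = _traj(traj.positions @ rot.T + np.array([123.0, -456.0]))
    if setting == "local":
        thr = LocalThresholds(5.0, np.pi, 0.01)
        a = local_collective_state(traj, thr, 2)
        b = local_collective_state(moved, thr, 2)
    else:
        thr = GlobalThresholds(Xi_AD=np.pi / 3, Xi_CM=5.0)
        a = global_collective_state(traj, thr, 2)
        b = global_collective_state(moved, thr, 2)
    np.testing.assert_array_equal(a.states, b.states)


def test_permutation_equivariance():
    traj = _random_walk_traj(4)
    perm = [2, 0, 1]
    permuted = _traj(traj.positions[:, perm, :])
    thr = LocalThresholds(8.0, 1.5 * np.pi, 0.02)
    a = local_collective_state(traj, thr, 2)
    b = local_collective_state(permuted, thr, 2)
    np.testing.assert_array_equal(a.states[:, perm], b.states)


def test_monotonicity_in_distance_and_field():
    traj = _random_walk_traj(5)
    base = local_collective_state(traj, LocalThresholds(4.0, 0.5 * np.pi, 0.0), 2)
    wider = local_collective_state(traj, LocalThresholds(8.0, 1.5 * np.pi, 0.0), 2)
    assert (wider.states >= base.states).all()
    # raising xi_TR can only turn individuals OFF
    stricter = local_collective_state(traj, LocalThresholds(4.0, 0.5 * np.pi, 0.05), 2)
    assert (stricter.states <= base.states).all()


# ----------------------------------------------------------------------
# containers / io
# ----------------------------------------------------------------------
def test_sequence_state_ints_little_endian():
    seq = CollectiveStateSequence(
        states=np.array([[1, 0, 1], [0, 1, 1]]), thresholds=None, dt_frames=1
    )
    np.testing.assert_array_equal(seq.state_ints(), [0b101, 0b110])


def test_trajectory_csv_roundtrip(tmp_path):
    traj = _random_walk_traj(6, n_fish=2, n=50)
    path = tmp_path / "traj.csv"
    traj.to_csv(path)
    back = Trajectory.from_csv(path)
    np.testing.assert_allclose(back.positions, traj.positions, atol=1e-9)


def test_trajectory_csv_missing_frames_rejected(tmp_path):
    traj = _random_walk_traj(7, n_fish=2, n=20)
    path = tmp_path / "traj.csv"
    traj.to_csv(path)
    import pandas as pd

    df = pd.read_csv(path)
    df = df[df["frame"] != 10]
    df.to_csv(path, index=False)
    with pytest.raises(ValueError):
        Trajectory.from_csv(path)


def test_sequence_csv_and_sidecar(tmp_path):
    traj = straight_pair()
    thr = LocalThresholds(100.0, np.pi, 0.0)
    seq = local_collective_state(traj, thr, 2)
    seq.to_csv(tmp_path / "states.csv")
    seq.write_sidecar(tmp_path / "states.json")
    import json

    meta = json.loads((tmp_path / "states.json").read_text())
    assert meta["thresholds"]["setting"] == "local"
    assert meta["dt_frames"] == 2
    assert meta["convention_flags"]["vf_half_angle"] is True
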