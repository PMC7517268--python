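"""Shared fixtures: small reference networks and synthetic trajectories."""

import numpy as np
import pytest

from swarmphi.synthetic_data import GeneratorConfig, boids_school, leader_follower_chain


@pytest.fixture(scope="session")
def copy_tpm() -> np.ndarray:
    """2-node copy network: each node is next-ON iff the other is ON now."""
    return np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)


@pytest.fixture(scope="session")
def noisy_tpm() -> np.ndarray:
    """Two causally independent, fully noisy nodes."""
    return np.full((4, 2), 0.5)


@pytest.fixture(scope="session")
def feedforward_tpm() -> np.ndarray:
    """Node 1 copies node 0; node 0 reads nothing (constant-0.5 column)."""
    return np.array([[0.5, 0], [0.5, 1], [0.5, 0], [0.5, 1]], dtype=float)


@pytest.fixture(scope="session")
def majority3_tpm() -> np.ndarray:
    """Fully coupled 3-node noisy-majority network (no self input)."""
    probs = np.empty((8, 3))
    for s in range(8):
        bits = [(s >> i) & 1 for i in range(3)]
        for v in range(3):
            others = [bits[u] for u in range(3) if u != v]
            probs[s, v] = 0.9 if sum(others) == 2 else (0.1 if sum(others) == 0 else 0.5)
    return probs


@pytest.fixture(scope="session")
def school2() -> "Trajectory":
    return boids_school(GeneratorConfig(n_fish=2, n_steps=4000, seed=11))


@pytest.fixture(scope="session")
def school3() -> "Trajectory":
    return boids_school(GeneratorConfig(n_fish=3, n_steps=4000, seed=12))


@pytest.fixture(scope="session")
def chain3() -> "Trajectory":
    return leader_follower_chain(GeneratorConfig(n_fish=3, n_steps=6000, seed=13))
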