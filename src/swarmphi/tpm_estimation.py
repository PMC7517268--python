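"""Estimate state-by-node TPMs from collective-state sequences, and
simulate sequences from a given TPM.

Estimation is plain maximum likelihood under the conditional-independence
assumption: entry (s, v) is the fraction of transitions out of previous
state ``s`` in which node ``v`` was ON next.  Previous states that never
occur are filled with the maximum-entropy value 0.5 per node by default
(consistent with the uniform unconstrained-input convention of the IIT
engine); Laplace smoothing is available behind a flag and applies to every
row.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .iit_core.types import StateByNodeTPM
from .state_encoding import CollectiveStateSequence

__all__ = [
    "TransitionCounts",
    "count_transitions",
    "estimate_tpm",
    "simulate_sequence",
    "state_occupancy",
]


@dataclass(frozen=True)
class TransitionCounts:
    """Raw transition tallies: per (previous state, node) the number of
    ON-outcomes and the total number of transitions out of that state."""

    on_counts: np.ndarray  # (2**n, n)
    totals: np.ndarray  # (2**n,)

    @property
    def n_nodes(self) -> int:
        return self.on_counts.shape[1]

    def to_csv(self, path) -> None:
        n = self.n_nodes
        df = pd.DataFrame(
            self.on_counts, columns=[f"on_count_node_{v}" for v in range(n)]
        )
        df.insert(0, "prev_state", np.arange(2**n))
        df["total"] = self.totals
        df.to_csv(path, index=False)


def _state_ints(seq) -> tuple[np.ndarray, int]:
    if isinstance(seq, CollectiveStateSequence):
        return seq.state_ints(), seq.n_individuals
    states = np.asarray(seq)
    if states.ndim != 2:
        raise ValueError("expected a CollectiveStateSequence or a (T, N) binary array")
    n = states.shape[1]
    weights = 1 << np.arange(n)
    return (states.astype(np.int64) * weights).sum(axis=1), n


def count_transitions(seq) -> TransitionCounts:
    ints, n = _state_ints(seq)
    if len(ints) < 2:
        raise ValueError("need at least 2 observations to count transitions")
    prev = ints[:-1]
    nxt = ints[1:]
    size = 2**n
    totals = np.bincount(prev, minlength=size).astype(np.int64)
    on_counts = np.empty((size, n), dtype=np.int64)
    for v in range(n):
        bit = (nxt >> v) & 1
        on_counts[:, v] = np.bincount(prev, weights=bit, minlength=size)
    return TransitionCounts(on_counts=on_counts, totals=totals)


def estimate_tpm(seq, smoothing: str = "maxent") -> StateByNodeTPM:
    """Maximum-likelihood state-by-node TPM from a state sequence.

    ``smoothing='maxent'`` fills rows for unseen previous states with 0.5;
    ``'laplace'`` adds one pseudo-ON and one pseudo-OFF transition to every
    (state, node) cell.
    """
    counts = count_transitions(seq)
    totals = counts.totals.astype(float)
    if smoothing == "maxent":
        probs = np.full(counts.on_counts.shape, 0.5)
        seen = totals > 0
        probs[seen] = counts.on_counts[seen] / totals[seen, None]
    elif smoothing == "laplace":
        probs = (counts.on_counts + 1.0) / (totals[:, None] + 2.0)
    else:
        raise ValueError(f"unknown smoothing {smoothing!r}")
    return StateByNodeTPM(probs)


def simulate_sequence(
    tpm: StateByNodeTPM,
    length: int,
    seed: int,
    initial_state: Optional[int] = None,
) -> CollectiveStateSequence:
    """Sample a Markov chain from the TPM, each node drawn independently
    from its conditional ON-probability.  Reproducible per seed."""
    if length < 1:
        raise ValueError("length must be >= 1")
    probs = tpm.probabilities if isinstance(tpm, StateByNodeTPM) else StateByNodeTPM(tpm).probabilities
    n = probs.shape[1]
    rng = np.random.default_rng(seed)
    weights = 1 << np.arange(n)
    if initial_state is None:
        state = int(rng.integers(2**n))
    else:
        state = int(initial_state)
    states = np.empty((length, n), dtype=np.uint8)
    uniforms = rng.random((length, n))
    bits = np.array([(state >> v) & 1 for v in range(n)], dtype=np.uint8)
    for t in range(length):
        bits = (uniforms[t] < probs[state]).astype(np.uint8)
        state = int(bits @ weights)
        states[t] = bits
    return CollectiveStateSequence(states=states, thresholds=None, dt_frames=1)


def state_occupancy(seq) -> np.ndarray:
    """Relative frequency of each of the 2**N collective states."""
    ints, n = _state_ints(seq)
    if len(ints) == 0:
        raise ValueError("empty sequence")
    return np.bincount(ints, minlength=2**n) / len(ints)
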