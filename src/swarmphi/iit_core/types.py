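"""Domain types for the IIT 3.0 engine.

All node indices are little-endian bit positions: node 0 is the least
significant bit of a collective-state integer.  TPM rows are indexed by
the previous collective state in that order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np

Bits = Tuple[int, ...]
Nodes = Tuple[int, ...]

#: below this magnitude a small-phi / big-phi value is treated as zero
PHI_EPS = 1e-10


@dataclass(frozen=True)
class StateByNodeTPM:
    """State-by-node transition probability matrix.

    ``probabilities[s, v]`` is the probability that node ``v`` is ON at the
    next step given previous collective state ``s`` (little-endian row
    order).  The full-state transition probability factorizes over nodes
    (conditional independence).
    """

    probabilities: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probabilities, dtype=float)
        if probs.ndim != 2:
            raise ValueError("TPM must be a 2-D (state-by-node) matrix")
        n = probs.shape[1]
        if probs.shape[0] != 2**n:
            raise ValueError(
                f"TPM must have 2**n_nodes rows: got {probs.shape[0]} rows for {n} nodes"
            )
        if probs.min() < -1e-12 or probs.max() > 1 + 1e-12:
            raise ValueError("TPM entries must lie in [0, 1]")
        probs = np.clip(probs, 0.0, 1.0)
        probs.setflags(write=False)
        object.__setattr__(self, "probabilities", probs)

    @property
    def n_nodes(self) -> int:
        return self.probabilities.shape[1]

    def to_text(self, path) -> None:
        """Write the plain-text exchange format (header + matrix)."""
        header = (
            f"# state-by-node TPM  n_nodes={self.n_nodes}  "
            "row_order=little-endian  entries=P(node ON | previous state)"
        )
        np.savetxt(path, self.probabilities, header=header.lstrip("# "), fmt="%.12g")

    @classmethod
    def from_text(cls, path) -> "StateByNodeTPM":
        return cls(np.loadtxt(path, ndmin=2))


@dataclass(frozen=True)
class Repertoire:
    """Probability distribution over the states of an ordered purview."""

    purview: Nodes
    distribution: np.ndarray

    def __post_init__(self) -> None:
        dist = np.asarray(self.distribution, dtype=float)
        if dist.shape != (2 ** len(self.purview),):
            raise ValueError("repertoire length must be 2**len(purview)")
        if dist.min() < -1e-12 or abs(dist.sum() - 1.0) > 1e-9:
            raise ValueError("repertoire must be a normalized distribution")
        dist.setflags(write=False)
        object.__setattr__(self, "distribution", dist)
        object.__setattr__(self, "purview", tuple(self.purview))


@dataclass(frozen=True)
class MechanismPartition:
    """Bipartition of a (mechanism, purview) pair into two constraining parts."""

    mechanism1: Nodes
    purview1: Nodes
    mechanism2: Nodes
    purview2: Nodes

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        def fmt(nodes):
            return "{" + ",".join(map(str, nodes)) + "}" if nodes else "{}"

        return (
            f"{fmt(self.mechanism1)}/{fmt(self.purview1)} x "
            f"{fmt(self.mechanism2)}/{fmt(self.purview2)}"
        )


@dataclass(frozen=True, eq=False)
class Concept:
    """A mechanism with maximally irreducible cause and effect repertoires."""

    mechanism: Nodes
    state: Bits  # state of the mechanism nodes
    phi: float
    phi_cause: float
    phi_effect: float
    cause_purview: Nodes
    effect_purview: Nodes
    cause_rep: np.ndarray  # over cause_purview states
    effect_rep: np.ndarray  # over effect_purview states
    cause_mip: Optional[MechanismPartition]
    effect_mip: Optional[MechanismPartition]
    # repertoires expanded over the full subsystem state space (used for
    # concept-space distances); filled by the engine that created the concept
    expanded_cause: np.ndarray = field(repr=False, default=None)
    expanded_effect: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True, eq=False)
class ConceptualStructure:
    """All concepts specified by a subsystem in a given state."""

    concepts: Tuple[Concept, ...]
    subsystem: Nodes
    state: Bits

    @property
    def sum_phi(self) -> float:
        return float(sum(c.phi for c in self.concepts))

    def __len__(self) -> int:
        return len(self.concepts)


@dataclass(frozen=True)
class SystemCut:
    """Unidirectional system cut: edges from ``from_part`` into ``to_part``
    are replaced with noise."""

    from_part: Nodes
    to_part: Nodes

    def __post_init__(self) -> None:
        f, t = tuple(self.from_part), tuple(self.to_part)
        if not f or not t or set(f) & set(t):
            raise ValueError("cut parts must be non-empty and disjoint")
        object.__setattr__(self, "from_part", f)
        object.__setattr__(self, "to_part", t)

    def severs_exactly(self, node: int) -> bool:
        """True if this cut isolates ``node`` from the rest (either direction)."""
        return self.from_part == (node,) or self.to_part == (node,)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{set(self.from_part)} -/-> {set(self.to_part)}"


@dataclass(frozen=True, eq=False)
class PhiResult:
    """Integrated (conceptual) information of a subsystem in a state."""

    state: Bits
    big_phi: float
    mip_cut: Optional[SystemCut]
    structure: ConceptualStructure
    subsystem: Nodes

    def to_dict(self) -> dict:
        return {
            "state": list(self.state),
            "subsystem": list(self.subsystem),
            "big_phi": self.big_phi,
            "mip_cut": None
            if self.mip_cut is None
            else {
                "from_part": list(self.mip_cut.from_part),
                "to_part": list(self.mip_cut.to_part),
                "direction": "from->to noised",
            },
            "concepts": [
                {
                    "mechanism": list(c.mechanism),
                    "state": list(c.state),
                    "phi": c.phi,
                    "phi_cause": c.phi_cause,
                    "phi_effect": c.phi_effect,
                    "cause_purview": list(c.cause_purview),
                    "effect_purview": list(c.effect_purview),
                }
                for c in self.structure.concepts
            ],
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))
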