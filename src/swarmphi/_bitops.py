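"""Little-endian bit/state helpers shared across modules.

Convention used throughout the package: node 0 is the least significant
bit of a collective-state integer, so state ``s`` assigns node ``i`` the
bit ``(s >> i) & 1``.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Iterator, Sequence, Tuple

Bits = Tuple[int, ...]


def state_to_bits(state: int, n_nodes: int) -> Bits:
    """Expand a state integer into an n-tuple of bits (node 0 first)."""
    if not 0 <= state < 2**n_nodes:
        raise ValueError(f"state {state} out of range for {n_nodes} nodes")
    return tuple((state >> i) & 1 for i in range(n_nodes))


def bits_to_state(bits: Sequence[int]) -> int:
    s = 0
    for i, b in enumerate(bits):
        s |= (int(b) & 1) << i
    return s


def substate(bits: Sequence[int], nodes: Sequence[int]) -> Bits:
    """Restrict a full bit-vector to the given (ordered) node subset."""
    return tuple(int(bits[v]) for v in nodes)


def powerset(nodes: Iterable[int], min_size: int = 1) -> Iterator[Bits]:
    """Subsets of ``nodes`` ordered by (size, lexicographic)."""
    nodes = tuple(nodes)
    for r in range(min_size, len(nodes) + 1):
        yield from itertools.combinations(nodes, r)


def subsets_preference_order(nodes: Iterable[int], min_size: int = 1) -> list[Bits]:
    """Subsets ordered largest-first, then lexicographically smallest.

    This is the tie-breaking order used for purview maximisation and the
    main-complex search.
    """
    return sorted(powerset(nodes, min_size), key=lambda s: (-len(s), s))
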