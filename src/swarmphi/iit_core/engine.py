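"""IIT 3.0 calculator for binary networks of up to ~6 nodes.

Implements cause/effect repertoires, mechanism-level integrated
information (small phi) with minimum-information partitions, concepts,
conceptual structures, and system-level integrated information (big Phi)
under unidirectional cuts, with either the cut-one approximation (2N
cuts) or exhaustive bipartition search.

Conventions (documented once, used everywhere):

* little-endian state indexing: node 0 is the least significant bit;
* effect repertoires factorize over purview nodes, with non-mechanism
  inputs replaced by independent maximum-entropy noise;
* cause repertoires are per-mechanism-node Bayesian inversions under a
  uniform prior, combined multiplicatively and renormalized;
* mechanism-level partitions pair an unordered mechanism bipartition
  (first part may be empty) with a directed purview bipartition, each
  part non-trivial;
* the distance between conceptual structures is a transport problem in
  concept space (phi is mass, ground distance is the sum of cause- and
  effect-repertoire EMDs over the full subsystem state space, surplus
  mass moves to the null concept);
* ties: among equal-phi purviews the largest then lexicographically
  smallest wins; among equal-Phi cuts the first in enumeration order
  (per node: incoming cut before outgoing cut) wins.
"""

from __future__ import annotations

import itertools
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .._bitops import powerset, subsets_preference_order, substate
from .transport import _emd_reduced, _solve_transport, hamming_ground
from .types import (
    PHI_EPS,
    Concept,
    ConceptualStructure,
    MechanismPartition,
    PhiResult,
    Repertoire,
    StateByNodeTPM,
    SystemCut,
)

Bits = Tuple[int, ...]
Nodes = Tuple[int, ...]

__all__ = [
    "SubsystemEngine",
    "PhiCalculator",
    "effect_repertoire",
    "cause_repertoire",
    "small_phi",
    "compute_concept",
    "conceptual_structure",
    "big_phi",
    "main_complex",
    "condition_on_background",
    "cut_one_cuts",
    "exhaustive_cuts",
    "structure_distance",
]


def _as_probs(tpm) -> np.ndarray:
    if isinstance(tpm, StateByNodeTPM):
        return tpm.probabilities
    return StateByNodeTPM(np.asarray(tpm, dtype=float)).probabilities


def _check_nodes(nodes: Sequence[int], n: int, name: str, allow_empty: bool = False) -> Nodes:
    nodes = tuple(int(v) for v in nodes)
    if not allow_empty and not nodes:
        raise ValueError(f"{name} must be non-empty")
    if len(set(nodes)) != len(nodes) or any(v < 0 or v >= n for v in nodes):
        raise ValueError(f"{name} must be distinct node indices in [0, {n})")
    if tuple(sorted(nodes)) != nodes:
        raise ValueError(f"{name} must be sorted in ascending node order")
    return nodes


def condition_on_background(tpm, subsystem: Sequence[int], state: Sequence[int]) -> np.ndarray:
    """Restrict a TPM to ``subsystem``, clamping external nodes to ``state``.

    External elements act as fixed background conditions: their current
    state is substituted into the inputs of every subsystem node, and only
    subsystem columns are kept.  Returns a (2**k, k) array indexed by the
    subsystem's local little-endian state.
    """
    probs = _as_probs(tpm)
    n = probs.shape[1]
    sub = _check_nodes(subsystem, n, "subsystem")
    bits = tuple(int(b) for b in state)
    external = [v for v in range(n) if v not in sub]
    out = np.empty((2 ** len(sub), len(sub)))
    for k, v in enumerate(sub):
        arr = probs[:, v].reshape((2,) * n, order="F")
        idx = [slice(None)] * n
        for e in external:
            idx[e] = bits[e]
        out[:, k] = np.ravel(arr[tuple(idx)], order="F")
    return out


def cut_one_cuts(nodes: Nodes) -> List[SystemCut]:
    """The 2N unidirectional cuts isolating one node (in from out)."""
    cuts = []
    for v in nodes:
        rest = tuple(u for u in nodes if u != v)
        cuts.append(SystemCut(from_part=rest, to_part=(v,)))
        cuts.append(SystemCut(from_part=(v,), to_part=rest))
    return cuts


def exhaustive_cuts(nodes: Nodes) -> List[SystemCut]:
    """All unidirectional bipartitions of ``nodes``."""
    cuts = []
    for r in range(1, len(nodes)):
        for part in itertools.combinations(nodes, r):
            rest = tuple(u for u in nodes if u not in part)
            cuts.append(SystemCut(from_part=part, to_part=rest))
    return cuts


def _mip_partitions(mech: Nodes, purview: Nodes) -> List[Tuple[Nodes, Nodes, Nodes, Nodes]]:
    """Admissible (M1, P1, M2, P2) bipartitions of a mechanism/purview pair.

    Mechanism bipartitions are unordered (the first part may be empty, the
    anchor element always sits in part 2); purview bipartitions are
    directed.  A part must constrain or be constrained by something, so
    (M1, P1) = (empty, empty) is excluded; (M2, P2) is never trivial since
    M2 contains the anchor.
    """
    out = []
    rest = mech[1:]
    for r1 in range(len(rest) + 1):
        for m1 in itertools.combinations(rest, r1):
            m2 = tuple(v for v in mech if v not in m1)
            for rp in range(len(purview) + 1):
                for p1 in itertools.combinations(purview, rp):
                    if not m1 and not p1:
                        continue
                    p2 = tuple(v for v in purview if v not in p1)
                    out.append((m1, p1, m2, p2))
    return out


class SubsystemEngine:
    """Caching IIT 3.0 evaluator over one (already conditioned) TPM.

    Node indices are local to the engine's state space.  Repertoires and
    concepts depend on the mechanism state only, so they are cached across
    collective states.
    """

    def __init__(self, probs: np.ndarray):
        probs = np.asarray(probs, dtype=float)
        self.n = probs.shape[1]
        if probs.shape[0] != 2**self.n:
            raise ValueError("engine TPM must be 2**n x n")
        self.probs = probs
        self.nodes: Nodes = tuple(range(self.n))
        self._ax = [probs[:, v].reshape((2,) * self.n, order="F") for v in range(self.n)]
        self._esn_cache: Dict[tuple, float] = {}
        self._csn_cache: Dict[tuple, np.ndarray] = {}
        self._erep_cache: Dict[tuple, np.ndarray] = {}
        self._crep_cache: Dict[tuple, Optional[np.ndarray]] = {}
        self._phimax_cache: Dict[tuple, tuple] = {}
        self._concept_cache: Dict[tuple, Optional[Concept]] = {}
        self._split_cache: Dict[tuple, np.ndarray] = {}
        self._purviews = subsets_preference_order(self.nodes)
        self._null_concept: Optional[Tuple[np.ndarray, np.ndarray]] = None
        # bit table per purview size, for vectorized Bernoulli products
        self._bits = {
            k: np.array(
                [[(z >> b) & 1 for z in range(2**k)] for b in range(k)], dtype=bool
            )
            for k in range(self.n + 1)
        }

    # ------------------------------------------------------------------
    # repertoires
    # ------------------------------------------------------------------
    def _node_on_prob(self, v: int, mech: Nodes, mstate: Bits) -> float:
        """P(v ON next) with ``mech`` clamped and other inputs max-entropy."""
        key = (v, mech, mstate)
        val = self._esn_cache.get(key)
        if val is None:
            idx = [slice(None)] * self.n
            for node, b in zip(mech, mstate):
                idx[node] = b
            val = float(np.mean(self._ax[v][tuple(idx)]))
            self._esn_cache[key] = val
        return val

    def _cause_factor(self, v: int, bit: int, purview: Nodes) -> np.ndarray:
        """Unnormalized single-node cause repertoire of node ``v``=``bit``
        marginalized onto ``purview`` (uniform prior over past states)."""
        key = (v, bit, purview)
        vec = self._csn_cache.get(key)
        if vec is None:
            arr = self._ax[v] if bit else 1.0 - self._ax[v]
            axes = tuple(a for a in range(self.n) if a not in purview)
            out = arr.sum(axis=axes) if axes else arr
            vec = np.ravel(out, order="F").copy()
            vec.setflags(write=False)
            self._csn_cache[key] = vec
        return vec

    def effect_rep(self, mech: Nodes, mstate: Bits, purview: Nodes) -> np.ndarray:
        key = (mech, mstate, purview)
        r = self._erep_cache.get(key)
        if r is None:
            k = len(purview)
            pons = np.array([self._node_on_prob(p, mech, mstate) for p in purview])
            if k == 0:
                r = np.ones(1)
            else:
                bits = self._bits[k]
                r = np.prod(np.where(bits, pons[:, None], 1.0 - pons[:, None]), axis=0)
            r.setflags(write=False)
            self._erep_cache[key] = r
        return r

    def cause_rep(self, mech: Nodes, mstate: Bits, purview: Nodes) -> Optional[np.ndarray]:
        key = (mech, mstate, purview)
        if key in self._crep_cache:
            return self._crep_cache[key]
        if not mech:
            size = 2 ** len(purview)
            r = np.full(size, 1.0 / size)
        else:
            prod: Optional[np.ndarray] = None
            for v, b in zip(mech, mstate):
                c = self._cause_factor(v, b, purview)
                prod = c.copy() if prod is None else prod * c
            total = prod.sum()
            r = None if total <= 0.0 else prod / total
        if r is not None:
            r.setflags(write=False)
        self._crep_cache[key] = r
        return r

    def repertoire(self, direction: str, mech: Nodes, mstate: Bits, purview: Nodes):
        if direction == "effect":
            return self.effect_rep(mech, mstate, purview)
        if direction == "cause":
            return self.cause_rep(mech, mstate, purview)
        raise ValueError(f"direction must be 'cause' or 'effect', got {direction!r}")

    def unconstrained(self, direction: str, purview: Nodes) -> np.ndarray:
        return self.repertoire(direction, (), (), purview)

    # ------------------------------------------------------------------
    # partitioned repertoires
    # ------------------------------------------------------------------
    def _split_idx(self, purview: Nodes, sub: Nodes) -> np.ndarray:
        """Map purview-local state index -> local index of ``sub`` bits."""
        key = (purview, sub)
        idx = self._split_cache.get(key)
        if idx is None:
            z = np.arange(2 ** len(purview))
            idx = np.zeros_like(z)
            for k, node in enumerate(sub):
                pos = purview.index(node)
                idx |= ((z >> pos) & 1) << k
            idx.setflags(write=False)
            self._split_cache[key] = idx
        return idx

    def _partitioned_rep(
        self,
        direction: str,
        mstate_map: Dict[int, int],
        m1: Nodes,
        p1: Nodes,
        m2: Nodes,
        p2: Nodes,
        purview: Nodes,
    ) -> Optional[np.ndarray]:
        # both directions factorize into the two parts' repertoires
        out: Optional[np.ndarray] = None
        for mk, pk in ((m1, p1), (m2, p2)):
            if not pk:
                continue
            mst = tuple(mstate_map[v] for v in mk)
            rep = (
                self.effect_rep(mk, mst, pk)
                if direction == "effect"
                else self.cause_rep(mk, mst, pk)
            )
            if rep is None:
                return None
            expanded = rep[self._split_idx(purview, pk)]
            out = expanded if out is None else out * expanded
        return out

    # ------------------------------------------------------------------
    # small phi
    # ------------------------------------------------------------------
    def phi_mip(
        self, mech: Nodes, mstate: Bits, purview: Nodes, direction: str
    ) -> Tuple[float, Optional[MechanismPartition], Optional[np.ndarray]]:
        """Minimum-information-partition small phi for one purview.

        Returns (phi, minimizing partition, unpartitioned repertoire).
        """
        full = self.repertoire(direction, mech, mstate, purview)
        if full is None:
            return 0.0, None, None
        mstate_map = dict(zip(mech, mstate))
        ground = hamming_ground(len(purview))
        best = np.inf
        best_part: Optional[MechanismPartition] = None
        for m1, p1, m2, p2 in _mip_partitions(mech, purview):
            part = self._partitioned_rep(direction, mstate_map, m1, p1, m2, p2, purview)
            if part is None:
                continue
            diff = np.abs(full - part)
            if diff.max() < 1e-12:
                return 0.0, MechanismPartition(m1, p1, m2, p2), full
            # EMD >= total variation: skip partitions that cannot improve
            if 0.5 * diff.sum() >= best - 1e-15:
                continue
            val = _emd_reduced(full, part, ground)
            if val < best - 1e-12:
                best = val
                best_part = MechanismPartition(m1, p1, m2, p2)
        if not np.isfinite(best):
            return 0.0, None, full
        return best, best_part, full

    def phi_max(self, mech: Nodes, mstate: Bits, direction: str):
        """Maximally irreducible repertoire over all candidate purviews.

        Returns (phi, purview, repertoire, partition); phi == 0.0 with
        ``None`` fields when the mechanism specifies nothing in this
        direction.
        """
        key = (mech, mstate, direction)
        hit = self._phimax_cache.get(key)
        if hit is not None:
            return hit
        best = (0.0, None, None, None)
        for purview in self._purviews:
            full = self.repertoire(direction, mech, mstate, purview)
            if full is None:
                continue
            # upper bound: the total-sever partition is always admissible
            ub = _emd_reduced(full, self.unconstrained(direction, purview), hamming_ground(len(purview)))
            if ub <= best[0] + PHI_EPS:
                continue
            phi, part, _ = self.phi_mip(mech, mstate, purview, direction)
            if phi > best[0] + PHI_EPS:
                best = (phi, purview, full, part)
        self._phimax_cache[key] = best
        return best

    # ------------------------------------------------------------------
    # concepts and structures
    # ------------------------------------------------------------------
    def concept(self, mech: Nodes, mstate: Bits) -> Optional[Concept]:
        key = (mech, mstate)
        if key in self._concept_cache:
            return self._concept_cache[key]
        phi_c, pv_c, rep_c, mip_c = self.phi_max(mech, mstate, "cause")
        concept: Optional[Concept] = None
        if phi_c > PHI_EPS:
            phi_e, pv_e, rep_e, mip_e = self.phi_max(mech, mstate, "effect")
            if phi_e > PHI_EPS:
                concept = Concept(
                    mechanism=mech,
                    state=mstate,
                    phi=min(phi_c, phi_e),
                    phi_cause=phi_c,
                    phi_effect=phi_e,
                    cause_purview=pv_c,
                    effect_purview=pv_e,
                    cause_rep=rep_c,
                    effect_rep=rep_e,
                    cause_mip=mip_c,
                    effect_mip=mip_e,
                    expanded_cause=self._expand(rep_c, pv_c, "cause"),
                    expanded_effect=self._expand(rep_e, pv_e, "effect"),
                )
        self._concept_cache[key] = concept
        return concept

    def _expand(self, rep: np.ndarray, purview: Nodes, direction: str) -> np.ndarray:
        """Expand a purview repertoire over the full subsystem state space,
        filling the complement with its unconstrained repertoire."""
        comp = tuple(v for v in self.nodes if v not in purview)
        full_space = self.nodes
        out = rep[self._split_idx(full_space, purview)].astype(float)
        if comp:
            out = out * self.unconstrained(direction, comp)[self._split_idx(full_space, comp)]
        return out

    def null_concept(self) -> Tuple[np.ndarray, np.ndarray]:
        """(cause, effect) repertoires of the fully unconstrained concept."""
        if self._null_concept is None:
            size = 2**self.n
            self._null_concept = (
                np.full(size, 1.0 / size),
                self.unconstrained("effect", self.nodes),
            )
        return self._null_concept

    def structure(self, state_bits: Bits) -> ConceptualStructure:
        concepts = []
        for mech in powerset(self.nodes):
            c = self.concept(mech, substate(state_bits, mech))
            if c is not None:
                concepts.append(c)
        return ConceptualStructure(
            concepts=tuple(concepts), subsystem=self.nodes, state=tuple(state_bits)
        )


# ----------------------------------------------------------------------
# conceptual-structure distance (extended EMD)
# ----------------------------------------------------------------------
def _concepts_match(a: Concept, b: Concept) -> bool:
    return (
        a.mechanism == b.mechanism
        and a.state == b.state
        and abs(a.phi - b.phi) < 1e-9
        and a.cause_purview == b.cause_purview
        and a.effect_purview == b.effect_purview
        and np.allclose(a.expanded_cause, b.expanded_cause, atol=1e-9)
        and np.allclose(a.expanded_effect, b.expanded_effect, atol=1e-9)
    )


def structure_distance(
    intact: ConceptualStructure,
    cut: ConceptualStructure,
    null_cause: np.ndarray,
    null_effect: np.ndarray,
    ground: np.ndarray,
    memo: Optional[dict] = None,
) -> float:
    """Transport distance between two conceptual structures.

    Concept mass (phi) moves in concept space; the ground distance between
    two concepts is the sum of the EMDs between their cause and effect
    repertoires expanded over the full subsystem space.  Mass of concepts
    destroyed (or created) by the cut is transported to (from) the null
    concept; because the ground distance is a metric, concepts identical in
    both structures can be cancelled first.
    """
    used = [False] * len(cut.concepts)
    u1: List[Concept] = []
    for c in intact.concepts:
        matched = False
        for j, d in enumerate(cut.concepts):
            if not used[j] and _concepts_match(c, d):
                used[j] = True
                matched = True
                break
        if not matched:
            u1.append(c)
    u2 = [d for j, d in enumerate(cut.concepts) if not used[j]]
    sum1 = sum(c.phi for c in u1)
    sum2 = sum(c.phi for c in u2)
    if sum1 + sum2 < 1e-12:
        return 0.0

    causes = [c.expanded_cause for c in u1] + [c.expanded_cause for c in u2] + [null_cause]
    effects = [c.expanded_effect for c in u1] + [c.expanded_effect for c in u2] + [null_effect]
    k1, k2 = len(u1), len(u2)
    npts = k1 + k2 + 1
    dist = np.zeros((npts, npts))
    for i in range(npts):
        for j in range(i + 1, npts):
            if memo is not None:
                key = (id(causes[i]), id(causes[j]), id(effects[i]), id(effects[j]))
                d = memo.get(key)
                if d is None:
                    d = _emd_reduced(causes[i], causes[j], ground) + _emd_reduced(
                        effects[i], effects[j], ground
                    )
                    memo[key] = d
            else:
                d = _emd_reduced(causes[i], causes[j], ground) + _emd_reduced(
                    effects[i], effects[j], ground
                )
            dist[i, j] = dist[j, i] = d

    supply = np.array([c.phi for c in u1] + [0.0] * k2 + [sum2])
    demand = np.array([0.0] * k1 + [c.phi for c in u2] + [sum1])
    src = np.flatnonzero(supply > 1e-15)
    snk = np.flatnonzero(demand > 1e-15)
    cost = np.ascontiguousarray(dist[np.ix_(src, snk)])
    return float(
        _solve_transport(
            np.ascontiguousarray(supply[src]), np.ascontiguousarray(demand[snk]), cost
        )
    )


# ----------------------------------------------------------------------
# big phi
# ----------------------------------------------------------------------
class PhiCalculator:
    """Computes big Phi for every state of one TPM, reusing concept caches
    across states and cuts (cut sets are state-independent)."""

    def __init__(self, probs: np.ndarray, cut_scheme: str = "cut_one"):
        probs = np.asarray(probs, dtype=float)
        self.engine = SubsystemEngine(probs)
        self.n = self.engine.n
        if self.n < 2:
            raise ValueError("big Phi requires a subsystem of size >= 2")
        if cut_scheme == "cut_one":
            self.cuts = cut_one_cuts(self.engine.nodes)
        elif cut_scheme == "exhaustive":
            self.cuts = exhaustive_cuts(self.engine.nodes)
        else:
            raise ValueError(f"unknown cut scheme {cut_scheme!r}")
        self.cut_scheme = cut_scheme
        self._cut_engines: Dict[SystemCut, SubsystemEngine] = {}
        self._ground = hamming_ground(self.n)
        # memo of concept-pair distances; expanded repertoires are cached on
        # the engines for the calculator's lifetime, so ids are stable keys
        self._dist_memo: dict = {}

    def _cut_engine(self, cut: SystemCut) -> SubsystemEngine:
        eng = self._cut_engines.get(cut)
        if eng is None:
            probs = self.engine.probs.copy()
            sever_axes = tuple(cut.from_part)
            for v in cut.to_part:
                noised = self.engine._ax[v].mean(axis=sever_axes, keepdims=True)
                probs[:, v] = np.ravel(
                    np.broadcast_to(noised, (2,) * self.n), order="F"
                )
            eng = SubsystemEngine(probs)
            self._cut_engines[cut] = eng
        return eng

    def cut_distances(self, state_bits: Bits) -> List[float]:
        """Distance from the intact structure to each evaluated cut's."""
        intact = self.engine.structure(state_bits)
        null_c, null_e = self.engine.null_concept()
        out = []
        for cut in self.cuts:
            cut_struct = self._cut_engine(cut).structure(state_bits)
            out.append(
                structure_distance(
                    intact, cut_struct, null_c, null_e, self._ground, memo=self._dist_memo
                )
            )
        return out

    def big_phi(self, state_bits: Bits) -> PhiResult:
        state_bits = tuple(int(b) for b in state_bits)
        intact = self.engine.structure(state_bits)
        if not intact.concepts:
            return PhiResult(
                state=state_bits,
                big_phi=0.0,
                mip_cut=self.cuts[0],
                structure=intact,
                subsystem=self.engine.nodes,
            )
        null_c, null_e = self.engine.null_concept()
        best = np.inf
        best_cut = None
        for cut in self.cuts:
            cut_struct = self._cut_engine(cut).structure(state_bits)
            d = structure_distance(
                intact, cut_struct, null_c, null_e, self._ground, memo=self._dist_memo
            )
            if d < best - 1e-12:
                best = d
                best_cut = cut
            if best <= PHI_EPS:
                break
        big = 0.0 if best <= PHI_EPS else float(best)
        return PhiResult(
            state=state_bits,
            big_phi=big,
            mip_cut=best_cut,
            structure=intact,
            subsystem=self.engine.nodes,
        )


# ----------------------------------------------------------------------
# relabelling helpers (subsystem-local indices -> network labels)
# ----------------------------------------------------------------------
def _relabel_nodes(nodes: Optional[Nodes], sub: Nodes) -> Optional[Nodes]:
    if nodes is None:
        return None
    return tuple(sub[v] for v in nodes)


def _relabel_partition(p: Optional[MechanismPartition], sub: Nodes):
    if p is None:
        return None
    return MechanismPartition(
        _relabel_nodes(p.mechanism1, sub),
        _relabel_nodes(p.purview1, sub),
        _relabel_nodes(p.mechanism2, sub),
        _relabel_nodes(p.purview2, sub),
    )


def _relabel_concept(c: Concept, sub: Nodes) -> Concept:
    return Concept(
        mechanism=_relabel_nodes(c.mechanism, sub),
        state=c.state,
        phi=c.phi,
        phi_cause=c.phi_cause,
        phi_effect=c.phi_effect,
        cause_purview=_relabel_nodes(c.cause_purview, sub),
        effect_purview=_relabel_nodes(c.effect_purview, sub),
        cause_rep=c.cause_rep,
        effect_rep=c.effect_rep,
        cause_mip=_relabel_partition(c.cause_mip, sub),
        effect_mip=_relabel_partition(c.effect_mip, sub),
        expanded_cause=c.expanded_cause,
        expanded_effect=c.expanded_effect,
    )


def _relabel_result(res: PhiResult, sub: Nodes, full_state: Bits) -> PhiResult:
    cut = res.mip_cut
    if cut is not None:
        cut = SystemCut(
            from_part=_relabel_nodes(cut.from_part, sub),
            to_part=_relabel_nodes(cut.to_part, sub),
        )
    structure = ConceptualStructure(
        concepts=tuple(_relabel_concept(c, sub) for c in res.structure.concepts),
        subsystem=sub,
        state=tuple(full_state),
    )
    return PhiResult(
        state=tuple(full_state),
        big_phi=res.big_phi,
        mip_cut=cut,
        structure=structure,
        subsystem=sub,
    )


# ----------------------------------------------------------------------
# functional API
# ----------------------------------------------------------------------
def effect_repertoire(tpm, mechanism, mech_state, purview) -> Repertoire:
    """Distribution over purview next-states with the mechanism clamped and
    all other inputs replaced by maximum-entropy noise."""
    probs = _as_probs(tpm)
    n = probs.shape[1]
    mech = _check_nodes(mechanism, n, "mechanism", allow_empty=True)
    pv = _check_nodes(purview, n, "purview")
    mstate = tuple(int(b) for b in mech_state)
    if len(mstate) != len(mech):
        raise ValueError("mech_state length must match mechanism length")
    eng = SubsystemEngine(probs)
    return Repertoire(pv, eng.effect_rep(mech, mstate, pv))


def cause_repertoire(tpm, mechanism, mech_state, purview) -> Optional[Repertoire]:
    """Bayesian inversion of the forward dynamics under a uniform prior,
    marginalized onto the purview; ``None`` when the mechanism state is
    unreachable (zero normalizer)."""
    probs = _as_probs(tpm)
    n = probs.shape[1]
    mech = _check_nodes(mechanism, n, "mechanism", allow_empty=True)
    pv = _check_nodes(purview, n, "purview")
    mstate = tuple(int(b) for b in mech_state)
    if len(mstate) != len(mech):
        raise ValueError("mech_state length must match mechanism length")
    eng = SubsystemEngine(probs)
    rep = eng.cause_rep(mech, mstate, pv)
    return None if rep is None else Repertoire(pv, rep)


def small_phi(tpm, mechanism, mech_state, purview, direction: str):
    """Mechanism-level integrated information over one purview.

    Returns (phi, minimum-information partition); (0.0, None) when the
    cause repertoire is undefined.
    """
    probs = _as_probs(tpm)
    n = probs.shape[1]
    mech = _check_nodes(mechanism, n, "mechanism")
    pv = _check_nodes(purview, n, "purview")
    mstate = tuple(int(b) for b in mech_state)
    eng = SubsystemEngine(probs)
    phi, part, _ = eng.phi_mip(mech, mstate, pv, direction)
    return phi, part


def compute_concept(tpm, state, mechanism) -> Optional[Concept]:
    """The concept specified by ``mechanism`` in the given full state, or
    ``None`` if it is reducible in either direction."""
    probs = _as_probs(tpm)
    n = probs.shape[1]
    mech = _check_nodes(mechanism, n, "mechanism")
    bits = tuple(int(b) for b in state)
    eng = SubsystemEngine(probs)
    return eng.concept(mech, substate(bits, mech))


def conceptual_structure(tpm, state, subsystem=None) -> ConceptualStructure:
    """All concepts of the subsystem (default: the full system) in ``state``;
    external elements are clamped to their current state."""
    probs = _as_probs(tpm)
    n = probs.shape[1]
    bits = tuple(int(b) for b in state)
    if subsystem is None:
        sub = tuple(range(n))
        eng = SubsystemEngine(probs)
        local_state = bits
    else:
        sub = _check_nodes(subsystem, n, "subsystem")
        eng = SubsystemEngine(condition_on_background(probs, sub, bits))
        local_state = substate(bits, sub)
    struct = eng.structure(local_state)
    return ConceptualStructure(
        concepts=tuple(_relabel_concept(c, sub) for c in struct.concepts),
        subsystem=sub,
        state=bits,
    )


def big_phi(tpm, state, subsystem=None, cut_scheme: str = "cut_one") -> PhiResult:
    """Integrated conceptual information of the subsystem in ``state``.

    ``cut_scheme='cut_one'`` evaluates the 2N single-node cuts;
    ``'exhaustive'`` evaluates every unidirectional bipartition.
    """
    probs = _as_probs(tpm)
    n = probs.shape[1]
    bits = tuple(int(b) for b in state)
    if subsystem is None:
        sub = tuple(range(n))
        local = probs
    else:
        sub = _check_nodes(subsystem, n, "subsystem")
        local = condition_on_background(probs, sub, bits)
    if len(sub) < 2:
        raise ValueError("big Phi requires a subsystem of size >= 2")
    calc = PhiCalculator(local, cut_scheme=cut_scheme)
    res = calc.big_phi(substate(bits, sub))
    return _relabel_result(res, sub, bits)


def main_complex(tpm, state, cut_scheme: str = "cut_one") -> Tuple[Nodes, PhiResult]:
    """The node subset (size >= 2) with maximal big Phi.

    Ties prefer the largest subset, then the lexicographically smallest.
    """
    probs = _as_probs(tpm)
    n = probs.shape[1]
    bits = tuple(int(b) for b in state)
    best: Optional[PhiResult] = None
    best_sub: Optional[Nodes] = None
    for sub in subsets_preference_order(tuple(range(n)), min_size=2):
        local = probs if len(sub) == n else condition_on_background(probs, sub, bits)
        calc = PhiCalculator(local, cut_scheme=cut_scheme)
        res = _relabel_result(calc.big_phi(substate(bits, sub)), sub, bits)
        if best is None or res.big_phi > best.big_phi + PHI_EPS:
            best = res
            best_sub = sub
    return best_sub, best
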