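"""Independent brute-force IIT 3.0 evaluator used as a test oracle.

Deliberately naive: works from the explicit enumeration of previous
states, enumerates every partition/purview/cut without caching tricks,
and uses its own earth mover's distance solver (Dijkstra-with-potentials
successive shortest paths; `emd_lp` is a scipy.linprog reference used to
spot-check both EMD implementations on random instances).

Conventions mirror the package's documented ones (little-endian states,
factorized effect repertoires, multiplied-and-renormalized per-node cause
inversions, unordered-mechanism x directed-purview partitions, transport
distance between conceptual structures with a null concept).
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linprog


# ----------------------------------------------------------------------
# EMD
# ----------------------------------------------------------------------
def hamming_matrix(n_bits: int) -> np.ndarray:
    size = 2**n_bits
    return np.array(
        [[bin(a ^ b).count("1") for b in range(size)] for a in range(size)], dtype=float
    )


def emd_lp(p, q, D) -> float:
    """Reference transport LP via scipy.linprog (slow, exact)."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    k = len(p)
    c = np.asarray(D, float).reshape(-1)
    A = np.zeros((2 * k, k * k))
    for i in range(k):
        A[i, i * k : (i + 1) * k] = 1.0
        A[k + i, i::k] = 1.0
    b = np.concatenate([p, q])
    res = linprog(c, A_eq=A, b_eq=b, bounds=(0, None), method="highs")
    assert res.status == 0
    return float(res.fun)


def emd_ssp(p, q, D) -> float:
    """Exact EMD via successive shortest paths (Dijkstra with potentials)."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    diff = p - q
    sources = [i for i in range(len(p)) if diff[i] > 1e-14]
    sinks = [j for j in range(len(p)) if diff[j] < -1e-14]
    if not sources or not sinks:
        return 0.0
    sup = [diff[i] for i in sources]
    dem = [-diff[j] for j in sinks]
    C = [[float(D[i][j]) for j in sinks] for i in sources]
    k, m = len(sources), len(sinks)
    nv = k + m
    pot = [0.0] * nv
    flow = [[0.0] * m for _ in range(k)]
    remaining = min(sum(sup), sum(dem))
    cost = 0.0
    while remaining > 1e-12:
        dist = [float("inf")] * nv
        parent = [-1] * nv
        done = [False] * nv
        for i in range(k):
            if sup[i] > 1e-15:
                dist[i] = 0.0
        while True:
            u = -1
            best = float("inf")
            for v in range(nv):
                if not done[v] and dist[v] < best:
                    best = dist[v]
                    u = v
            if u < 0:
                break
            done[u] = True
            if u < k:  # source -> every sink
                for j in range(m):
                    w = C[u][j] + pot[u] - pot[k + j]
                    if dist[u] + w < dist[k + j] - 1e-15:
                        dist[k + j] = dist[u] + w
                        parent[k + j] = u
            else:  # sink -> sources with flow (backward arcs)
                j = u - k
                for i in range(k):
                    if flow[i][j] > 1e-15:
                        w = -C[i][j] + pot[u] - pot[i]
                        if dist[u] + w < dist[i] - 1e-15:
                            dist[i] = dist[u] + w
                            parent[i] = u
        target = -1
        best = float("inf")
        for j in range(m):
            if dem[j] > 1e-15 and dist[k + j] < best:
                best = dist[k + j]
                target = j
        assert target >= 0, "transport problem disconnected"
        for v in range(nv):
            if dist[v] < float("inf"):
                pot[v] += min(dist[v], dist[k + target])
        # bottleneck
        amt = dem[target]
        v = k + target
        while True:
            u = parent[v]
            if v >= k:  # arrived via forward arc u -> v
                pass
            else:  # arrived via backward arc (sink u) -> source v
                amt = min(amt, flow[v][u - k])
            if u < k and parent[u] == -1:
                amt = min(amt, sup[u])
                break
            v = u
        # apply
        v = k + target
        while True:
            u = parent[v]
            if v >= k:
                flow[u][v - k] += amt
                cost_delta = C[u][v - k]
                cost += amt * cost_delta
            else:
                flow[v][u - k] -= amt
                cost -= amt * C[v][u - k]
            if u < k and parent[u] == -1:
                sup[u] -= amt
                break
            v = u
        dem[target] -= amt
        remaining -= amt
    return cost


# ----------------------------------------------------------------------
# brute-force IIT
# ----------------------------------------------------------------------
PHI_EPS = 1e-10


def bits_of(state: int, n: int):
    return tuple((state >> i) & 1 for i in range(n))


def sub_bits(bits, nodes):
    return tuple(bits[v] for v in nodes)


def all_subsets(nodes, min_size=1):
    nodes = tuple(nodes)
    out = []
    for r in range(min_size, len(nodes) + 1):
        out.extend(itertools.combinations(nodes, r))
    return out


def purview_preference(nodes):
    return sorted(all_subsets(nodes), key=lambda s: (-len(s), s))


def mechanism_purview_partitions(mech, purview):
    """Same partition set as the engine, enumerated differently: canonical
    unordered mechanism pairs x ordered purview pairs, deduplicated."""
    seen = set()
    out = []
    for r in range(len(mech) + 1):
        for m1 in itertools.combinations(mech, r):
            m2 = tuple(v for v in mech if v not in m1)
            for rp in range(len(purview) + 1):
                for p1 in itertools.combinations(purview, rp):
                    p2 = tuple(v for v in purview if v not in p1)
                    if (not m1 and not p1) or (not m2 and not p2):
                        continue
                    key = frozenset([(m1, p1), (m2, p2)])
                    if key in seen:
                        continue
                    seen.add(key)
                    out.append((m1, p1, m2, p2))
    return out


class BruteForceIIT:
    """Exhaustive IIT 3.0 evaluation of one state-by-node TPM."""

    def __init__(self, probs):
        probs = np.asarray(probs, float)
        self.n = probs.shape[1]
        self.size = 2**self.n
        assert probs.shape[0] == self.size
        self.probs = probs
        self.ground = hamming_matrix(self.n)

    # -- repertoires (explicit enumeration over previous states) --------
    def effect_rep(self, mech, mstate, purview):
        prev_states = [
            s
            for s in range(self.size)
            if all((s >> v) & 1 == b for v, b in zip(mech, mstate))
        ]
        pons = {}
        for v in purview:
            pons[v] = sum(self.probs[s, v] for s in prev_states) / len(prev_states)
        rep = np.empty(2 ** len(purview))
        for z in range(2 ** len(purview)):
            prob = 1.0
            for k, v in enumerate(purview):
                bit = (z >> k) & 1
                prob *= pons[v] if bit else 1.0 - pons[v]
            rep[z] = prob
        return rep

    def cause_rep(self, mech, mstate, purview):
        if not mech:
            return np.full(2 ** len(purview), 1.0 / 2 ** len(purview))
        rep = np.ones(2 ** len(purview))
        for v, b in zip(mech, mstate):
            factor = np.zeros(2 ** len(purview))
            for s in range(self.size):
                z = 0
                for k, u in enumerate(purview):
                    z |= ((s >> u) & 1) << k
                lik = self.probs[s, v] if b else 1.0 - self.probs[s, v]
                factor[z] += lik
            rep *= factor
        total = rep.sum()
        if total <= 0.0:
            return None
        return rep / total

    def repertoire(self, direction, mech, mstate, purview):
        if direction == "effect":
            return self.effect_rep(mech, mstate, purview)
        return self.cause_rep(mech, mstate, purview)

    # -- small phi -------------------------------------------------------
    def partitioned_rep(self, direction, mech, mstate, m1, p1, m2, p2, purview):
        rep = np.ones(2 ** len(purview))
        for mk, pk in ((m1, p1), (m2, p2)):
            if not pk:
                continue
            sk = tuple(mstate[mech.index(v)] for v in mk)
            part = self.repertoire(direction, mk, sk, pk)
            if part is None:
                return None
            for z in range(2 ** len(purview)):
                zk = 0
                for kk, u in enumerate(pk):
                    zk |= ((z >> purview.index(u)) & 1) << kk
                rep[z] *= part[zk]
        return rep

    def small_phi(self, mech, mstate, purview, direction):
        full = self.repertoire(direction, mech, mstate, purview)
        if full is None:
            return 0.0, None
        g = hamming_matrix(len(purview))
        best = float("inf")
        best_part = None
        for m1, p1, m2, p2 in mechanism_purview_partitions(mech, purview):
            part = self.partitioned_rep(direction, mech, mstate, m1, p1, m2, p2, purview)
            if part is None:
                continue
            d = emd_ssp(full, part, g)
            if d < best - 1e-12:
                best = d
                best_part = (m1, p1, m2, p2)
        return best, best_part

    def phi_max(self, mech, mstate, direction):
        best = (0.0, None, None)
        for purview in purview_preference(range(self.n)):
            full = self.repertoire(direction, mech, mstate, purview)
            if full is None:
                continue
            phi, _ = self.small_phi(mech, mstate, purview, direction)
            if phi > best[0] + PHI_EPS:
                best = (phi, purview, full)
        return best

    # -- concepts --------------------------------------------------------
    def expand(self, rep, purview, direction):
        comp = tuple(v for v in range(self.n) if v not in purview)
        out = np.empty(self.size)
        if comp:
            comp_rep = self.repertoire(direction, (), (), comp)
        for s in range(self.size):
            z = 0
            for k, u in enumerate(purview):
                z |= ((s >> u) & 1) << k
            val = rep[z]
            if comp:
                zc = 0
                for k, u in enumerate(comp):
                    zc |= ((s >> u) & 1) << k
                val *= comp_rep[zc]
            out[s] = val
        return out

    def concept(self, mech, mstate):
        phi_c, pv_c, rep_c = self.phi_max(mech, mstate, "cause")
        if phi_c <= PHI_EPS:
            return None
        phi_e, pv_e, rep_e = self.phi_max(mech, mstate, "effect")
        if phi_e <= PHI_EPS:
            return None
        return {
            "mechanism": mech,
            "phi": min(phi_c, phi_e),
            "phi_cause": phi_c,
            "phi_effect": phi_e,
            "cause_purview": pv_c,
            "effect_purview": pv_e,
            "exp_cause": self.expand(rep_c, pv_c, "cause"),
            "exp_effect": self.expand(rep_e, pv_e, "effect"),
        }

    def structure(self, state_bits):
        concepts = []
        for mech in all_subsets(range(self.n)):
            c = self.concept(mech, sub_bits(state_bits, mech))
            if c is not None:
                concepts.append(c)
        return concepts

    # -- big phi ---------------------------------------------------------
    def cut_tpm(self, from_part, to_part):
        new = self.probs.copy()
        for v in to_part:
            for s in range(self.size):
                agree = [
                    s2
                    for s2 in range(self.size)
                    if all(
                        ((s2 >> u) & 1) == ((s >> u) & 1)
                        for u in range(self.n)
                        if u not in from_part
                    )
                ]
                new[s, v] = float(np.mean([self.probs[s2, v] for s2 in agree]))
        return new

    def null_concept_reps(self):
        return (
            np.full(self.size, 1.0 / self.size),
            self.effect_rep((), (), tuple(range(self.n))),
        )

    def structure_distance(self, c1_list, c2_list):
        null_cause, null_effect = self.null_concept_reps()

        def same(a, b):
            return (
                a["mechanism"] == b["mechanism"]
                and abs(a["phi"] - b["phi"]) < 1e-9
                and a["cause_purview"] == b["cause_purview"]
                and a["effect_purview"] == b["effect_purview"]
                and np.allclose(a["exp_cause"], b["exp_cause"], atol=1e-9)
                and np.allclose(a["exp_effect"], b["exp_effect"], atol=1e-9)
            )

        c2_left = list(c2_list)
        u1 = []
        for a in c1_list:
            hit = next((b for b in c2_left if same(a, b)), None)
            if hit is not None:
                c2_left.remove(hit)
            else:
                u1.append(a)
        u2 = c2_left
        s1 = sum(c["phi"] for c in u1)
        s2 = sum(c["phi"] for c in u2)
        if s1 + s2 < 1e-12:
            return 0.0
        pts = (
            [(c["exp_cause"], c["exp_effect"]) for c in u1]
            + [(c["exp_cause"], c["exp_effect"]) for c in u2]
            + [(null_cause, null_effect)]
        )
        npts = len(pts)
        D = np.zeros((npts, npts))
        for i in range(npts):
            for j in range(npts):
                if i != j:
                    D[i, j] = emd_ssp(pts[i][0], pts[j][0], self.ground) + emd_ssp(
                        pts[i][1], pts[j][1], self.ground
                    )
        supply = np.array([c["phi"] for c in u1] + [0.0] * len(u2) + [s2])
        demand = np.array([0.0] * len(u1) + [c["phi"] for c in u2] + [s1])
        return emd_unbalanced(supply, demand, D)

    def system_cuts(self, scheme):
        nodes = tuple(range(self.n))
        cuts = []
        if scheme == "cut_one":
            for v in nodes:
                rest = tuple(u for u in nodes if u != v)
                cuts.append((rest, (v,)))
                cuts.append(((v,), rest))
        else:
            for r in range(1, self.n):
                for part in itertools.combinations(nodes, r):
                    rest = tuple(u for u in nodes if u not in part)
                    cuts.append((part, rest))
        return cuts

    def big_phi(self, state_bits, scheme="cut_one"):
        intact = self.structure(state_bits)
        cuts = self.system_cuts(scheme)
        if not intact:
            return 0.0, cuts[0], intact
        best = float("inf")
        best_cut = None
        for cut in cuts:
            sub = BruteForceIIT(self.cut_tpm(*cut))
            d = self.structure_distance(intact, sub.structure(state_bits))
            if d < best - 1e-12:
                best = d
                best_cut = cut
        if best <= PHI_EPS:
            best = 0.0
        return best, best_cut, intact


def emd_unbalanced(supply, demand, D) -> float:
    """Transport with general (equal-total) supply/demand masses; the
    solver works on the pointwise difference, so shared mass cancels."""
    return emd_ssp(supply, demand, D)
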