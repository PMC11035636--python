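"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (explicit loops, exhaustive
enumeration) that share no code with the package internals.
"""

import math
from itertools import permutations

import numpy as np


def brute_force_modified_cosine(s1, s2, tol):
    """Exhaustive maximum over all one-to-one peak assignments.

    A pair (i, k) may contribute when it matches directly or shifted by
    the precursor difference; enumerates every injective mapping of the
    smaller spectrum's peaks onto the larger's.  Only feasible for <= 8
    peaks a side.
    """
    small, big, swapped = (s1, s2, False) if s1.n_peaks <= s2.n_peaks else (s2, s1, True)
    shift = (s2.precursor_mz - s1.precursor_mz) * (-1 if swapped else 1)
    n, m = small.n_peaks, big.n_peaks
    weight = [[0.0] * m for _ in range(n)]
    allowed = [[False] * m for _ in range(n)]
    for i in range(n):
        for k in range(m):
            direct = abs(small.mz[i] - big.mz[k]) <= tol
            shifted = abs(small.mz[i] + shift - big.mz[k]) <= tol
            if direct or shifted:
                allowed[i][k] = True
                weight[i][k] = small.intensity[i] * big.intensity[k]
    best_score, best_count = 0.0, 0
    for assign in permutations(range(m), n):
        score, count = 0.0, 0
        for i, k in enumerate(assign):
            if allowed[i][k]:
                score += weight[i][k]
                count += 1
        if score > best_score:
            best_score, best_count = score, count
    norm = math.sqrt(sum(v * v for v in s1.intensity)) * math.sqrt(
        sum(v * v for v in s2.intensity)
    )
    if norm == 0:
        return 0.0, 0
    return best_score / norm, best_count


def naive_infotheory(P):
    """Loop-based H_j, P_i, S_i, S_ij, delta_j on a plain 2-D array."""
    P = np.asarray(P, dtype=float)
    m, t = P.shape
    H = []
    for j in range(t):
        h = 0.0
        for i in range(m):
            if P[i, j] > 0:
                h -= P[i, j] * math.log2(P[i, j])
        H.append(h)
    Pi = [sum(P[i, j] for j in range(t)) / t for i in range(m)]
    S, S_cond = [], []
    for i in range(m):
        row = []
        total = 0.0
        for j in range(t):
            if P[i, j] > 0:
                ratio = P[i, j] / Pi[i]
                term = ratio * math.log2(ratio)
            else:
                term = 0.0
            row.append(term)
            total += term
        S_cond.append(row)
        S.append(total / t)
    delta = []
    for j in range(t):
        delta.append(sum(P[i, j] * S[i] for i in range(m)))
    return (
        np.array(H),
        np.array(Pi),
        np.array(S),
        np.array(S_cond),
        np.array(delta),
    )


def replay_component_cap(graph, max_component):
    """Greedy weakest-edge-first capping, re-implemented from scratch.

    Removes, from any component larger than the cap, its lowest-cosine
    edge (ties by the sorted edge-id pair) until all components fit.
    Operates on a copy; returns the surviving edge set.
    """
    import networkx as nx

    g = graph.copy()
    while True:
        oversized = [c for c in nx.connected_components(g) if len(c) > max_component]
        if not oversized:
            break
        comp = sorted(oversized, key=lambda c: sorted(c)[0])[0]
        worst = None
        for a, b, data in g.edges(comp, data=True):
            key = (data["cosine"], tuple(sorted((a, b))))
            if worst is None or key < worst[0]:
                worst = (key, (a, b))
        g.remove_edge(*worst[1])
    return {tuple(sorted(e)) for e in g.edges}
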