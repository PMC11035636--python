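"""Feature-based molecular networking.

Spectral similarity is the *modified cosine*: fragment peaks of two MS²
spectra may be matched either directly (|Δm/z| ≤ tol) or shifted by the
precursor mass difference (|Δm/z − Δprecursor| ≤ tol), each peak used at
most once.  The score is the sum of matched intensity products divided
by the product of the spectra's Euclidean intensity norms, so identical
spectra score 1.0.

The peak pairing is solved as an exact maximum-weight one-to-one
assignment over the combined direct+shifted candidate matrix
(Hungarian algorithm); spectra of practical size make this cheap and it
guarantees the reported score is the true optimum over all admissible
pairings.

Network topology follows the standard feature-based molecular
networking rules: edges require a minimum cosine (default 0.5) and a
minimum number of matched peaks (default 5), survive only if mutual
within each endpoint's top-K (default 10) candidates, analog precursor
differences are capped (default 500 Th), and oversized connected
components are split by iteratively removing their weakest edge until
no component exceeds the cap (default 100 nodes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment

from .io import FeatureTable, MsSpectrum

__all__ = [
    "SpectralEdge",
    "MolecularNetwork",
    "modified_cosine",
    "build_network",
    "network_summary",
]


@dataclass(frozen=True)
class SpectralEdge:
    feature_a: str
    feature_b: str
    cosine: float
    matched_peaks: int
    precursor_delta: float  # precursor_mz(b) - precursor_mz(a), signed


@dataclass
class MolecularNetwork:
    """Graph over MS² features with cosine-weighted edges."""

    graph: nx.Graph

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[SpectralEdge]:
        out = []
        for a, b, data in self.graph.edges(data=True):
            a, b = sorted((a, b))
            out.append(
                SpectralEdge(a, b, data["cosine"], data["matched_peaks"], data["precursor_delta"])
            )
        return sorted(out, key=lambda e: (e.feature_a, e.feature_b))

    @property
    def components(self) -> list[frozenset[str]]:
        return sorted(
            (frozenset(c) for c in nx.connected_components(self.graph)),
            key=lambda c: sorted(c)[0],
        )

    def to_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, str(path))

    def to_edgelist_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("feature_a\tfeature_b\tcosine\tmatched_peaks\tprecursor_delta\n")
            for e in self.edges:
                fh.write(
                    f"{e.feature_a}\t{e.feature_b}\t{e.cosine:.6f}\t"
                    f"{e.matched_peaks}\t{e.precursor_delta:.5f}\n"
                )


def _match_weight_matrix(s1: MsSpectrum, s2: MsSpectrum, tol: float) -> np.ndarray:
    """Intensity-product weights for all admissible peak pairs.

    A pair (i, k) is admissible if it matches directly or shifted by the
    precursor mass difference; inadmissible pairs get weight 0.
    """
    shift = s2.precursor_mz - s1.precursor_mz
    d_direct = np.abs(s1.mz[:, None] - s2.mz[None, :])
    d_shift = np.abs(s1.mz[:, None] + shift - s2.mz[None, :])
    admissible = (d_direct <= tol) | (d_shift <= tol)
    weights = s1.intensity[:, None] * s2.intensity[None, :]
    return np.where(admissible, weights, 0.0)


def modified_cosine(
    s1: MsSpectrum, s2: MsSpectrum, fragment_tol: float = 0.01
) -> tuple[float, int]:
    """Modified-cosine similarity between two MS² spectra.

    Returns ``(cosine, matched_peaks)`` where the cosine is the maximum
    over all one-to-one peak pairings (direct or precursor-shifted) of
    the matched intensity-product sum, normalized by the product of the
    two spectra's Euclidean intensity norms.  Raw intensities are used
    (no square-root weighting) unless callers pre-transform peaks.
    """
    if fragment_tol <= 0:
        raise ValueError("fragment_tol must be positive")
    if s1.n_peaks == 0 or s2.n_peaks == 0:
        raise ValueError("modified_cosine requires non-empty spectra")
    norm = float(np.linalg.norm(s1.intensity) * np.linalg.norm(s2.intensity))
    if norm == 0.0:
        return 0.0, 0
    weights = _match_weight_matrix(s1, s2, fragment_tol)
    if not weights.any():
        return 0.0, 0
    rows, cols = linear_sum_assignment(weights, maximize=True)
    chosen = weights[rows, cols]
    used = chosen > 0
    score = float(chosen[used].sum() / norm)
    return min(score, 1.0), int(used.sum())


def _mean_relative_abundance(table: FeatureTable) -> dict[str, float]:
    ab = table.abundance
    totals = ab.sum(axis=0)
    rel = ab.divide(totals.replace(0.0, np.nan), axis=1).fillna(0.0)
    return rel.mean(axis=1).to_dict()


def build_network(
    spectra: Sequence[MsSpectrum],
    abundances: FeatureTable | None = None,
    cosine_min: float = 0.5,
    min_matched: int = 5,
    top_k: int = 10,
    max_delta: float = 500.0,
    max_component: int = 100,
    fragment_tol: float = 0.01,
) -> MolecularNetwork:
    """Build the molecular network from MS² spectra.

    Stages: (i) score all spectrum pairs with |Δprecursor| ≤ ``max_delta``
    and keep candidates with cosine ≥ ``cosine_min`` and ≥ ``min_matched``
    matched peaks; (ii) keep an edge only if each endpoint ranks the
    other within its ``top_k`` best candidates (ties broken by ascending
    feature id); (iii) while any connected component exceeds
    ``max_component`` nodes, delete its lowest-cosine edge.  Node
    attributes carry precursor m/z and, when ``abundances`` is given,
    the feature's mean relative abundance across samples.
    """
    spectra = sorted(spectra, key=lambda s: s.feature_id)
    ids = [s.feature_id for s in spectra]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate feature ids among spectra")
    if abundances is not None:
        missing = [i for i in ids if i not in abundances.abundance.index]
        if missing:
            raise ValueError(f"spectra without abundance rows: {missing[:5]}")
        node_size = _mean_relative_abundance(abundances)
    else:
        node_size = {}

    candidates: list[SpectralEdge] = []
    for s1, s2 in combinations(spectra, 2):
        delta = s2.precursor_mz - s1.precursor_mz
        if abs(delta) > max_delta:
            continue
        cos, matched = modified_cosine(s1, s2, fragment_tol)
        if cos >= cosine_min and matched >= min_matched:
            candidates.append(SpectralEdge(s1.feature_id, s2.feature_id, cos, matched, delta))

    # mutual top-K: rank each node's candidates by cosine desc, partner id asc
    per_node: dict[str, list[SpectralEdge]] = {i: [] for i in ids}
    for e in candidates:
        per_node[e.feature_a].append(e)
        per_node[e.feature_b].append(e)
    top: dict[str, set[tuple[str, str]]] = {}
    for node, edges in per_node.items():
        edges_sorted = sorted(
            edges,
            key=lambda e: (-e.cosine, e.feature_b if e.feature_a == node else e.feature_a),
        )
        top[node] = {(e.feature_a, e.feature_b) for e in edges_sorted[:top_k]}
    retained = [
        e
        for e in candidates
        if (e.feature_a, e.feature_b) in top[e.feature_a]
        and (e.feature_a, e.feature_b) in top[e.feature_b]
    ]

    graph = nx.Graph()
    for spec in spectra:
        graph.add_node(
            spec.feature_id,
            precursor_mz=spec.precursor_mz,
            mean_relative_abundance=float(node_size.get(spec.feature_id, 0.0)),
        )
    for e in retained:
        graph.add_edge(
            e.feature_a,
            e.feature_b,
            cosine=e.cosine,
            matched_peaks=e.matched_peaks,
            precursor_delta=e.precursor_delta,
        )

    _cap_components(graph, max_component)
    return MolecularNetwork(graph)


def _cap_components(graph: nx.Graph, max_component: int) -> None:
    """Iteratively remove the weakest edge of any oversized component."""
    while True:
        oversized = [c for c in nx.connected_components(graph) if len(c) > max_component]
        if not oversized:
            return
        comp = min(oversized, key=lambda c: sorted(c)[0])
        sub_edges = [
            (a, b, d) for a, b, d in graph.edges(comp, data=True)
        ]
        a, b, _ = min(
            sub_edges, key=lambda t: (t[2]["cosine"], tuple(sorted((t[0], t[1]))))
        )
        graph.remove_edge(a, b)


def network_summary(net: MolecularNetwork) -> tuple[int, int, int]:
    """(n_nodes, n_in_components, n_singletons).

    A singleton is a node of degree 0; every other node sits in a
    structure-similarity grouping (component of size ≥ 2).
    """
    n_nodes = net.graph.number_of_nodes()
    n_singletons = sum(1 for _, deg in net.graph.degree() if deg == 0)
    return n_nodes, n_nodes - n_singletons, n_singletons
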