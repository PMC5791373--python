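"""All-path graph (APG) kernel over transformed dependency graphs.

The input dependency graph is rewritten into an edge-weighted, edge-unlabelled
graph: every labelled edge l(a, b) becomes a fresh edge-node vertex carrying
label ``l`` plus two unlabelled directed edges (a -> l) and (l -> b), each
inheriting the original weight. A second, disconnected subgraph encodes the
linear order of the sentence: one vertex per token (labelled with the lemma
and a position tag relative to the focus pair — before / entity1 / middle /
entity2 / after), chained left to right.

For the combined graph with weighted adjacency matrix A, the total
connectivity over all directed paths is the Neumann series
W = sum_{i>=1} A^i = (I - A)^{-1} - I, which converges when the spectral
radius of A is below 1. With the 0/1 label allocation matrix L
(L[i, j] = 1 iff label l_i is present on vertex v_j), the label-pair
connectivity matrix is G^m = L W L^T, and the kernel between two graphs is
the Frobenius inner product of their G^m matrices aligned on the label union.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .model import DepGraph, RelationInstance

logger = logging.getLogger(__name__)

__all__ = [
    "ApgConfig",
    "ApgGraph",
    "ConnectivityMatrices",
    "ConvergenceError",
    "transform_dependency_subgraph",
    "build_linear_subgraph",
    "combine_fragments",
    "connectivity",
    "label_connectivity",
    "apg_graph",
    "apg_featurize",
    "apg_kernel",
    "apg_normalized",
]


class ConvergenceError(ValueError):
    """Raised when the Neumann series for a graph does not converge."""


@dataclass
class ApgConfig:
    """Tunable settings of the APG kernel.

    ``w_linear`` weights the left-to-right token chain (the linear subgraph
    carries the positional signal, so it gets the emphasized 0.9 weight);
    ``convergence_mode`` chooses between rescaling a near-divergent adjacency
    matrix (with a logged warning) and raising :class:`ConvergenceError`.
    """

    w_linear: float = 0.9
    convergence_mode: str = "rescale"  # rescale | error
    include_position_tags: bool = True
    keep_entity_lemma: bool = True


@dataclass
class ApgGraph:
    """Edge-unlabelled weighted digraph with multi-label vertices.

    ``labels[i]`` is the label set of vertex ``i``; ``parts[i]`` records which
    subgraph the vertex belongs to (``dependency`` or ``linear``) — the two
    fragments are vertex-disjoint and mutually unconnected.
    """

    labels: list[frozenset[str]]
    edges: list[tuple[int, int, float]]
    parts: list[str] = field(default_factory=list)

    @property
    def n_vertices(self) -> int:
        return len(self.labels)

    def adjacency(self) -> np.ndarray:
        A = np.zeros((self.n_vertices, self.n_vertices))
        for u, v, w in self.edges:
            A[u, v] = w
        return A


@dataclass
class ConnectivityMatrices:
    """A, W = (I-A)^{-1} - I, the label allocation L, and G^m = L W L^T."""

    label_order: list[str]
    A: np.ndarray
    W: np.ndarray
    L: np.ndarray
    Gm: np.ndarray


def transform_dependency_subgraph(graph: DepGraph) -> ApgGraph:
    """Convert labelled edges into edge-node vertices with split edges.

    Each original edge contributes one new vertex (labelled with the edge's
    dependency label) and two unlabelled edges carrying the original weight.
    Parallel edges yield separate edge-nodes; label allocation later
    aggregates them. Original vertices keep their label sets.
    """
    order = sorted(graph.vertices)
    index = {v: i for i, v in enumerate(order)}
    labels = [graph.vertices[v].labels for v in order]
    parts = ["dependency"] * len(order)
    edges: list[tuple[int, int, float]] = []
    for e in graph.edges:
        node = len(labels)
        labels.append(frozenset([e.label]))
        parts.append("dependency")
        edges.append((index[e.source], node, e.weight))
        edges.append((node, index[e.target], e.weight))
    return ApgGraph(labels=labels, edges=edges, parts=parts)


def _position_tag(
    i: int, first: frozenset[int], second: frozenset[int], first_is_e1: bool
) -> str:
    if i in first:
        return "entity1" if first_is_e1 else "entity2"
    if i in second:
        return "entity2" if first_is_e1 else "entity1"
    if i < min(first):
        return "before"
    if i > max(second):
        return "after"
    return "middle"


def build_linear_subgraph(
    tokens: list[str],
    e1_positions: frozenset[int],
    e2_positions: frozenset[int],
    config: ApgConfig | None = None,
) -> ApgGraph:
    """Left-to-right token chain with positional labels.

    ``tokens`` are lemmas in document order; the two position sets are
    0-based token indices of the focus mentions. Each vertex carries the
    lemma plus its position tag; the n-1 chain edges carry ``w_linear``.
    Overlapping mentions are resolved by span start (logged).
    """
    config = config or ApgConfig()
    if not e1_positions or not e2_positions:
        raise ValueError("both focus mentions need at least one token position")
    if e1_positions == e2_positions:
        raise ValueError("focus mentions must differ")
    overlap = e1_positions & e2_positions
    if overlap:
        logger.warning("overlapping focus mentions at positions %s", sorted(overlap))
    first_is_e1 = min(e1_positions) <= min(e2_positions)
    first, second = (
        (e1_positions, e2_positions) if first_is_e1 else (e2_positions, e1_positions)
    )
    labels = []
    for i, lemma in enumerate(tokens):
        if config.include_position_tags:
            tag = _position_tag(i, first, second, first_is_e1)
            if i in first | second and not config.keep_entity_lemma:
                labels.append(frozenset([tag]))
            else:
                labels.append(frozenset([lemma, tag]))
        else:
            labels.append(frozenset([lemma]))
    edges = [(i, i + 1, config.w_linear) for i in range(len(tokens) - 1)]
    return ApgGraph(labels=labels, edges=edges, parts=["linear"] * len(tokens))


def combine_fragments(dep: ApgGraph, linear: ApgGraph) -> ApgGraph:
    """Disjoint union of the dependency and linear fragments."""
    off = dep.n_vertices
    return ApgGraph(
        labels=dep.labels + linear.labels,
        edges=dep.edges + [(u + off, v + off, w) for u, v, w in linear.edges],
        parts=dep.parts + linear.parts,
    )


def connectivity(A: np.ndarray, mode: str = "rescale") -> np.ndarray:
    """Total path connectivity W = (I - A)^{-1} - I.

    Entry W[u, v] is the sum over all directed u -> v paths of the product of
    edge weights along the path. Requires spectral radius rho(A) < 1; a
    near-divergent matrix is either rescaled (``mode="rescale"``, logged) or
    rejected (``mode="error"``).
    """
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    if n == 0:
        return A.copy()
    rho = float(np.max(np.abs(np.linalg.eigvals(A)))) if A.any() else 0.0
    if rho >= 1.0 - 1e-6:
        if mode == "error":
            raise ConvergenceError(
                f"spectral radius {rho:.6f} >= 1; the all-path series diverges"
            )
        scale = 0.99 * (1.0 - 1e-6) / rho
        logger.warning(
            "adjacency spectral radius %.6f >= 1; rescaling edge weights by %.6f",
            rho,
            scale,
        )
        A = A * scale
    I = np.eye(n)
    return np.linalg.solve(I - A, I) - I


def label_connectivity(
    g: ApgGraph, mode: str = "rescale"
) -> ConnectivityMatrices:
    """Label allocation L and label-pair connectivity G^m = L W L^T.

    Rows of L are ordered by label string, so G^m has a canonical label order
    for cross-graph alignment.
    """
    label_order = sorted(set().union(*g.labels)) if g.labels else []
    A = g.adjacency()
    W = connectivity(A, mode=mode)
    L = np.zeros((len(label_order), g.n_vertices))
    row = {lab: i for i, lab in enumerate(label_order)}
    for j, labs in enumerate(g.labels):
        for lab in labs:
            L[row[lab], j] = 1.0
    Gm = L @ W @ L.T
    return ConnectivityMatrices(label_order=label_order, A=A, W=W, L=L, Gm=Gm)


def apg_graph(instance: RelationInstance, config: ApgConfig | None = None) -> ApgGraph:
    """Assemble the combined (dependency + linear) graph for one instance."""
    config = config or ApgConfig()
    dep = transform_dependency_subgraph(instance.graph)
    linear = build_linear_subgraph(
        instance.linear_tokens, instance.e1_positions, instance.e2_positions, config
    )
    return combine_fragments(dep, linear)


def apg_featurize(
    instance: RelationInstance, config: ApgConfig | None = None
) -> ConnectivityMatrices:
    """Label-pair connectivity matrix for one classification instance."""
    config = config or ApgConfig()
    return label_connectivity(apg_graph(instance, config), mode=config.convergence_mode)


def _aligned_product(c1: ConnectivityMatrices, c2: ConnectivityMatrices) -> float:
    shared = sorted(set(c1.label_order) & set(c2.label_order))
    if not shared:
        return 0.0
    i1 = [c1.label_order.index(lab) for lab in shared]
    i2 = [c2.label_order.index(lab) for lab in shared]
    return float(np.sum(c1.Gm[np.ix_(i1, i1)] * c2.Gm[np.ix_(i2, i2)]))


def apg_kernel(
    a: RelationInstance, b: RelationInstance, config: ApgConfig | None = None
) -> float:
    """APG kernel: Frobenius inner product of the two G^m matrices.

    The label spaces are aligned on the union of labels; labels missing from
    one graph contribute zero rows and columns, so the sum reduces to the
    shared-label submatrices.
    """
    return _aligned_product(apg_featurize(a, config), apg_featurize(b, config))


def apg_normalized(
    a: RelationInstance, b: RelationInstance, config: ApgConfig | None = None
) -> float:
    """Cosine-normalized APG kernel in [0, 1]; 0 when either self-kernel is 0."""
    ca, cb = apg_featurize(a, config), apg_featurize(b, config)
    kaa = float(np.sum(ca.Gm * ca.Gm))
    kbb = float(np.sum(cb.Gm * cb.Gm))
    if kaa <= 0.0 or kbb <= 0.0:
        return 0.0
    return _aligned_product(ca, cb) / math.sqrt(kaa * kbb)
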