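"""Edge-weighted approximate subgraph matching (ASM) kernel.

The kernel compares two dependency graphs by (1) mapping every node label in
the joint vocabulary to the vertex bearing it (disconnected dummy vertices
stand in for labels a graph lacks), and (2) for every ordered label pair,
comparing the shortest paths between the mapped vertices through an explicit
feature map:

* ``distance``   — product of all edge weights on the path,
* ``forward``    — product over edges traversed along their direction,
* ``backward``   — product over edges traversed against their direction,
* ``edgelabel:l``— product over path edges bearing dependency label ``l``
  (other edges contribute weight^0 = 1).

The kernel score is the sum over ordered label pairs of the dot products of
the two graphs' path feature maps; pairs involving a dummy vertex or a
disconnected vertex pair contribute zero. Because each graph's feature maps
depend only on that graph, the kernel is an explicit inner product and hence
symmetric and positive semi-definite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .graphs import bfs_shortest_path
from .model import DepGraph, Edge

__all__ = [
    "FeatureMap",
    "LabelVertexMap",
    "make_label_vertex_map",
    "shortest_path",
    "path_feature_map",
    "pair_feature_maps",
    "asm_kernel",
    "asm_normalized",
]

DISTANCE = "distance"
FORWARD = "forward"
BACKWARD = "backward"
EDGE_LABEL_PREFIX = "edgelabel:"

#: A sparse feature map ``key -> value in [0, 1]``; ``None`` stands for the
#: no-path zero vector, whose dot product with anything is 0.
FeatureMap = dict[str, float]


@dataclass
class LabelVertexMap:
    """Bijection between a label vocabulary and one graph's vertices.

    Labels the graph does not realize are assigned fresh disconnected dummy
    vertices (recorded in ``dummies``); duplicate labels within the graph are
    resolved to the lowest-id bearer.
    """

    vocabulary: list[str]
    mapping: dict[str, int]
    dummies: set[str] = field(default_factory=set)


def make_label_vertex_map(
    g1: DepGraph, g2: DepGraph
) -> tuple[LabelVertexMap, LabelVertexMap]:
    """Build the label-vertex maps for two graphs over their joint vocabulary."""
    vocab = sorted(g1.labels() | g2.labels())
    maps = []
    for g in (g1, g2):
        next_dummy = max(g.vertices, default=0) + 1
        mapping: dict[str, int] = {}
        dummies: set[str] = set()
        for lab in vocab:
            v = g.vertex_with_label(lab)
            if v is None:
                mapping[lab] = next_dummy
                dummies.add(lab)
                next_dummy += 1
            else:
                mapping[lab] = v
        maps.append(LabelVertexMap(vocabulary=vocab, mapping=mapping, dummies=dummies))
    return maps[0], maps[1]


def shortest_path(
    graph: DepGraph, u: int, v: int
) -> list[tuple[Edge, bool]] | None:
    """Minimum-hop undirected path as ``(edge, forward?)`` steps.

    ``forward`` means the edge was traversed source -> target. Returns an
    empty list for ``u == v`` and ``None`` when the vertices are disconnected.
    Tie-breaking is deterministic (ascending-vertex-id BFS).
    """
    steps = bfs_shortest_path(graph, u, v)
    if steps is None:
        return None
    return [(graph.edges[ei], fwd) for ei, fwd in steps]


def path_feature_map(path: list[tuple[Edge, bool]] | None) -> FeatureMap | None:
    """Evaluate the structural / directional / edge-label features of a path.

    An empty path yields all-1 values for the three structural keys and no
    edge-label keys; a ``None`` path yields ``None`` (the zero vector).
    """
    if path is None:
        return None
    features: FeatureMap = {DISTANCE: 1.0, FORWARD: 1.0, BACKWARD: 1.0}
    for edge, forward in path:
        features[DISTANCE] *= edge.weight
        if forward:
            features[FORWARD] *= edge.weight
        else:
            features[BACKWARD] *= edge.weight
        key = EDGE_LABEL_PREFIX + edge.label
        features[key] = features.get(key, 1.0) * edge.weight
    return features


def _single_source_steps(
    graph: DepGraph, source: int
) -> dict[int, list[tuple[int, bool]]]:
    """Deterministic BFS tree from ``source``: vertex -> path as (edge, fwd) steps."""
    adj = graph.undirected_adjacency()
    parent: dict[int, tuple[int, int, bool]] = {}
    visited = {source}
    frontier = [source]
    while frontier:
        nxt = []
        for node in frontier:
            for nb, ei, fwd in adj[node]:
                if nb not in visited:
                    visited.add(nb)
                    parent[nb] = (node, ei, fwd)
                    nxt.append(nb)
        frontier = nxt
    paths: dict[int, list[tuple[int, bool]]] = {source: []}
    for v in visited:
        if v == source:
            continue
        steps: list[tuple[int, bool]] = []
        cur = v
        while cur != source:
            prev, ei, fwd = parent[cur]
            steps.append((ei, fwd))
            cur = prev
        steps.reverse()
        paths[v] = steps
    return paths


def pair_feature_maps(
    graph: DepGraph, include_diagonal: bool = False
) -> dict[tuple[str, str], FeatureMap]:
    """Path feature maps for every connected ordered label pair of one graph.

    Keys are ordered ``(l_i, l_j)`` label pairs over the graph's own labels;
    pairs whose mapped vertices are disconnected are omitted (zero vector).
    Label self-pairs are omitted unless ``include_diagonal`` (their maps are
    degenerate all-1 vectors that only add a constant to every kernel value).
    """
    labels = sorted(graph.labels())
    bearer = {lab: graph.vertex_with_label(lab) for lab in labels}
    by_source: dict[int, dict[int, list[tuple[int, bool]]]] = {}
    out: dict[tuple[str, str], FeatureMap] = {}
    for li in labels:
        x = bearer[li]
        if x not in by_source:
            by_source[x] = _single_source_steps(graph, x)
        reach = by_source[x]
        for lj in labels:
            if li == lj and not include_diagonal:
                continue
            y = bearer[lj]
            if y not in reach:
                continue
            path = [(graph.edges[ei], fwd) for ei, fwd in reach[y]]
            fm = path_feature_map(path)
            assert fm is not None
            out[(li, lj)] = fm
    return out


def _dot(a: FeatureMap, b: FeatureMap) -> float:
    if len(b) < len(a):
        a, b = b, a
    return sum(v * b[k] for k, v in a.items() if k in b)


def asm_kernel(
    g1: DepGraph, g2: DepGraph, include_diagonal: bool = False
) -> float:
    """ASM kernel score: sum over ordered label pairs of path-feature dot products.

    Labels outside a graph's own label set map to disconnected dummies and
    contribute zero, so the sum effectively runs over the shared label pairs;
    enlarging the vocabulary never changes the value.
    """
    f1 = pair_feature_maps(g1, include_diagonal)
    f2 = pair_feature_maps(g2, include_diagonal)
    if len(f2) < len(f1):
        f1, f2 = f2, f1
    return sum(_dot(fm, f2[key]) for key, fm in f1.items() if key in f2)


def asm_normalized(
    g1: DepGraph, g2: DepGraph, include_diagonal: bool = False
) -> float:
    """Cosine-normalized ASM kernel in [0, 1]; 0 when either self-kernel is 0."""
    k11 = asm_kernel(g1, g1, include_diagonal)
    k22 = asm_kernel(g2, g2, include_diagonal)
    if k11 <= 0.0 or k22 <= 0.0:
        return 0.0
    return asm_kernel(g1, g2, include_diagonal) / math.sqrt(k11 * k22)
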