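"""Graph construction: sentence graphs, entity-path weighting, focus vertices,
cross-sentence merging, and classification-instance generation.

The pipeline for one candidate concept pair is

    build_dep_graph (per sentence)
      -> merge_cross_sentence (cross-level instances only)
      -> assign_edge_weights (0.9 on the shortest entity path, 0.3 elsewhere)
      -> attach_focus_vertices (Entity1/Entity2 markers)

Shortest paths are minimum-hop paths on the undirected graph, found by
breadth-first search expanding neighbours in ascending vertex-id order, so
every tie is broken deterministically.
"""

from __future__ import annotations

import itertools
import logging

from .model import (
    FOCUS_EDGE_LABEL,
    FOCUS_LABEL_E1,
    FOCUS_LABEL_E2,
    SENTENCE_BOUNDARY_LABEL,
    W_DEFAULT,
    W_PATH,
    DepGraph,
    Document,
    Edge,
    Provenance,
    RelationInstance,
    Sentence,
    Vertex,
)

logger = logging.getLogger(__name__)

__all__ = [
    "build_dep_graph",
    "bfs_shortest_path",
    "assign_edge_weights",
    "attach_focus_vertices",
    "merge_cross_sentence",
    "merge_offset",
    "build_instances",
]


def build_dep_graph(sentence: Sentence) -> DepGraph:
    """One vertex per token (label = lemma), one edge per dependency.

    All edge weights start at the default 0.3; entity-path weighting is a
    separate, later step. Duplicate (head, dependent, label) triples are
    collapsed.
    """
    vertices = {
        t.index: Vertex(id=t.index, labels=frozenset([t.lemma]), kind="token")
        for t in sentence.tokens
    }
    edges: list[Edge] = []
    seen: set[tuple[int, int, str]] = set()
    for h, d, lab in sentence.edges:
        key = (h, d, lab)
        if key in seen:
            continue
        seen.add(key)
        edges.append(Edge(source=h, target=d, label=lab, weight=W_DEFAULT))
    return DepGraph(vertices=vertices, edges=edges, roots=list(sentence.roots))


def bfs_shortest_path(
    graph: DepGraph, u: int, v: int
) -> list[tuple[int, bool]] | None:
    """Minimum-hop undirected path from ``u`` to ``v``.

    Returns a list of ``(edge index, forward?)`` steps, empty for ``u == v``,
    or ``None`` when disconnected. Deterministic: BFS expands neighbours in
    ascending (vertex id, edge index) order and keeps first discoveries.
    """
    if u not in graph.vertices or v not in graph.vertices:
        raise KeyError(f"unknown vertex in ({u}, {v})")
    if u == v:
        return []
    adj = graph.undirected_adjacency()
    parent: dict[int, tuple[int, int, bool]] = {}
    frontier = [u]
    visited = {u}
    while frontier:
        nxt: list[int] = []
        for node in frontier:
            for nb, ei, fwd in adj[node]:
                if nb in visited:
                    continue
                visited.add(nb)
                parent[nb] = (node, ei, fwd)
                if nb == v:
                    steps: list[tuple[int, bool]] = []
                    cur = v
                    while cur != u:
                        prev, ei2, fwd2 = parent[cur]
                        steps.append((ei2, fwd2))
                        cur = prev
                    steps.reverse()
                    return steps
                nxt.append(nb)
        frontier = nxt
    return None


def assign_edge_weights(
    graph: DepGraph,
    e1: int,
    e2: int,
    w_path: float = W_PATH,
    w_default: float = W_DEFAULT,
) -> DepGraph:
    """Weight edges on the shortest undirected e1-e2 path ``w_path``, others
    ``w_default``.

    Idempotent for fixed (e1, e2); never changes topology. When the two
    vertices are disconnected all edges get ``w_default`` and the returned
    graph's ``no_path`` flag is set.
    """
    if e1 not in graph.vertices or e2 not in graph.vertices:
        raise KeyError(f"unknown focus vertex in ({e1}, {e2})")
    path = bfs_shortest_path(graph, e1, e2)
    weights = {i: w_default for i in range(len(graph.edges))}
    if path is not None:
        for ei, _ in path:
            weights[ei] = w_path
    out = graph.with_edge_weights(weights)
    out.no_path = path is None
    return out


def attach_focus_vertices(
    graph: DepGraph,
    e1: int,
    e2: int,
    focus_edge_weight: float = W_PATH,
) -> DepGraph:
    """Attach the ``Entity1``/``Entity2`` focus vertices to the pair in focus.

    Each focus vertex connects to its entity vertex by a directed edge with
    the reserved label ``focus``. A second application is rejected.
    """
    if e1 == e2:
        raise ValueError("focus vertices require two distinct entity vertices")
    if e1 not in graph.vertices or e2 not in graph.vertices:
        raise KeyError(f"unknown focus vertex in ({e1}, {e2})")
    present = graph.labels()
    if FOCUS_LABEL_E1 in present or FOCUS_LABEL_E2 in present:
        raise ValueError("focus vertices already attached")
    f1 = max(graph.vertices) + 1
    f2 = f1 + 1
    vertices = dict(graph.vertices)
    vertices[f1] = Vertex(id=f1, labels=frozenset([FOCUS_LABEL_E1]), kind="focus")
    vertices[f2] = Vertex(id=f2, labels=frozenset([FOCUS_LABEL_E2]), kind="focus")
    edges = list(graph.edges) + [
        Edge(source=f1, target=e1, label=FOCUS_EDGE_LABEL, weight=focus_edge_weight),
        Edge(source=f2, target=e2, label=FOCUS_EDGE_LABEL, weight=focus_edge_weight),
    ]
    return DepGraph(vertices=vertices, edges=edges, roots=list(graph.roots), no_path=graph.no_path)


def merge_offset(g1: DepGraph) -> int:
    """Vertex-id shift applied to the second graph by :func:`merge_cross_sentence`."""
    return max(g1.vertices)


def merge_cross_sentence(g1: DepGraph, g2: DepGraph) -> DepGraph:
    """Join two sentence graphs with a root-to-root ``SentenceBoundary`` edge.

    ``g1`` must precede ``g2`` in document order. Vertex ids of ``g2`` are
    shifted by ``merge_offset(g1)``; the boundary edge runs from the earlier
    root to the later root with the default weight (it is re-weighted to 0.9
    later if it lies on the entity shortest path).
    """
    if not g1.roots or not g2.roots:
        raise ValueError("both graphs must have a recorded root to be merged")
    off = merge_offset(g1)
    vertices = dict(g1.vertices)
    for v in g2.vertices.values():
        vertices[v.id + off] = Vertex(id=v.id + off, labels=v.labels, kind=v.kind)
    edges = list(g1.edges) + [
        Edge(source=e.source + off, target=e.target + off, label=e.label, weight=e.weight)
        for e in g2.edges
    ]
    edges.append(
        Edge(
            source=g1.roots[0],
            target=g2.roots[0] + off,
            label=SENTENCE_BOUNDARY_LABEL,
            weight=W_DEFAULT,
        )
    )
    return DepGraph(
        vertices=vertices,
        edges=edges,
        roots=list(g1.roots) + [r + off for r in g2.roots],
    )


# ---------------------------------------------------------------------------
# Instance generation
# ---------------------------------------------------------------------------


def _linear_context(
    doc: Document,
    s_i: int,
    s_j: int | None,
    m1_tokens: set[int],
    m2_tokens: set[int],
) -> tuple[list[str], frozenset[int], frozenset[int]]:
    """Concatenated lemma sequence plus 0-based mention token positions."""
    lemmas = [t.lemma for t in doc.sentences[s_i].tokens]
    e1 = {i - 1 for i in m1_tokens}
    if s_j is None:
        e2 = {i - 1 for i in m2_tokens}
    else:
        off = len(lemmas)
        lemmas += [t.lemma for t in doc.sentences[s_j].tokens]
        e2 = {off + i - 1 for i in m2_tokens}
    return lemmas, frozenset(e1), frozenset(e2)


def _mention_tokens(sent: Sentence, mention) -> set[int]:
    return {
        t.index
        for t in sent.tokens
        if t.span is not None
        and any(t.span[0] < e and s < t.span[1] for s, e in mention.spans)
    }


def _candidate_pairs(doc: Document) -> list[tuple[str, str, str]]:
    """(C, D, gold label) triples: annotated pairs, else Chemical x Disease."""
    if doc.candidate_pairs is not None:
        return list(doc.candidate_pairs)
    chems = sorted({m.concept_id for m in doc.entities if m.entity_type == "Chemical"})
    dises = sorted({m.concept_id for m in doc.entities if m.entity_type == "Disease"})
    return [
        (c, d, "positive" if (c, d) in doc.gold_relations else "negative")
        for c, d in itertools.product(chems, dises)
    ]


def build_instances(
    doc: Document,
    w_path: float = W_PATH,
    w_default: float = W_DEFAULT,
    focus_edge_weight: float = W_PATH,
    max_cross_sentence_distance: int | None = None,
) -> list[RelationInstance]:
    """Generate one classification instance per candidate-pair realization.

    For each candidate concept pair (C, D): when at least one sentence bears
    mentions of both concepts, one sentence-level instance is built per
    co-mention mention pair; otherwise one cross-level instance is built per
    (sentence with C) x (sentence with D) pair, using the first mention of
    each concept in its sentence. Each instance's graph runs through
    build -> merge (cross only) -> weight -> focus.
    """
    instances: list[RelationInstance] = []
    by_concept: dict[str, list] = {}
    for m in doc.entities:
        by_concept.setdefault(m.concept_id, []).append(m)
    sent_graphs = [build_dep_graph(s) for s in doc.sentences]

    for c1, c2, label in _candidate_pairs(doc):
        ms1, ms2 = by_concept.get(c1, []), by_concept.get(c2, [])
        if not ms1 or not ms2:
            logger.warning(
                "document %s: concept pair (%s, %s) skipped, missing mentions",
                doc.doc_id,
                c1,
                c2,
            )
            continue
        sents1 = {m.sentence_index for m in ms1}
        sents2 = {m.sentence_index for m in ms2}
        common = sorted(sents1 & sents2)
        if common:
            for s_i in common:
                for m1 in (m for m in ms1 if m.sentence_index == s_i):
                    for m2 in (m for m in ms2 if m.sentence_index == s_i):
                        if m1.head_token_index == m2.head_token_index:
                            continue
                        g = assign_edge_weights(
                            sent_graphs[s_i],
                            m1.head_token_index,
                            m2.head_token_index,
                            w_path,
                            w_default,
                        )
                        g = attach_focus_vertices(
                            g,
                            m1.head_token_index,
                            m2.head_token_index,
                            focus_edge_weight,
                        )
                        toks, p1, p2 = _linear_context(
                            doc,
                            s_i,
                            None,
                            _mention_tokens(doc.sentences[s_i], m1),
                            _mention_tokens(doc.sentences[s_i], m2),
                        )
                        instances.append(
                            RelationInstance(
                                graph=g,
                                focus=(m1.head_token_index, m2.head_token_index),
                                label=label,
                                level="sentence",
                                provenance=Provenance(doc.doc_id, (c1, c2), (s_i,)),
                                linear_tokens=toks,
                                e1_positions=p1,
                                e2_positions=p2,
                            )
                        )
        else:
            for s_i in sorted(sents1):
                for s_j in sorted(sents2):
                    if (
                        max_cross_sentence_distance is not None
                        and abs(s_i - s_j) > max_cross_sentence_distance
                    ):
                        logger.info(
                            "document %s: pair (%s, %s) sentence pair (%d, %d) "
                            "beyond max distance, skipped",
                            doc.doc_id,
                            c1,
                            c2,
                            s_i,
                            s_j,
                        )
                        continue
                    m1 = next(m for m in ms1 if m.sentence_index == s_i)
                    m2 = next(m for m in ms2 if m.sentence_index == s_j)
                    first, second = (s_i, s_j) if s_i < s_j else (s_j, s_i)
                    merged = merge_cross_sentence(sent_graphs[first], sent_graphs[second])
                    off = merge_offset(sent_graphs[first])
                    v1 = m1.head_token_index + (off if s_i == second else 0)
                    v2 = m2.head_token_index + (off if s_j == second else 0)
                    merged = assign_edge_weights(merged, v1, v2, w_path, w_default)
                    merged = attach_focus_vertices(merged, v1, v2, focus_edge_weight)
                    t1 = _mention_tokens(doc.sentences[s_i], m1)
                    t2 = _mention_tokens(doc.sentences[s_j], m2)
                    if s_i < s_j:
                        toks, p1, p2 = _linear_context(doc, s_i, s_j, t1, t2)
                    else:
                        toks, p2, p1 = _linear_context(doc, s_j, s_i, t2, t1)
                    instances.append(
                        RelationInstance(
                            graph=merged,
                            focus=(v1, v2),
                            label=label,
                            level="cross",
                            provenance=Provenance(doc.doc_id, (c1, c2), (s_i, s_j)),
                            linear_tokens=toks,
                            e1_positions=p1,
                            e2_positions=p2,
                        )
                    )
    return instances
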