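"""Graph construction: weighting, focus vertices, merging, instance generation."""

import networkx as nx
import numpy as np
import pytest

from relkern.graphs import (
    assign_edge_weights,
    attach_focus_vertices,
    build_dep_graph,
    build_instances,
    merge_cross_sentence,
    merge_offset,
)
from relkern.model import (
    FOCUS_LABEL_E1,
    FOCUS_LABEL_E2,
    SENTENCE_BOUNDARY_LABEL,
    Sentence,
    Token,
)
from relkern.synthetic import fig1_sentence

from conftest import random_dep_graph


def to_nx_undirected(graph) -> nx.MultiGraph:
    g = nx.MultiGraph()
    g.add_nodes_from(graph.vertices)
    for e in graph.edges:
        g.add_edge(e.source, e.target)
    return g


def chain_sentence(words, labels=None) -> Sentence:
    tokens = [
        Token(index=i + 1, word=w, lemma=w.lower()) for i, w in enumerate(words)
    ]
    labels = labels or ["dep"] * (len(words) - 1)
    edges = [(i, i + 1, labels[i - 1]) for i in range(1, len(words))]
    return Sentence(tokens=tokens, edges=edges, roots=[1])


# ---------------------------------------------------------------------------
# build_dep_graph
# ---------------------------------------------------------------------------


def test_enhanced_graph_has_undirected_cycle(fig1):
    graph, _ = fig1
    assert len(graph.vertices) == 7
    assert len(graph.edges) == 7
    und = to_nx_undirected(graph)
    # caused(3) - alcohol(5) - fatigue(7) - caused(3) is a cycle
    cycle_nodes = {frozenset(c) for c in nx.cycle_basis(nx.Graph(und))}
    assert frozenset({3, 5, 7}) in cycle_nodes


def test_single_token_sentence():
    g = build_dep_graph(chain_sentence(["run"]))
    assert len(g.vertices) == 1 and len(g.edges) == 0


def test_default_weights_are_0_3():
    g = build_dep_graph(chain_sentence(["a", "b", "c"]))
    assert all(e.weight == 0.3 for e in g.edges)


# ---------------------------------------------------------------------------
# assign_edge_weights
# ---------------------------------------------------------------------------


def test_fig1_entity_path_weighting(fig1):
    graph, (e1, e2) = fig1
    heavy = [(e.source, e.target, e.label) for e in graph.edges if e.weight == 0.9]
    assert sorted(heavy) == [(3, 1, "nsubj"), (3, 7, "nmod:by")]
    assert sum(1 for e in graph.edges if e.weight == 0.3) == 5


def test_same_entity_reweights_nothing(fig1):
    graph, _ = fig1
    g = assign_edge_weights(build_dep_graph(fig1_sentence()), 3, 3)
    assert all(e.weight == 0.3 for e in g.edges)


def test_disconnected_entities_set_no_path_flag():
    sent = Sentence(
        tokens=[Token(index=i, word=w, lemma=w) for i, w in enumerate("abcd", 1)],
        edges=[(1, 2, "dep"), (3, 4, "dep")],
        roots=[1, 3],
    )
    g = assign_edge_weights(build_dep_graph(sent), 1, 4)
    assert g.no_path
    assert all(e.weight == 0.3 for e in g.edges)


def test_weighting_idempotent_and_topology_preserving():
    rng = np.random.default_rng(42)
    for _ in range(25):
        g = random_dep_graph(rng)
        ids = sorted(g.vertices)
        e1, e2 = ids[0], ids[-1]
        once = assign_edge_weights(g, e1, e2)
        twice = assign_edge_weights(once, e1, e2)
        assert [(e.source, e.target, e.label) for e in once.edges] == [
            (e.source, e.target, e.label) for e in g.edges
        ]
        assert [(e.source, e.target, e.label, e.weight) for e in once.edges] == [
            (e.source, e.target, e.label, e.weight) for e in twice.edges
        ]


def test_unknown_vertex_rejected(fig1):
    graph, _ = fig1
    with pytest.raises(KeyError):
        assign_edge_weights(graph, 1, 99)


# ---------------------------------------------------------------------------
# attach_focus_vertices
# ---------------------------------------------------------------------------


def test_focus_vertices_added_once(fig1):
    graph, (e1, e2) = fig1
    g = attach_focus_vertices(graph, e1, e2)
    assert len(g.vertices) == 9 and len(g.edges) == 9
    assert sum(1 for v in g.vertices.values() if FOCUS_LABEL_E1 in v.labels) == 1
    assert sum(1 for v in g.vertices.values() if FOCUS_LABEL_E2 in v.labels) == 1
    with pytest.raises(ValueError, match="already"):
        attach_focus_vertices(g, e1, e2)


def test_focus_order_matters(fig1):
    graph, (e1, e2) = fig1
    g_ab = attach_focus_vertices(graph, e1, e2)
    g_ba = attach_focus_vertices(graph, e2, e1)
    tgt = {
        lab: e.target
        for g in (g_ab,)
        for e in g.edges
        if e.label == "focus"
        for lab in g.vertices[e.source].labels
    }
    tgt_swapped = {
        lab: e.target
        for e in g_ba.edges
        if e.label == "focus"
        for lab in g_ba.vertices[e.source].labels
    }
    assert tgt[FOCUS_LABEL_E1] == tgt_swapped[FOCUS_LABEL_E2]
    assert tgt[FOCUS_LABEL_E2] == tgt_swapped[FOCUS_LABEL_E1]


# ---------------------------------------------------------------------------
# merge_cross_sentence
# ---------------------------------------------------------------------------


def test_merge_counts_and_labels():
    g1 = build_dep_graph(chain_sentence(["a", "b", "c"], ["nsubj", "dobj"]))
    g2 = build_dep_graph(chain_sentence(["d", "e", "f"], ["amod", "case"]))
    m = merge_cross_sentence(g1, g2)
    assert len(m.vertices) == 6
    assert len(m.edges) == len(g1.edges) + len(g2.edges) + 1
    assert {e.label for e in m.edges} == {
        "nsubj",
        "dobj",
        "amod",
        "case",
        SENTENCE_BOUNDARY_LABEL,
    }


def test_merge_then_weight_crosses_boundary():
    g1 = build_dep_graph(chain_sentence(["a", "b", "c"]))
    g2 = build_dep_graph(chain_sentence(["d", "e", "f"]))
    m = merge_cross_sentence(g1, g2)
    off = merge_offset(g1)
    weighted = assign_edge_weights(m, 3, 3 + off)
    boundary = next(e for e in weighted.edges if e.label == SENTENCE_BOUNDARY_LABEL)
    assert boundary.weight == 0.9  # shortest path c..root1..root2..f uses it
    # hand trace: path c-b-a-(boundary)-d-e-f covers all 5 edges
    assert all(e.weight == 0.9 for e in weighted.edges)


def test_merge_symmetric_undirected_topology():
    rng = np.random.default_rng(3)
    for _ in range(10):
        g1, g2 = random_dep_graph(rng), random_dep_graph(rng)
        m12 = merge_cross_sentence(g1, g2)
        m21 = merge_cross_sentence(g2, g1)
        assert nx.is_isomorphic(to_nx_undirected(m12), to_nx_undirected(m21))


def test_merge_requires_roots():
    g1 = build_dep_graph(chain_sentence(["a", "b"]))
    g2 = build_dep_graph(chain_sentence(["c", "d"]))
    g2.roots = []
    with pytest.raises(ValueError, match="root"):
        merge_cross_sentence(g1, g2)


# ---------------------------------------------------------------------------
# build_instances
# ---------------------------------------------------------------------------


def test_table1_co_mention_pair_yields_two_sentence_instances(table1):
    instances = build_instances(table1)
    co = [i for i in instances if i.provenance.pair == ("D011441", "D056486")]
    assert len(co) == 2
    assert all(i.level == "sentence" for i in co)
    assert all(i.label == "positive" for i in co)
    assert sorted(i.provenance.sentence_indices for i in co) == [(0,), (1,)]


def test_table1_cross_pair_instances(table1):
    instances = build_instances(table1)
    cross = [i for i in instances if i.provenance.pair == ("D011441", "D006521")]
    assert len(cross) == 2  # title chem x s2, abstract chem x s2
    assert all(i.level == "cross" for i in cross)
    assert all(i.label == "positive" for i in cross)
    for inst in cross:
        boundary = [e for e in inst.graph.edges if e.label == SENTENCE_BOUNDARY_LABEL]
        assert len(boundary) == 1


def test_instances_partition_levels(table1, small_corpus):
    instances = build_instances(table1) + small_corpus
    by_pair = {}
    for inst in instances:
        key = (inst.provenance.doc_id, inst.provenance.pair)
        by_pair.setdefault(key, set()).add(inst.level)
    assert all(len(levels) == 1 for levels in by_pair.values())


def test_every_instance_has_one_focus_pair(small_corpus):
    for inst in small_corpus:
        labs = [lab for v in inst.graph.vertices.values() for lab in v.labels]
        assert labs.count(FOCUS_LABEL_E1) == 1
        assert labs.count(FOCUS_LABEL_E2) == 1


def test_concept_without_mention_skipped(table1, caplog):
    doc = table1
    doc2 = type(doc)(
        doc_id=doc.doc_id,
        text=doc.text,
        sentences=doc.sentences,
        sentence_spans=doc.sentence_spans,
        entities=doc.entities,
        gold_relations=doc.gold_relations,
        candidate_pairs=[("D011441", "D999999", "negative")],
    )
    with caplog.at_level("WARNING"):
        assert build_instances(doc2) == []
    assert "missing mentions" in caplog.text
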