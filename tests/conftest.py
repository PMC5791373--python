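"""Shared fixtures: random graphs, the worked-example structures, and a
synthetic PPI-XML corpus built from the generator."""

from __future__ import annotations

import numpy as np
import pytest

from relkern.model import DepGraph, Edge, Provenance, RelationInstance, Vertex
from relkern.synthetic import GenConfig, fig1_fixture, generate_corpus, table1_fixture

DEP_LABELS = ["nsubj", "dobj", "nmod:by", "conj:and", "amod"]


def random_dep_graph(rng: np.random.Generator, n_max: int = 8) -> DepGraph:
    """Random connected graph with distinct vertex labels and 0.3/0.9 weights.

    A spanning tree (each vertex attaches to a random earlier one) plus a few
    extra edges, so undirected cycles occur regularly.
    """
    n = int(rng.integers(2, n_max + 1))
    vertices = {
        i: Vertex(id=i, labels=frozenset([f"l{i}"])) for i in range(1, n + 1)
    }
    seen: set[tuple[int, int, str]] = set()
    edges: list[Edge] = []

    def add(u: int, v: int) -> None:
        lab = DEP_LABELS[int(rng.integers(0, len(DEP_LABELS)))]
        w = 0.9 if rng.random() < 0.5 else 0.3
        if (u, v, lab) not in seen:
            seen.add((u, v, lab))
            edges.append(Edge(source=u, target=v, label=lab, weight=w))

    for i in range(2, n + 1):
        add(int(rng.integers(1, i)), i)
    for _ in range(int(rng.integers(0, n))):
        u, v = (int(x) + 1 for x in rng.choice(n, size=2, replace=False))
        add(u, v)
    return DepGraph(vertices=vertices, edges=edges, roots=[1])


def make_instance(
    graph: DepGraph,
    focus: tuple[int, int],
    tokens: list[str],
    e1_pos: frozenset[int],
    e2_pos: frozenset[int],
    label: str = "negative",
) -> RelationInstance:
    return RelationInstance(
        graph=graph,
        focus=focus,
        label=label,
        level="sentence",
        provenance=Provenance("t", ("c1", "c2"), (0,)),
        linear_tokens=tokens,
        e1_positions=e1_pos,
        e2_positions=e2_pos,
    )


@pytest.fixture(scope="session")
def fig1():
    return fig1_fixture()


@pytest.fixture(scope="session")
def table1():
    return table1_fixture()


@pytest.fixture(scope="session")
def small_corpus():
    """20 synthetic documents -> instances, used by algebra/invariant tests."""
    from relkern.graphs import build_instances

    docs = generate_corpus(GenConfig(n_documents=20, seed=11))
    return [inst for d in docs for inst in build_instances(d)]


def synthetic_ppi_xml(n_docs: int = 30, seed: int = 5) -> str:
    """Serialize sentence-level synthetic documents in the unified PPI dialect."""
    from lxml import etree

    docs = generate_corpus(
        GenConfig(n_documents=n_docs, seed=seed, p_cross=0.0, noise=0.0)
    )
    corpus = etree.Element("corpus", source="synthetic")
    for doc in docs:
        d_el = etree.SubElement(corpus, "document", id=doc.doc_id)
        for s_idx, (sent, (s_start, _)) in enumerate(
            zip(doc.sentences, doc.sentence_spans)
        ):
            s_text = doc.text[doc.sentence_spans[s_idx][0] : doc.sentence_spans[s_idx][1]]
            s_el = etree.SubElement(
                d_el, "sentence", id=f"{doc.doc_id}.s{s_idx}", text=s_text
            )
            local = [m for m in doc.entities if m.sentence_index == s_idx]
            for m in local:
                a, b = m.spans[0]
                etree.SubElement(
                    s_el,
                    "entity",
                    id=m.mention_id,
                    charOffset=f"{a - s_start}-{b - s_start - 1}",
                    type="protein",
                    text=m.text,
                )
            if len(local) == 2:
                positive = doc.gold_relations != set()
                etree.SubElement(
                    s_el,
                    "pair",
                    id=f"{doc.doc_id}.p0",
                    e1=local[0].mention_id,
                    e2=local[1].mention_id,
                    interaction=str(positive),
                )
            tz = etree.SubElement(s_el, "tokenization")
            for t in sent.tokens:
                etree.SubElement(
                    tz,
                    "token",
                    id=f"t{t.index}",
                    charOffset=f"{t.span[0] - s_start}-{t.span[1] - s_start - 1}",
                    POS="NN",
                    text=t.word,
                )
            p_el = etree.SubElement(s_el, "parse")
            for h, dpd, lab in sent.edges:
                etree.SubElement(
                    p_el, "dependency", t1=f"t{h}", t2=f"t{dpd}", type=lab
                )
    return etree.tostring(corpus, pretty_print=True).decode()
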