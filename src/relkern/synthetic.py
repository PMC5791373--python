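"""Worked fixtures and a planted-signal corpus generator.

Two fixed fixtures support the worked examples: the seven-token enhanced
dependency graph of the sentence "Seizures were caused by Alcohol and
Fatigue" (whose undirected form contains a cycle through "caused", "alcohol"
and "fatigue"), and a CDR-style annotated title+abstract document about
propylthiouracil-induced liver damage, with five entity mentions and two gold
chemical-disease relations (one expressed within single sentences, one only
across a sentence boundary). The parses bundled with the document fixture are
hand-written plausible analyses, not corpus data.

The generator produces random multi-sentence documents with dependency trees
drawn by sequential head-attachment plus occasional extra enhanced edges
(creating cycles), one chemical and one disease mention per document, and a
plantable lexical/structural signal. Positive pairs use the compact
subject-trigger-object construction: both mentions are syntactic dependents
of a trigger token ("induce", "cause") that sits between them in linear
order — or, for cross-sentence pairs, the trigger is the root of the
chemical-bearing sentence so the merged shortest path passes through it.
Negative pairs fall at arbitrary positions with their random attachments and
never contain a trigger, so with zero noise a rule-based path detector is a
perfect oracle for the planted signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graphs import assign_edge_weights, bfs_shortest_path, build_dep_graph
from .io import resolve_mention_positions, write_conllu, write_pubtator
from .model import (
    DepGraph,
    Document,
    EntityMention,
    RelationInstance,
    Sentence,
    Token,
)

__all__ = [
    "GenConfig",
    "fig1_fixture",
    "table1_fixture",
    "generate_corpus",
    "corpus_to_conllu",
    "corpus_to_pubtator",
    "trigger_on_path",
]

DEFAULT_DEP_LABELS = ("nsubj", "dobj", "nmod:by", "conj:and", "case", "amod", "advmod")


@dataclass
class GenConfig:
    """Study conditions for the generated corpus.

    Defaults emulate a CDR-like document collection: short abstracts of 2-4
    sentences, a positive rate of about a third, 30% of relations expressed
    only across sentence boundaries, and a 10% chance that a positive pair
    lacks its trigger (label noise relative to the planted lexical signal).
    """

    n_documents: int = 100
    sentences_per_document: tuple[int, int] = (2, 4)
    tokens_per_sentence: tuple[int, int] = (6, 10)
    vocab_size: int = 50
    dep_labels: tuple[str, ...] = DEFAULT_DEP_LABELS
    triggers: tuple[str, ...] = ("induce", "cause")
    p_positive: float = 0.35
    p_cross: float = 0.3
    p_extra_edge: float = 0.15
    noise: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_positive, self.p_cross, self.p_extra_edge, self.noise):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.tokens_per_sentence[0] < 5:
            raise ValueError("sentences need >= 5 tokens to host trigger and entities")
        if self.vocab_size < 3:
            raise ValueError("vocabulary too small for the requested entities")


# ---------------------------------------------------------------------------
# Worked fixtures
# ---------------------------------------------------------------------------


def fig1_sentence() -> Sentence:
    """The 7-token enhanced dependency parse of the worked-example sentence."""
    words = ["Seizures", "were", "caused", "by", "Alcohol", "and", "Fatigue"]
    tokens = [
        Token(index=i + 1, word=w, lemma=w.lower(), pos="_")
        for i, w in enumerate(words)
    ]
    edges = [
        (3, 1, "nsubj"),
        (3, 2, "auxpass"),
        (5, 4, "case"),
        (3, 5, "nmod:by"),
        (5, 6, "cc"),
        (5, 7, "conj:and"),
        (3, 7, "nmod:by"),
    ]
    return Sentence(tokens=tokens, edges=edges, roots=[3])


def fig1_fixture() -> tuple[DepGraph, tuple[int, int]]:
    """Weighted worked-example graph and its entity pair (seizures, fatigue).

    The two edges on the shortest entity path — nsubj(caused, seizures) and
    nmod:by(caused, fatigue) — carry weight 0.9; the other five carry 0.3.
    """
    graph = build_dep_graph(fig1_sentence())
    e1 = graph.vertex_with_label("seizures")
    e2 = graph.vertex_with_label("fatigue")
    assert e1 is not None and e2 is not None
    return assign_edge_weights(graph, e1, e2), (e1, e2)


_T1_TITLE = "Propylthiouracil-induced hepatic damage."
_T1_ABSTRACT = (
    "Two cases of propylthiouracil-induced liver damage have been observed. "
    "The first case is of an acute type of damage, proven by rechallenge; "
    "the second presents a clinical and histologic picture resembling "
    "chronic active hepatitis, with spontaneous remission."
)

# Hand-written dependency analyses (word, head, deprel); head 0 = root.
_T1_PARSES: list[list[tuple[str, int, str]]] = [
    [
        ("Propylthiouracil-induced", 3, "amod"),
        ("hepatic", 3, "amod"),
        ("damage", 0, "root"),
        (".", 3, "punct"),
    ],
    [
        ("Two", 2, "nummod"),
        ("cases", 9, "nsubjpass"),
        ("of", 6, "case"),
        ("propylthiouracil-induced", 6, "amod"),
        ("liver", 6, "compound"),
        ("damage", 2, "nmod:of"),
        ("have", 9, "aux"),
        ("been", 9, "auxpass"),
        ("observed", 0, "root"),
        (".", 9, "punct"),
    ],
    [
        ("The", 3, "det"),
        ("first", 3, "amod"),
        ("case", 4, "nsubj"),
        ("is", 0, "root"),
        ("of", 8, "case"),
        ("an", 8, "det"),
        ("acute", 8, "amod"),
        ("type", 4, "nmod:of"),
        ("of", 10, "case"),
        ("damage", 8, "nmod:of"),
        (",", 4, "punct"),
        ("proven", 10, "acl"),
        ("by", 14, "case"),
        ("rechallenge", 12, "nmod:by"),
        (";", 4, "punct"),
        ("the", 17, "det"),
        ("second", 18, "nsubj"),
        ("presents", 4, "parataxis"),
        ("a", 23, "det"),
        ("clinical", 23, "amod"),
        ("and", 23, "cc"),
        ("histologic", 23, "amod"),
        ("picture", 18, "dobj"),
        ("resembling", 23, "acl"),
        ("chronic", 27, "amod"),
        ("active", 27, "amod"),
        ("hepatitis", 24, "dobj"),
        (",", 18, "punct"),
        ("with", 31, "case"),
        ("spontaneous", 31, "amod"),
        ("remission", 18, "nmod:with"),
        (".", 4, "punct"),
    ],
]

_T1_MENTIONS = [
    ("D011441", "Chemical", "Propylthiouracil", 0, 16),
    ("D011441", "Chemical", "propylthiouracil", 54, 70),
    ("D056486", "Disease", "hepatic damage", 25, 39),
    ("D056486", "Disease", "liver damage", 79, 91),
    ("D006521", "Disease", "chronic active hepatitis", 246, 270),
]


def _locate(text: str, word: str, cursor: int) -> tuple[int, int]:
    start = text.index(word, cursor)
    return start, start + len(word)


def table1_fixture() -> Document:
    """The CDR sample document: 5 mentions, 2 gold chemical-disease relations.

    The (D011441, D056486) relation is co-mentioned in the title and the first
    abstract sentence; the (D011441, D006521) relation spans a sentence
    boundary (no sentence mentions both concepts).
    """
    text = _T1_TITLE + " " + _T1_ABSTRACT
    sentences: list[Sentence] = []
    spans: list[tuple[int, int]] = []
    cursor = 0
    for parse in _T1_PARSES:
        tokens = []
        edges = []
        sent_start = None
        for i, (word, head, deprel) in enumerate(parse, start=1):
            s, e = _locate(text, word, cursor)
            cursor = e
            sent_start = s if sent_start is None else sent_start
            tokens.append(Token(index=i, word=word, lemma=word.lower(), span=(s, e)))
            if head > 0:
                edges.append((head, i, deprel))
        sentences.append(Sentence(tokens=tokens, edges=edges))
        spans.append((sent_start, cursor))
    entities = [
        EntityMention(
            mention_id=f"T1.m{i}",
            concept_id=cid,
            entity_type=etype,
            spans=[(s, e)],
            text=mtext,
        )
        for i, (cid, etype, mtext, s, e) in enumerate(_T1_MENTIONS)
    ]
    doc = Document(
        doc_id="T1",
        text=text,
        sentences=sentences,
        sentence_spans=spans,
        entities=entities,
        gold_relations={("D011441", "D056486"), ("D011441", "D006521")},
    )
    resolve_mention_positions(doc)
    return doc


# ---------------------------------------------------------------------------
# Planted-signal corpus
# ---------------------------------------------------------------------------


@dataclass
class _SentencePlan:
    lemmas: list[str]
    heads: list[int]  # head of token i+1; 0 = root
    deprels: list[str]
    extra_edges: list[tuple[int, int, str]] = field(default_factory=list)


def _random_sentence(rng: np.random.Generator, config: GenConfig) -> _SentencePlan:
    lo, hi = config.tokens_per_sentence
    n = int(rng.integers(lo, hi + 1))
    vocab = [f"w{i:03d}" for i in range(config.vocab_size)]
    lemmas = [vocab[int(k)] for k in rng.integers(0, config.vocab_size, size=n)]
    heads = [0] + [int(rng.integers(1, i)) for i in range(2, n + 1)]
    deprels = ["root"] + [
        config.dep_labels[int(k)]
        for k in rng.integers(0, len(config.dep_labels), size=n - 1)
    ]
    plan = _SentencePlan(lemmas=lemmas, heads=heads, deprels=deprels)
    if rng.random() < config.p_extra_edge and n >= 4:
        u, v = (int(x) + 1 for x in rng.choice(n, size=2, replace=False))
        if plan.heads[v - 1] != u and plan.heads[u - 1] != v:
            lab = config.dep_labels[int(rng.integers(0, len(config.dep_labels)))]
            plan.extra_edges.append((u, v, lab))
    return plan


def _plan_to_sentence(plan: _SentencePlan, doc_cursor: int) -> tuple[Sentence, int]:
    tokens = []
    cursor = doc_cursor
    for i, lemma in enumerate(plan.lemmas, start=1):
        start = cursor
        end = start + len(lemma)
        tokens.append(Token(index=i, word=lemma, lemma=lemma, span=(start, end)))
        cursor = end + 1
    edges = [
        (h, i + 1, plan.deprels[i])
        for i, h in enumerate(plan.heads)
        if h > 0
    ]
    edges += plan.extra_edges
    roots = [i + 1 for i, h in enumerate(plan.heads) if h == 0]
    return Sentence(tokens=tokens, edges=edges, roots=roots), cursor


def generate_corpus(config: GenConfig) -> list[Document]:
    """Generate documents with a planted chemical-disease relation signal.

    Pure function of ``config.seed``: re-running with the same configuration
    reproduces the corpus byte for byte.
    """
    rng = np.random.default_rng(config.seed)
    docs: list[Document] = []
    for d in range(config.n_documents):
        positive = rng.random() < config.p_positive
        cross = rng.random() < config.p_cross
        planted = positive and rng.random() >= config.noise
        trigger = config.triggers[int(rng.integers(0, len(config.triggers)))]

        lo, hi = config.sentences_per_document
        n_sent = int(rng.integers(max(lo, 2) if cross else lo, hi + 1))
        plans: list[_SentencePlan] = []
        if cross:
            si, sj = sorted(
                int(x) for x in rng.choice(n_sent, size=2, replace=False)
            )
        else:
            si = sj = int(rng.integers(0, n_sent))

        chem_lemma = f"chem{d:03d}"
        dis_lemma = f"dis{d:03d}"
        chem_pos = dis_pos = None
        for s in range(n_sent):
            plan = _random_sentence(rng, config)
            n = len(plan.lemmas)
            if not cross and s == si:
                if positive:
                    # Related pairs are expressed by the compact
                    # subject-trigger-object construction ("chemx induces
                    # disx"): adjacent in linear order, both entities
                    # dependents of the trigger token. The trigger is
                    # re-attached below e1 so its head chain never passes
                    # through either entity, keeping the structure a tree.
                    e1 = int(rng.integers(2, n - 1))
                    t, e2 = e1 + 1, e1 + 2
                    plan.heads[t - 1] = int(rng.integers(1, e1))
                    plan.heads[e1 - 1] = t
                    plan.deprels[e1 - 1] = "nsubj"
                    plan.heads[e2 - 1] = t
                    plan.deprels[e2 - 1] = "dobj"
                    if planted:
                        plan.lemmas[t - 1] = trigger
                else:
                    # Unrelated co-mentions: entities fall at arbitrary
                    # positions with their generated attachments.
                    e1, e2 = sorted(
                        int(x) + 2 for x in rng.choice(n - 1, size=2, replace=False)
                    )
                plan.lemmas[e1 - 1] = chem_lemma
                plan.lemmas[e2 - 1] = dis_lemma
                plan.extra_edges = [
                    (u, v, lab)
                    for u, v, lab in plan.extra_edges
                    if e1 not in (u, v) and e2 not in (u, v)
                ]
                chem_pos = (s, e1)
                dis_pos = (s, e2)
            elif cross and s == si:
                e1 = int(rng.integers(2, n + 1))
                if positive:
                    # Prominent mention: subject of the sentence root, which
                    # carries the trigger ("chemx induces ...").
                    plan.heads[e1 - 1] = 1
                    plan.deprels[e1 - 1] = "nsubj"
                    if planted:
                        plan.lemmas[0] = trigger
                plan.lemmas[e1 - 1] = chem_lemma
                plan.extra_edges = [
                    (u, v, lab) for u, v, lab in plan.extra_edges if e1 not in (u, v)
                ]
                chem_pos = (s, e1)
            elif cross and s == sj:
                e2 = int(rng.integers(2, n + 1))
                if positive:
                    plan.heads[e2 - 1] = 1
                    plan.deprels[e2 - 1] = "dobj"
                plan.lemmas[e2 - 1] = dis_lemma
                plan.extra_edges = [
                    (u, v, lab) for u, v, lab in plan.extra_edges if e2 not in (u, v)
                ]
                dis_pos = (s, e2)
            plans.append(plan)

        sentences = []
        spans = []
        cursor = 0
        for plan in plans:
            sent, cursor = _plan_to_sentence(plan, cursor)
            start = sent.tokens[0].span[0]
            end = sent.tokens[-1].span[1]
            sentences.append(sent)
            spans.append((start, end))
        text_parts = [" ".join(p.lemmas) for p in plans]
        text = " ".join(text_parts)

        assert chem_pos is not None and dis_pos is not None
        chem_id = f"C{d:05d}"
        dis_id = f"D{d:05d}"
        entities = []
        for mid, (cid, etype, (s_idx, t_idx)) in enumerate(
            [(chem_id, "Chemical", chem_pos), (dis_id, "Disease", dis_pos)]
        ):
            tok = sentences[s_idx].tokens[t_idx - 1]
            entities.append(
                EntityMention(
                    mention_id=f"d{d}.m{mid}",
                    concept_id=cid,
                    entity_type=etype,
                    spans=[tok.span],
                    sentence_index=s_idx,
                    head_token_index=t_idx,
                    text=tok.word,
                )
            )
        docs.append(
            Document(
                doc_id=f"synth{d:05d}",
                text=text,
                sentences=sentences,
                sentence_spans=spans,
                entities=entities,
                gold_relations={(chem_id, dis_id)} if positive else set(),
            )
        )
    return docs


def corpus_to_conllu(docs: list[Document]) -> str:
    return "".join(write_conllu(doc.sentences, doc_id=doc.doc_id) for doc in docs)


def corpus_to_pubtator(docs: list[Document]) -> str:
    return write_pubtator(docs)


def trigger_on_path(
    instance: RelationInstance, triggers: tuple[str, ...] = ("induce", "cause")
) -> bool:
    """Rule-based detector: is a trigger lemma on the focus shortest path?

    With zero generation noise this detector recovers the planted labels
    perfectly, upper-bounding what the kernels can learn from the corpus.
    """
    steps = bfs_shortest_path(instance.graph, *instance.focus)
    if steps is None:
        return False
    on_path: set[int] = set(instance.focus)
    for ei, _ in steps:
        e = instance.graph.edges[ei]
        on_path.update((e.source, e.target))
    trig = set(triggers)
    return any(
        instance.graph.vertices[v].labels & trig for v in on_path
    )
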