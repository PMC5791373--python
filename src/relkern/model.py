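"""Core data types for dependency-graph relation extraction.

A sentence's dependency parse is held as a :class:`Sentence` (tokens plus
head/label edges); graph-level operations work on :class:`DepGraph`, a small
directed multigraph whose vertices carry label sets (lemmas, or the reserved
``Entity1``/``Entity2`` focus labels) and whose edges carry a dependency label
and a weight in (0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "Token",
    "Sentence",
    "Vertex",
    "Edge",
    "DepGraph",
    "EntityMention",
    "Document",
    "Provenance",
    "RelationInstance",
    "FOCUS_LABEL_E1",
    "FOCUS_LABEL_E2",
    "FOCUS_EDGE_LABEL",
    "SENTENCE_BOUNDARY_LABEL",
    "W_PATH",
    "W_DEFAULT",
]

# Reserved labels. Focus vertices mark which entity pair an instance is about;
# the sentence-boundary edge joins the roots of two merged sentence graphs.
FOCUS_LABEL_E1 = "Entity1"
FOCUS_LABEL_E2 = "Entity2"
FOCUS_EDGE_LABEL = "focus"
SENTENCE_BOUNDARY_LABEL = "SentenceBoundary"

#: Edge weight for edges on the shortest dependency path between the two
#: focus entities, and the default weight for every other edge.
W_PATH = 0.9
W_DEFAULT = 0.3


@dataclass(frozen=True)
class Token:
    """One token of a parsed sentence.

    ``index`` is the 1-based position within the sentence; ``span`` is the
    0-based half-open character range in the document text (``None`` when the
    sentence was read without offsets).
    """

    index: int
    word: str
    lemma: str
    pos: str = "_"
    span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"token index must be >= 1, got {self.index}")
        if not self.lemma:
            raise ValueError("token lemma must be non-empty")
        if self.span is not None and not self.span[0] < self.span[1]:
            raise ValueError(f"bad token span {self.span}")


@dataclass
class Sentence:
    """A parsed sentence: tokens plus dependency edges.

    ``edges`` are (head index, dependent index, label) triples with 1-based
    token indices; head 0 marks the sentence root and is kept in ``roots``
    rather than as an edge.
    """

    tokens: list[Token]
    edges: list[tuple[int, int, str]]
    roots: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.tokens)
        for h, d, lab in self.edges:
            if not (1 <= h <= n and 1 <= d <= n):
                raise ValueError(f"edge ({h},{d},{lab}) out of range for {n} tokens")
        if not self.roots and self.tokens:
            headed = {d for _, d, _ in self.edges}
            self.roots = [t.index for t in self.tokens if t.index not in headed]

    @property
    def text_tokens(self) -> list[str]:
        return [t.word for t in self.tokens]


@dataclass(frozen=True)
class Vertex:
    id: int
    labels: frozenset[str]
    kind: str = "token"  # token | edge-node | focus | dummy

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValueError("vertex label set must be non-empty")


@dataclass(frozen=True)
class Edge:
    source: int
    target: int
    label: str
    weight: float = W_DEFAULT

    def __post_init__(self) -> None:
        if not 0.0 < self.weight <= 1.0:
            raise ValueError(f"edge weight must be in (0,1], got {self.weight}")


@dataclass
class DepGraph:
    """Directed labelled dependency graph over one or two merged sentences.

    Invariants: edge endpoints exist among vertices; at most one edge per
    (source, target, label) triple; ``roots`` holds one sentence head per
    merged sentence. ``no_path`` is set by the weighting step when the two
    focus entities are disconnected.
    """

    vertices: dict[int, Vertex]
    edges: list[Edge]
    roots: list[int] = field(default_factory=list)
    no_path: bool = False

    def __post_init__(self) -> None:
        seen: set[tuple[int, int, str]] = set()
        for e in self.edges:
            if e.source not in self.vertices or e.target not in self.vertices:
                raise ValueError(f"edge {e} references unknown vertex")
            key = (e.source, e.target, e.label)
            if key in seen:
                raise ValueError(f"duplicate edge {key}")
            seen.add(key)

    # -- helpers -----------------------------------------------------------
    def copy(self) -> "DepGraph":
        return DepGraph(dict(self.vertices), list(self.edges), list(self.roots), self.no_path)

    def undirected_adjacency(self) -> dict[int, list[tuple[int, int, bool]]]:
        """Adjacency as ``vertex -> [(neighbour, edge index, forward?)]``.

        Neighbour lists are sorted by (neighbour id, edge index) so that
        breadth-first traversals are deterministic. ``forward`` is True when
        the edge is traversed source -> target.
        """
        adj: dict[int, list[tuple[int, int, bool]]] = {v: [] for v in self.vertices}
        for i, e in enumerate(self.edges):
            adj[e.source].append((e.target, i, True))
            adj[e.target].append((e.source, i, False))
        for v in adj:
            adj[v].sort()
        return adj

    def labels(self) -> set[str]:
        out: set[str] = set()
        for v in self.vertices.values():
            out |= v.labels
        return out

    def vertex_with_label(self, label: str) -> int | None:
        """Lowest-id vertex bearing ``label`` (duplicate-label policy)."""
        ids = [v.id for v in self.vertices.values() if label in v.labels]
        return min(ids) if ids else None

    def with_edge_weights(self, weights: dict[int, float]) -> "DepGraph":
        """New graph with edge ``i`` reweighted to ``weights[i]`` (others kept)."""
        edges = [
            replace(e, weight=weights.get(i, e.weight)) for i, e in enumerate(self.edges)
        ]
        return DepGraph(dict(self.vertices), edges, list(self.roots), self.no_path)


@dataclass
class EntityMention:
    """A gold entity mention: concept id, type, and character span(s)."""

    mention_id: str
    concept_id: str
    entity_type: str
    spans: list[tuple[int, int]]
    sentence_index: int = -1
    head_token_index: int = -1
    text: str = ""


@dataclass
class Document:
    """A title+abstract document with parses, mentions and gold relations.

    ``candidate_pairs`` restricts the candidate concept-pair universe (as the
    PPI corpora do, pair by pair); when ``None`` every Chemical concept x
    Disease concept combination is a candidate, the CDR convention.
    """

    doc_id: str
    text: str
    sentences: list[Sentence]
    sentence_spans: list[tuple[int, int]]
    entities: list[EntityMention]
    gold_relations: set[tuple[str, str]] = field(default_factory=set)
    candidate_pairs: list[tuple[str, str, str]] | None = None  # (c1, c2, label)


@dataclass(frozen=True)
class Provenance:
    doc_id: str
    pair: tuple[str, str]
    sentence_indices: tuple[int, ...]


@dataclass
class RelationInstance:
    """One classification example: a focused, weighted dependency graph.

    ``linear_tokens`` carries the token lemma sequence (in document order,
    concatenated across the two sentences for cross-level instances) together
    with the positions of the two focus mentions, which the all-path graph
    kernel needs to build its linear-order subgraph.
    """

    graph: DepGraph
    focus: tuple[int, int]
    label: str  # positive | negative
    level: str  # sentence | cross
    provenance: Provenance
    linear_tokens: list[str] = field(default_factory=list)
    e1_positions: frozenset[int] = frozenset()
    e2_positions: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        for v in self.focus:
            if v not in self.graph.vertices:
                raise ValueError(f"focus vertex {v} not in graph")
        if self.label not in ("positive", "negative"):
            raise ValueError(f"bad label {self.label!r}")
        if self.level not in ("sentence", "cross"):
            raise ValueError(f"bad level {self.level!r}")
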