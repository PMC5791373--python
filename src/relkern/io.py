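"""Readers and writers for the standard interchange formats.

Three formats are supported:

* CoNLL-U (10-column) for dependency-parsed sentences. When the DEPS column
  is present its enhanced edge set is used for the whole sentence (enhanced
  dependency graphs may contain undirected cycles); otherwise the basic
  HEAD/DEPREL tree is used. Token character offsets round-trip through the
  MISC column as ``SpanStart=..|SpanEnd=..``.
* The unified PPI corpus XML dialect (corpus > document > sentence > entity /
  pair, with bundled tokenization and dependency elements), as distributed
  for AIMed, BioInfer, HPRD50, IEPA and LLL. charOffset ends are inclusive in
  that dialect and are converted to 0-based half-open spans internally.
* PubTator-style tab-separated document annotations (title/abstract lines,
  mention lines with document-level offsets and concept ids, and relation
  lines ``CID<TAB>chemical<TAB>disease``) for CDR-like corpora.
"""

from __future__ import annotations

import io as _stdio
from typing import Iterable, TextIO

from lxml import etree

from .model import Document, EntityMention, Sentence, Token

__all__ = [
    "ConlluError",
    "read_conllu",
    "read_conllu_grouped",
    "write_conllu",
    "read_ppi_xml",
    "read_pubtator",
    "write_pubtator",
    "resolve_mention_positions",
]


class ConlluError(ValueError):
    """Malformed CoNLL-U input; the message names the offending line."""


def _as_stream(stream: TextIO | str) -> TextIO:
    if isinstance(stream, str):
        return _stdio.StringIO(stream)
    return stream


def _parse_misc_span(misc: str) -> tuple[int, int] | None:
    start = end = None
    for part in misc.split("|"):
        if part.startswith("SpanStart="):
            start = int(part[len("SpanStart=") :])
        elif part.startswith("SpanEnd="):
            end = int(part[len("SpanEnd=") :])
    if start is None or end is None:
        return None
    return (start, end)


def _check_acyclic_heads(heads: dict[int, int], lineno: int) -> None:
    for start in heads:
        seen = set()
        cur = start
        while cur != 0:
            if cur in seen:
                raise ConlluError(
                    f"cyclic HEAD chain involving token {start} (sentence ending near line {lineno})"
                )
            seen.add(cur)
            cur = heads.get(cur, 0)


def _finish_sentence(
    rows: list[tuple[int, list[str]]], lineno: int
) -> Sentence:
    tokens: list[Token] = []
    heads: dict[int, int] = {}
    basic: list[tuple[int, int, str]] = []
    enhanced: list[tuple[int, int, str]] = []
    enhanced_roots: list[int] = []
    has_deps = False
    for ln, cols in rows:
        idx = int(cols[0])
        misc = cols[9] if len(cols) > 9 else "_"
        tokens.append(
            Token(
                index=idx,
                word=cols[1],
                lemma=cols[2].lower() if cols[2] != "_" else cols[1].lower(),
                pos=cols[3],
                span=_parse_misc_span(misc),
            )
        )
        head_col, deprel, deps = cols[6], cols[7], cols[8]
        if head_col != "_":
            head = int(head_col)
            heads[idx] = head
            if head > 0:
                basic.append((head, idx, deprel))
        if deps != "_":
            has_deps = True
            for item in deps.split("|"):
                h_str, _, rel = item.partition(":")
                h = int(h_str)
                if h == 0:
                    enhanced_roots.append(idx)
                else:
                    enhanced.append((h, idx, rel))
    _check_acyclic_heads(heads, lineno)
    if has_deps:
        sent = Sentence(tokens=tokens, edges=enhanced, roots=enhanced_roots or [])
    else:
        roots = [i for i, h in heads.items() if h == 0]
        sent = Sentence(tokens=tokens, edges=basic, roots=roots)
    return sent


def read_conllu(stream: TextIO | str) -> list[Sentence]:
    """Parse a CoNLL-U stream into sentences.

    Enhanced (DEPS) edges take precedence over the basic tree when present
    anywhere in a sentence; multiword-token ranges (``1-2``) and empty nodes
    (``1.1``) are skipped. A cyclic basic HEAD chain raises :class:`ConlluError`.
    """
    sentences: list[Sentence] = []
    rows: list[tuple[int, list[str]]] = []
    for lineno, raw in enumerate(_as_stream(stream), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            if rows:
                sentences.append(_finish_sentence(rows, lineno))
                rows = []
            continue
        if line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 8:
            raise ConlluError(f"line {lineno}: expected >= 8 tab-separated columns")
        if "-" in cols[0] or "." in cols[0]:
            continue  # multiword range / empty node
        try:
            int(cols[0])
            if cols[6] != "_":
                int(cols[6])
        except ValueError as exc:
            raise ConlluError(f"line {lineno}: bad numeric field ({exc})") from None
        while len(cols) < 10:
            cols.append("_")
        rows.append((lineno, cols))
    if rows:
        sentences.append(_finish_sentence(rows, lineno))
    return sentences


def read_conllu_grouped(stream: TextIO | str) -> dict[str, list[Sentence]]:
    """Like :func:`read_conllu` but grouped by ``# newdoc id = ...`` markers."""
    groups: dict[str, list[Sentence]] = {}
    current = ""
    buf: list[str] = []

    def flush() -> None:
        if buf:
            groups.setdefault(current, []).extend(read_conllu("".join(buf)))
            buf.clear()

    for raw in _as_stream(stream):
        if raw.startswith("# newdoc id ="):
            flush()
            current = raw.split("=", 1)[1].strip()
        else:
            buf.append(raw)
    flush()
    return groups


def write_conllu(sentences: Iterable[Sentence], doc_id: str | None = None) -> str:
    """Serialize sentences to CoNLL-U text (edges in the DEPS column)."""
    out: list[str] = []
    if doc_id is not None:
        out.append(f"# newdoc id = {doc_id}\n")
    for sent in sentences:
        deps_by_token: dict[int, list[str]] = {t.index: [] for t in sent.tokens}
        for h, d, lab in sent.edges:
            deps_by_token[d].append(f"{h}:{lab}")
        for r in sent.roots:
            deps_by_token[r].insert(0, "0:root")
        for t in sent.tokens:
            misc = "_"
            if t.span is not None:
                misc = f"SpanStart={t.span[0]}|SpanEnd={t.span[1]}"
            deps = "|".join(deps_by_token[t.index]) or "_"
            out.append(
                "\t".join(
                    [
                        str(t.index),
                        t.word,
                        t.lemma,
                        t.pos,
                        "_",
                        "_",
                        "_",
                        "_",
                        deps,
                        misc,
                    ]
                )
                + "\n"
            )
        out.append("\n")
    return "".join(out)


# ---------------------------------------------------------------------------
# Unified PPI corpus XML
# ---------------------------------------------------------------------------


def _split_offsets(text: str) -> list[tuple[int, int]]:
    """Parse ``a-b`` or ``a-b,c-d`` inclusive offsets into half-open spans."""
    spans = []
    for part in text.split(","):
        a, _, b = part.partition("-")
        spans.append((int(a), int(b) + 1))
    return spans


def _token_id_to_index(tid: str) -> int:
    return int(tid.lstrip("t"))


def read_ppi_xml(stream: TextIO | str | bytes) -> list[Document]:
    """Read the unified PPI XML dialect into :class:`Document` objects.

    Each annotated ``<pair>`` becomes one entry of ``candidate_pairs`` with
    the label carried by its ``interaction`` attribute; interacting pairs are
    also entered into the document's gold relation set. Entity character
    offsets are sentence-relative in the dialect and are shifted to
    document-level spans here.
    """
    if isinstance(stream, str) and stream.lstrip().startswith("<"):
        data = stream.encode()
    elif isinstance(stream, bytes):
        data = stream
    else:
        data = _as_stream(stream).read().encode()
    root = etree.fromstring(data)
    docs: list[Document] = []
    for doc_el in root.iter("document"):
        sentences: list[Sentence] = []
        spans: list[tuple[int, int]] = []
        entities: list[EntityMention] = []
        pairs: list[tuple[str, str, str]] = []
        gold: set[tuple[str, str]] = set()
        text_parts: list[str] = []
        offset = 0
        entity_ids: set[str] = set()
        for s_idx, sent_el in enumerate(doc_el.iter("sentence")):
            s_text = sent_el.get("text", "")
            s_start = offset
            s_end = offset + len(s_text)
            text_parts.append(s_text)
            spans.append((s_start, s_end))

            tokens: list[Token] = []
            for tok_el in sent_el.iter("token"):
                t_spans = _split_offsets(tok_el.get("charOffset"))
                tokens.append(
                    Token(
                        index=_token_id_to_index(tok_el.get("id")),
                        word=tok_el.get("text"),
                        lemma=tok_el.get("lemma", tok_el.get("text")).lower(),
                        pos=tok_el.get("POS", "_"),
                        span=(t_spans[0][0] + s_start, t_spans[0][1] + s_start),
                    )
                )
            tokens.sort(key=lambda t: t.index)
            edges = [
                (
                    _token_id_to_index(dep_el.get("t1")),
                    _token_id_to_index(dep_el.get("t2")),
                    dep_el.get("type"),
                )
                for dep_el in sent_el.iter("dependency")
            ]
            sentences.append(Sentence(tokens=tokens, edges=edges))

            for ent_el in sent_el.iter("entity"):
                ent_spans = [
                    (a + s_start, b + s_start)
                    for a, b in _split_offsets(ent_el.get("charOffset"))
                ]
                for a, b in ent_spans:
                    if b > s_end:
                        raise ValueError(
                            f"entity offset {ent_el.get('charOffset')} outside "
                            f"sentence {sent_el.get('id')}"
                        )
                eid = ent_el.get("id")
                entity_ids.add(eid)
                entities.append(
                    EntityMention(
                        mention_id=eid,
                        concept_id=eid,
                        entity_type=ent_el.get("type", "protein"),
                        spans=ent_spans,
                        sentence_index=s_idx,
                        text=ent_el.get("text", ""),
                    )
                )
            for pair_el in sent_el.iter("pair"):
                e1, e2 = pair_el.get("e1"), pair_el.get("e2")
                if e1 not in entity_ids or e2 not in entity_ids:
                    raise ValueError(
                        f"pair {pair_el.get('id')} references unknown entity"
                    )
                positive = pair_el.get("interaction", "False").lower() == "true"
                pairs.append((e1, e2, "positive" if positive else "negative"))
                if positive:
                    gold.add((e1, e2))
            offset = s_end + 1  # single separator between sentences
        doc = Document(
            doc_id=doc_el.get("id"),
            text=" ".join(text_parts),
            sentences=sentences,
            sentence_spans=spans,
            entities=entities,
            gold_relations=gold,
            candidate_pairs=pairs,
        )
        if sentences and all(s.tokens for s in sentences):
            resolve_mention_positions(doc)
        docs.append(doc)
    return docs


# ---------------------------------------------------------------------------
# PubTator
# ---------------------------------------------------------------------------


def read_pubtator(
    stream: TextIO | str,
    parses: dict[str, list[Sentence]] | None = None,
) -> list[Document]:
    """Read PubTator-style annotations; ``parses`` supplies dependency parses.

    ``parses`` maps document id to parsed sentences whose token spans index
    into ``title + " " + abstract``. Sentence spans are inferred from token
    spans; mentions are assigned to sentences by span containment.
    """
    docs_raw: dict[str, dict] = {}
    order: list[str] = []
    for raw in _as_stream(stream):
        line = raw.rstrip("\n")
        if not line:
            continue
        if "|t|" in line or "|a|" in line:
            pmid, kind, text = line.split("|", 2)
            if pmid not in docs_raw:
                docs_raw[pmid] = {"t": "", "a": "", "mentions": [], "relations": set()}
                order.append(pmid)
            docs_raw[pmid][kind] = text
            continue
        cols = line.split("\t")
        pmid = cols[0]
        if len(cols) >= 2 and cols[1] == "CID":
            docs_raw[pmid]["relations"].add((cols[2], cols[3]))
        elif len(cols) >= 6:
            start, end = int(cols[1]), int(cols[2])
            docs_raw[pmid]["mentions"].append(
                (start, end, cols[3], cols[4], cols[5])
            )
    documents: list[Document] = []
    for pmid in order:
        rec = docs_raw[pmid]
        text = rec["t"] + " " + rec["a"] if rec["a"] else rec["t"]
        sentences = (parses or {}).get(pmid, [])
        spans = []
        for sent in sentences:
            tok_spans = [t.span for t in sent.tokens if t.span is not None]
            if not tok_spans:
                raise ValueError(f"document {pmid}: parsed tokens lack spans")
            spans.append((min(s for s, _ in tok_spans), max(e for _, e in tok_spans)))
        entities = []
        for m_i, (start, end, m_text, m_type, concept) in enumerate(rec["mentions"]):
            entities.append(
                EntityMention(
                    mention_id=f"{pmid}.m{m_i}",
                    concept_id=concept,
                    entity_type=m_type,
                    spans=[(start, end)],
                    text=m_text,
                )
            )
        doc = Document(
            doc_id=pmid,
            text=text,
            sentences=sentences,
            sentence_spans=spans,
            entities=entities,
            gold_relations=set(rec["relations"]),
        )
        if sentences:
            resolve_mention_positions(doc)
        documents.append(doc)
    return documents


def write_pubtator(docs: Iterable[Document]) -> str:
    """Serialize documents to PubTator text (title line split at first sentence)."""
    out: list[str] = []
    for doc in docs:
        if doc.sentence_spans:
            title_end = doc.sentence_spans[0][1]
        else:
            title_end = len(doc.text)
        title = doc.text[:title_end]
        abstract = doc.text[title_end + 1 :] if title_end + 1 <= len(doc.text) else ""
        out.append(f"{doc.doc_id}|t|{title}\n")
        if abstract:
            out.append(f"{doc.doc_id}|a|{abstract}\n")
        for m in doc.entities:
            s, e = m.spans[0], m.spans[-1]
            out.append(
                f"{doc.doc_id}\t{s[0]}\t{e[1]}\t{m.text or doc.text[s[0]:e[1]]}"
                f"\t{m.entity_type}\t{m.concept_id}\n"
            )
        for c, d in sorted(doc.gold_relations):
            out.append(f"{doc.doc_id}\tCID\t{c}\t{d}\n")
        out.append("\n")
    return "".join(out)


def resolve_mention_positions(doc: Document) -> None:
    """Assign sentence index and head token to each mention, in place.

    The head token is the unique mention token whose syntactic head lies
    outside the mention; when none or several qualify the last mention token
    is used.
    """
    for mention in doc.entities:
        m_start = min(s for s, _ in mention.spans)
        m_end = max(e for _, e in mention.spans)
        sent_idx = None
        for i, (s, e) in enumerate(doc.sentence_spans):
            if s <= m_start and m_end <= e:
                sent_idx = i
                break
        if sent_idx is None:
            raise ValueError(
                f"mention {mention.mention_id} spans {mention.spans} lie outside "
                f"every sentence of document {doc.doc_id}"
            )
        mention.sentence_index = sent_idx
        sent = doc.sentences[sent_idx]
        in_mention = [
            t.index
            for t in sent.tokens
            if t.span is not None
            and any(t.span[0] < e and s < t.span[1] for s, e in mention.spans)
        ]
        if not in_mention:
            raise ValueError(
                f"mention {mention.mention_id} covers no token in document {doc.doc_id}"
            )
        head_of = {d: h for h, d, _ in sent.edges}
        member = set(in_mention)
        external = [
            i for i in in_mention if head_of.get(i, 0) not in member
        ]
        mention.head_token_index = external[0] if len(external) == 1 else in_mention[-1]
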