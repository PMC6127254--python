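"""Literature corpus I/O, boolean query filtering, and document identity.

A corpus is a line-delimited JSON file, one article per line with fields
``doc_id``, ``title``, ``abstract`` and optionally ``body`` (full text).
Documents are the unit of counting for every downstream statistic: the
background size, concept document frequencies, and sample sizes all count
documents, never mentions.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Document",
    "CorpusQuery",
    "CorpusError",
    "read_corpus",
    "write_corpus",
    "filter_by_query",
    "tokenize",
]

# Hyphen, slash and underscore act as token separators so that forms like
# "iron-overload" match the two-token term "iron overload".
_TOKEN_RE = re.compile(r"[A-Za-z0-9]+(?:\.[0-9]+)?")

# Sentence boundary: sentence-final punctuation, whitespace, then an
# uppercase letter or digit. Deliberately simple; abbreviation-aware
# segmentation is out of scope.
_SENT_RE = re.compile(r"(?<=[.!?])\s+(?=[A-Z0-9])")


class CorpusError(ValueError):
    """Raised for malformed corpus files or invariant violations."""


@dataclass(frozen=True)
class Document:
    """One article: identifier, title/abstract, optional full-text sentences."""

    doc_id: str
    title: str = ""
    abstract: str = ""
    body_sentences: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise CorpusError("Document requires a non-empty doc_id")
        object.__setattr__(self, "body_sentences", tuple(self.body_sentences))

    @property
    def has_fulltext(self) -> bool:
        return len(self.body_sentences) > 0

    @property
    def text(self) -> str:
        """Title + abstract + body as one string (document scope)."""
        parts = [self.title, self.abstract, *self.body_sentences]
        return " ".join(p for p in parts if p)

    def text_units(self) -> list[str]:
        """Units for sentence-scope co-mention: title+abstract first, then
        each body sentence."""
        head = " ".join(p for p in (self.title, self.abstract) if p)
        return [head] + list(self.body_sentences)


@dataclass(frozen=True)
class CorpusQuery:
    """Boolean retrieval query: at least one topic term AND at least one
    organism term, whole-word and case-insensitive.

    Multi-word phrases (e.g. ``homo sapiens``) match as contiguous token
    sequences.
    """

    topic_terms: frozenset[str]
    organism_terms: frozenset[str]

    def __init__(self, topic_terms: Iterable[str], organism_terms: Iterable[str]):
        topic = frozenset(t.strip().strip('"') for t in topic_terms if t.strip())
        organism = frozenset(t.strip().strip('"') for t in organism_terms if t.strip())
        if not topic or not organism:
            raise CorpusError("CorpusQuery requires non-empty topic and organism term sets")
        object.__setattr__(self, "topic_terms", topic)
        object.__setattr__(self, "organism_terms", organism)


#: The boolean query used to assemble a mutation-centric corpus from a
#: general literature repository.
DEFAULT_QUERY = CorpusQuery(
    topic_terms=[
        "mutation", "mutations", "indel", "indels", "deletion", "deletions",
        "insertion", "insertions", "mutagenesis",
    ],
    organism_terms=[
        "human", "homo sapiens", "bacterium", "bacteria", "virus", "viruses",
        "fungi", "fungus",
    ],
)


def tokenize(text: str, lower: bool = True) -> list[str]:
    toks = _TOKEN_RE.findall(text)
    return [t.lower() for t in toks] if lower else toks


def split_sentences(text: str) -> tuple[str, ...]:
    text = text.strip()
    if not text:
        return ()
    return tuple(s for s in _SENT_RE.split(text) if s.strip())


def read_corpus(path: str | Path) -> list[Document]:
    """Read a line-delimited JSON corpus.

    Raises :class:`CorpusError` on duplicate ``doc_id``, a record without a
    ``doc_id``, or unparseable lines (reported with their line number).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    docs: list[Document] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"line {lineno}: malformed record ({exc.msg})") from exc
            if not isinstance(rec, dict) or not rec.get("doc_id"):
                raise CorpusError(f"line {lineno}: record without doc_id")
            doc_id = str(rec["doc_id"])
            if doc_id in seen:
                raise CorpusError(f"line {lineno}: duplicate doc_id {doc_id!r}")
            seen.add(doc_id)
            body = rec.get("body", "")
            docs.append(
                Document(
                    doc_id=doc_id,
                    title=str(rec.get("title", "")),
                    abstract=str(rec.get("abstract", "")),
                    body_sentences=split_sentences(str(body)) if body else (),
                )
            )
    return docs


def write_corpus(docs: Iterable[Document], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for d in docs:
            rec = {"doc_id": d.doc_id, "title": d.title, "abstract": d.abstract}
            if d.body_sentences:
                rec["body"] = " ".join(d.body_sentences)
            fh.write(json.dumps(rec) + "\n")


def _contains_term(doc_tokens: Sequence[str], term: str) -> bool:
    term_toks = tokenize(term)
    if not term_toks:
        return False
    if len(term_toks) == 1:
        return term_toks[0] in doc_tokens
    n = len(term_toks)
    first = term_toks[0]
    for i, tok in enumerate(doc_tokens[: len(doc_tokens) - n + 1]):
        if tok == first and list(doc_tokens[i : i + n]) == term_toks:
            return True
    return False


def matches_query(doc: Document, q: CorpusQuery) -> bool:
    toks = tokenize(doc.text)
    tokset = toks  # list: phrase matching needs order
    has_topic = any(_contains_term(tokset, t) for t in q.topic_terms)
    if not has_topic:
        return False
    return any(_contains_term(tokset, t) for t in q.organism_terms)


def filter_by_query(docs: Iterable[Document], q: CorpusQuery) -> list[Document]:
    """Retain documents whose combined text contains >=1 topic term AND
    >=1 organism term (whole-word, case-insensitive)."""
    return [d for d in docs if matches_query(d, q)]
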