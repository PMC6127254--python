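"""Topic dictionaries and dictionary-based document annotation.

Dictionaries are tab-delimited: ``concept_id<TAB>preferred_name<TAB>
synonyms<TAB>dictionary_name`` with pipe-separated synonyms (the fourth
column optional). Annotation produces the concept -> documents postings
(the background annotation) that the enrichment stage consumes.

Matching policy
---------------
* leftmost-longest, non-overlapping spans over a token sequence;
* case-insensitive for terms of four or more characters, exact-case for
  terms of three characters or fewer (protects short gene symbols such as
  NS1 from matching prose);
* hyphen, slash and underscore are token separators;
* if several concepts claim the identical winning span (e.g. a gene and a
  disease both named NS1), all of them are posted — ambiguity is kept,
  not resolved.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .corpus import Document, _TOKEN_RE

__all__ = [
    "DictionaryEntry",
    "AnnotationIndex",
    "DictionaryError",
    "load_dictionary",
    "write_dictionary",
    "annotate",
    "brute_force_match",
]

#: terms of at most this many characters must match with exact case
SHORT_TERM_LEN = 3


class DictionaryError(ValueError):
    """Malformed dictionary file or invariant violation."""


@dataclass(frozen=True)
class DictionaryEntry:
    concept_id: str
    preferred_name: str
    synonyms: frozenset[str]
    dictionary_name: str = "default"

    def __post_init__(self) -> None:
        if not self.concept_id:
            raise DictionaryError("empty concept_id")
        if not self.preferred_name:
            raise DictionaryError(f"{self.concept_id}: empty preferred_name")
        syns = frozenset(s for s in self.synonyms if s) | {self.preferred_name}
        if any(not s for s in syns):
            raise DictionaryError(f"{self.concept_id}: empty synonym")
        object.__setattr__(self, "synonyms", syns)


@dataclass
class AnnotationIndex:
    """Concept -> document postings plus per-(concept, doc) mention counts.

    ``doc_count`` is the number of documents annotated (the background size
    |B|); ``postings[c]`` realises |C| for concept c as a document set.
    When built at sentence scope, ``unit_postings`` additionally maps each
    concept to the (doc_id, unit_index) pairs it occurs in, where unit 0 is
    title+abstract and units 1.. are full-text sentences.
    """

    postings: dict[str, set[str]] = field(default_factory=dict)
    mention_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    doc_count: int = 0
    scope: str = "document"
    dictionary_of: dict[str, str] = field(default_factory=dict)
    unit_postings: dict[str, set[tuple[str, int]]] = field(default_factory=dict)
    unit_count: int = 0

    def doc_frequency(self, concept_id: str) -> int:
        return len(self.postings.get(concept_id, ()))

    def annotated_doc_ids(self) -> set[str]:
        """Documents with at least one dictionary hit."""
        out: set[str] = set()
        for s in self.postings.values():
            out |= s
        return out


def load_dictionary(path: str | Path, dictionary_name: str | None = None) -> list[DictionaryEntry]:
    """Load one tab-delimited dictionary file.

    An empty synonyms cell yields ``synonyms == {preferred_name}``.
    Duplicate concept_id rows are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    entries: list[DictionaryEntry] = []
    seen: set[str] = set()
    default_name = dictionary_name or path.stem
    with path.open() as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise DictionaryError(f"{path.name} line {lineno}: expected >=2 columns")
            concept_id = row[0].strip()
            if concept_id in seen:
                raise DictionaryError(f"{path.name} line {lineno}: duplicate concept_id {concept_id!r}")
            seen.add(concept_id)
            preferred = row[1].strip()
            syn_cell = row[2].strip() if len(row) > 2 else ""
            synonyms = frozenset(s.strip() for s in syn_cell.split("|") if s.strip())
            dname = row[3].strip() if len(row) > 3 and row[3].strip() else default_name
            entries.append(
                DictionaryEntry(
                    concept_id=concept_id,
                    preferred_name=preferred,
                    synonyms=synonyms,
                    dictionary_name=dname,
                )
            )
    return entries


def write_dictionary(entries: Iterable[DictionaryEntry], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for e in entries:
            w.writerow([e.concept_id, e.preferred_name, "|".join(sorted(e.synonyms)), e.dictionary_name])


# ---------------------------------------------------------------------------
# Matching


def _term_tokens(term: str) -> tuple[str, ...]:
    return tuple(_TOKEN_RE.findall(term))


class _TermIndex:
    """Terms indexed by casefolded first token for leftmost-longest scan."""

    def __init__(self, entries: Iterable[DictionaryEntry]):
        # first_token(lower) -> list of (token_tuple, exact_case, concept_id)
        self.by_first: dict[str, list[tuple[tuple[str, ...], bool, str]]] = defaultdict(list)
        self.dictionary_of: dict[str, str] = {}
        n = 0
        for e in entries:
            self.dictionary_of[e.concept_id] = e.dictionary_name
            n += 1
            for syn in e.synonyms:
                toks = _term_tokens(syn)
                if not toks:
                    continue
                exact = len(syn) <= SHORT_TERM_LEN
                key = toks[0].lower()
                stored = toks if exact else tuple(t.lower() for t in toks)
                self.by_first[key].append((stored, exact, e.concept_id))
        if n == 0:
            raise DictionaryError("annotate requires at least one dictionary entry")
        # longest candidates first so the scan can stop at the first length tier
        for cands in self.by_first.values():
            cands.sort(key=lambda c: -len(c[0]))


def _scan(tokens_exact: Sequence[str], idx: _TermIndex) -> list[tuple[int, int, str]]:
    """Return (start, length, concept_id) matches, leftmost-longest,
    non-overlapping; equal-length spans at one position all posted."""
    tokens_lower = [t.lower() for t in tokens_exact]
    out: list[tuple[int, int, str]] = []
    i, n = 0, len(tokens_exact)
    while i < n:
        cands = idx.by_first.get(tokens_lower[i])
        best_len = 0
        winners: list[str] = []
        if cands:
            for stored, exact, cid in cands:
                L = len(stored)
                if best_len and L < best_len:
                    break  # sorted by length desc
                if i + L > n:
                    continue
                window = tokens_exact[i : i + L] if exact else tokens_lower[i : i + L]
                if tuple(window) == stored:
                    if L > best_len:
                        best_len, winners = L, [cid]
                    elif L == best_len and cid not in winners:
                        winners.append(cid)
        if best_len:
            for cid in winners:
                out.append((i, best_len, cid))
            i += best_len
        else:
            i += 1
    return out


def annotate(
    docs: Iterable[Document],
    entries: Iterable[DictionaryEntry],
    scope: str = "document",
) -> AnnotationIndex:
    """Annotate documents with dictionary terms.

    ``scope="document"`` indexes title+abstract+body per document;
    ``scope="sentence"`` additionally records, for each concept, the
    (doc_id, unit) pairs so that pair enrichment can require co-mention
    within one sentence of a full-text body.
    """
    if scope not in ("document", "sentence"):
        raise ValueError(f"unknown scope {scope!r}")
    entries = list(entries)
    idx = _TermIndex(entries)
    index = AnnotationIndex(scope=scope, dictionary_of=dict(idx.dictionary_of))
    for doc in docs:
        index.doc_count += 1
        if scope == "document":
            units = [doc.text]
        else:
            units = doc.text_units()
        for u, unit_text in enumerate(units):
            toks = _TOKEN_RE.findall(unit_text)
            for _start, _length, cid in _scan(toks, idx):
                index.postings.setdefault(cid, set()).add(doc.doc_id)
                key = (cid, doc.doc_id)
                index.mention_counts[key] = index.mention_counts.get(key, 0) + 1
                if scope == "sentence":
                    index.unit_postings.setdefault(cid, set()).add((doc.doc_id, u))
        if scope == "sentence":
            index.unit_count += len(units)
    return index


def brute_force_match(text: str, entries: Iterable[DictionaryEntry]) -> list[tuple[int, int, str]]:
    """Independent reference matcher: try every synonym at every token
    offset, then resolve leftmost-longest non-overlapping. Quadratic; for
    validation on short texts only."""
    tokens_exact = _TOKEN_RE.findall(text)
    tokens_lower = [t.lower() for t in tokens_exact]
    spans: list[tuple[int, int, str]] = []  # (start, length, concept)
    for e in entries:
        for syn in e.synonyms:
            toks = _term_tokens(syn)
            if not toks:
                continue
            exact = len(syn) <= SHORT_TERM_LEN
            target = toks if exact else tuple(t.lower() for t in toks)
            L = len(target)
            for i in range(len(tokens_exact) - L + 1):
                window = tokens_exact[i : i + L] if exact else tokens_lower[i : i + L]
                if tuple(window) == target:
                    spans.append((i, L, e.concept_id))
    # leftmost-longest, non-overlapping; ties on identical span all kept
    out: list[tuple[int, int, str]] = []
    pos = 0
    while spans:
        live = [s for s in spans if s[0] >= pos]
        if not live:
            break
        start = min(s[0] for s in live)
        here = [s for s in live if s[0] == start]
        best = max(s[1] for s in here)
        for s in sorted(set(here)):
            if s[1] == best:
                out.append(s)
        pos = start + best
        spans = live
    return out
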