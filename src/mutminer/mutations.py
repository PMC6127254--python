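"""Mutation mention extraction, tmVar-style normalization, cleaning, and
catalog validation.

A recognized mention is normalized to the pipe-delimited canonical form

    <seq_level>|<OPERATION>|<wild>|<position>|<mutant>

e.g. ``p|SUB|K|227|M`` (protein substitution, wild-type lysine, position
227, mutant methionine), or to ``SNP: rs<digits>`` for dbSNP identifiers.
The extractor is a rule/regex recognizer over a fixed set of surface
styles (single-letter and three-letter missense, verbose prose, DNA
substitutions, del/ins/dup/fs/delins forms, rs/ss identifiers); it is not
a full HGVS grammar.

Cleaning applies three corpus-level rules to the raw extraction: a
frequency threshold (normalized forms occurring more than 50,000 times
corpus-wide are artifacts, e.g. short patterns like "A > C"), a position
sanity rule (no alphabetic or non-positive positions), and a
field-completeness rule (a substitution must carry sequence level, wild
type, position, and mutant — a hit normalized to ``|SUB|A||`` is
deleted).
"""

from __future__ import annotations

import csv
import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .corpus import Document

__all__ = [
    "NormalizedVariant",
    "MutationMention",
    "CatalogRecord",
    "ValidationReport",
    "NormalizationError",
    "AMINO3_TO_1",
    "AMINO_NAME_TO_1",
    "extract_mentions",
    "normalize_mention",
    "parse_normalized_form",
    "clean_mentions",
    "validate_against_catalog",
    "read_catalog",
    "read_mention_table",
    "write_mention_table",
    "DEFAULT_FREQ_THRESHOLD",
]

DEFAULT_FREQ_THRESHOLD = 50_000

AMINO3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "TER": "*", "STOP": "*",
}

AMINO_NAME_TO_1 = {
    "alanine": "A", "arginine": "R", "asparagine": "N", "aspartate": "D",
    "aspartic acid": "D", "cysteine": "C", "glutamine": "Q", "glutamate": "E",
    "glutamic acid": "E", "glycine": "G", "histidine": "H", "isoleucine": "I",
    "leucine": "L", "lysine": "K", "methionine": "M", "phenylalanine": "F",
    "proline": "P", "serine": "S", "threonine": "T", "tryptophan": "W",
    "tyrosine": "Y", "valine": "V",
}

_CATEGORY_OF_OP = {
    "SUB": "Substitution",
    "DEL": "Deletion",
    "INS": "Insertion",
    "DUP": "Duplication",
    "INDEL": "InDels",
    "FS": "Frameshift",
}


class NormalizationError(ValueError):
    """Surface form matched no recognized pattern or has an unmappable residue."""


@dataclass(frozen=True)
class NormalizedVariant:
    """Canonical variant tuple; serialized as level|OP|wild|pos|mutant.

    ``position`` is kept as a string so that malformed values read from
    external mention tables (alphabetic or negative positions) survive to
    the cleaning stage, where they are rejected. ``span_end`` records the
    end of a positional range (e.g. 76_77); the serialized form shows the
    start only.
    """

    seq_level: str = ""         # "c" (DNA) or "p" (protein), may be empty
    operation: str = ""         # SUB, DEL, INS, DUP, FS, INDEL
    wild: str = ""
    position: str = ""
    mutant: str = ""
    rs_id: str = ""             # "rs<digits>" / "ss<digits>"; excludes tuple fields
    span_end: str = field(default="", compare=False)

    def serialize(self) -> str:
        if self.rs_id:
            return f"SNP: {self.rs_id}"
        return f"{self.seq_level}|{self.operation}|{self.wild}|{self.position}|{self.mutant}"

    @property
    def category(self) -> str:
        if self.rs_id:
            return "SNP"
        return _CATEGORY_OF_OP.get(self.operation, "Unknown")

    def position_ok(self) -> bool:
        return bool(re.fullmatch(r"[0-9]+", self.position)) and int(self.position) > 0

    def comparison_key(self) -> tuple:
        """Key for catalog/annotation matching: rs id, or the
        (operation, wild, position, mutant) tuple."""
        if self.rs_id:
            return ("RS", self.rs_id.lower())
        return (self.operation, self.wild.upper(), self.position, self.mutant.upper())


@dataclass(frozen=True)
class MutationMention:
    doc_id: str
    surface: str
    count: int
    variant: NormalizedVariant

    @property
    def category(self) -> str:
        return self.variant.category


def parse_normalized_form(form: str) -> NormalizedVariant:
    """Parse a serialized form back to a variant (round-trip inverse of
    :meth:`NormalizedVariant.serialize`). Malformed field values are kept
    verbatim for the cleaning stage to reject."""
    form = form.strip()
    m = re.fullmatch(r"SNP:\s*((?:rs|ss)[0-9]+)", form, re.IGNORECASE)
    if m:
        return NormalizedVariant(rs_id=m.group(1).lower())
    parts = form.split("|")
    if len(parts) != 5:
        raise NormalizationError(f"cannot parse normalized form {form!r}")
    level, op, wild, pos, mut = (p.strip() for p in parts)
    return NormalizedVariant(seq_level=level, operation=op.upper(), wild=wild,
                             position=pos, mutant=mut)


# ---------------------------------------------------------------------------
# Surface patterns.  Order matters: more specific (longer) patterns first so
# that e.g. "c.76_78delinsTT" is not consumed as a deletion.

_AA1 = "ACDEFGHIKLMNPQRSTVWY"
_AA3 = "|".join(AMINO3_TO_1)
_NAME = "|".join(sorted(AMINO_NAME_TO_1, key=len, reverse=True))

def _aa3(code: str) -> str:
    try:
        return AMINO3_TO_1[code.upper()]
    except KeyError:
        raise NormalizationError(f"unmappable residue name {code!r}") from None


def _aaname(name: str) -> str:
    try:
        return AMINO_NAME_TO_1[name.lower()]
    except KeyError:
        raise NormalizationError(f"unmappable residue name {name!r}") from None


# Each entry: (style, compiled regex, builder taking the match object).
_PATTERNS: list[tuple[str, re.Pattern, object]] = []


def _pattern(style: str, pattern: str):
    def reg(fn):
        _PATTERNS.append((style, re.compile(pattern), fn))
        return fn
    return reg


@_pattern("rsid", r"\b(rs|ss|RS|SS|Rs|Ss)\s?([0-9]+)\b")
def _p_rsid(m):
    return NormalizedVariant(rs_id=m.group(1).lower() + m.group(2))


@_pattern("dna_delins", r"\bc\.([0-9]+)(?:_([0-9]+))?delins([ACGT]+)\b")
def _p_dna_delins(m):
    return NormalizedVariant(seq_level="c", operation="INDEL", position=m.group(1),
                             mutant=m.group(3), span_end=m.group(2) or "")


@_pattern("dna_ins", r"\bc\.([0-9]+)(?:_([0-9]+))?ins([ACGT]+)\b")
def _p_dna_ins(m):
    return NormalizedVariant(seq_level="c", operation="INS", position=m.group(1),
                             mutant=m.group(3), span_end=m.group(2) or "")


@_pattern("dna_dup", r"\bc\.([0-9]+)(?:_([0-9]+))?dup([ACGT]*)\b")
def _p_dna_dup(m):
    return NormalizedVariant(seq_level="c", operation="DUP", wild=m.group(3),
                             position=m.group(1), span_end=m.group(2) or "")


@_pattern("dna_del", r"\bc\.([0-9]+)(?:_([0-9]+))?del([ACGT]*)\b")
def _p_dna_del(m):
    return NormalizedVariant(seq_level="c", operation="DEL", wild=m.group(3),
                             position=m.group(1), span_end=m.group(2) or "")


@_pattern("dna_sub", r"\b(?:c\.)?([0-9]+)\s?([ACGT])\s?(?:>|->|-->|→)\s?([ACGT])\b")
def _p_dna_sub(m):
    return NormalizedVariant(seq_level="c", operation="SUB", wild=m.group(2),
                             position=m.group(1), mutant=m.group(3))


# Positionless substitution artifact ("A > C"): normalizes with an empty
# position field, exactly the kind of hit the cleaning stage deletes.
@_pattern("dna_sub_nopos", r"(?<![0-9A-Za-z])([ACGT])\s?(?:>|->|-->|→)\s?([ACGT])(?![0-9A-Za-z])")
def _p_dna_sub_nopos(m):
    return NormalizedVariant(seq_level="", operation="SUB", wild=m.group(1),
                             position="", mutant=m.group(2))


@_pattern("protein_fs3", rf"\b(?:p\.)?((?i:{_AA3}))([0-9]+)fs(?:\*|Ter)?[0-9]*\b")
def _p_fs3(m):
    return NormalizedVariant(seq_level="p", operation="FS", wild=_aa3(m.group(1)),
                             position=m.group(2))


@_pattern("protein_fs1", rf"\b(?:p\.)?([{_AA1}])([0-9]+)fs(?:\*|Ter)?[0-9]*\b")
def _p_fs1(m):
    return NormalizedVariant(seq_level="p", operation="FS", wild=m.group(1),
                             position=m.group(2))


@_pattern("protein_del3", rf"\b(?:p\.)?((?i:{_AA3}))([0-9]+)del\b")
def _p_del3(m):
    return NormalizedVariant(seq_level="p", operation="DEL", wild=_aa3(m.group(1)),
                             position=m.group(2))


@_pattern("protein_del1", rf"\b(?:p\.)?([{_AA1}])([0-9]+)del\b")
def _p_del1(m):
    return NormalizedVariant(seq_level="p", operation="DEL", wild=m.group(1),
                             position=m.group(2))


@_pattern("protein_del_prefix", rf"\bdel([{_AA1}])([0-9]+)\b")
def _p_del_prefix(m):
    return NormalizedVariant(seq_level="p", operation="DEL", wild=m.group(1),
                             position=m.group(2))


@_pattern("protein_ins3", rf"\b(?:p\.)?((?i:{_AA3}))([0-9]+)_((?i:{_AA3}))([0-9]+)ins((?i:(?:{_AA3})+))\b")
def _p_ins3(m):
    mut = "".join(_aa3(m.group(5)[i:i + 3]) for i in range(0, len(m.group(5)), 3))
    return NormalizedVariant(seq_level="p", operation="INS", position=m.group(2),
                             mutant=mut, span_end=m.group(4))


@_pattern("protein_missense3", rf"\b(?:p\.)?((?i:{_AA3}))\s?([0-9]+)\s?((?i:{_AA3}))\b")
def _p_mis3(m):
    return NormalizedVariant(seq_level="p", operation="SUB", wild=_aa3(m.group(1)),
                             position=m.group(2), mutant=_aa3(m.group(3)))


@_pattern("protein_missense1", rf"\b(?:p\.)?([{_AA1}])([0-9]+)([{_AA1}])\b")
def _p_mis1(m):
    return NormalizedVariant(seq_level="p", operation="SUB", wild=m.group(1),
                             position=m.group(2), mutant=m.group(3))


@_pattern(
    "verbose",
    rf"\b((?i:{_NAME}))\s+(?:to|for|into)\s+((?i:{_NAME}))\s+(?:at|in)\s+"
    rf"(?:position|codon|residue|amino\s+acid)\s+([0-9]+)\b",
)
def _p_verbose(m):
    return NormalizedVariant(seq_level="p", operation="SUB", wild=_aaname(m.group(1)),
                             position=m.group(3), mutant=_aaname(m.group(2)))


_STYLES = tuple(s for s, _, _ in _PATTERNS)


def scan_text(text: str) -> list[tuple[str, NormalizedVariant]]:
    """Scan text with every pattern; overlapping matches are resolved in
    pattern-priority order (specific before generic), then left to right."""
    hits: list[tuple[int, int, int, str, NormalizedVariant]] = []
    for prio, (style, rx, fn) in enumerate(_PATTERNS):
        for m in rx.finditer(text):
            try:
                var = fn(m)
            except NormalizationError:
                continue
            hits.append((m.start(), m.end(), prio, m.group(0), var))
    # priority first so e.g. rs-ids beat the 1-letter missense pattern,
    # then leftmost
    hits.sort(key=lambda h: (h[2], h[0], -(h[1] - h[0])))
    taken: list[tuple[int, int]] = []
    out: list[tuple[int, str, NormalizedVariant]] = []
    for start, end, _prio, surface, var in hits:
        if any(start < e and s < end for s, e in taken):
            continue
        taken.append((start, end))
        out.append((start, surface, var))
    out.sort(key=lambda h: h[0])
    return [(surface, var) for _s, surface, var in out]


def normalize_mention(surface: str) -> NormalizedVariant:
    """Normalize a single surface mention; raises
    :class:`NormalizationError` if no pattern covers the whole string."""
    surface = surface.strip()
    for style, rx, fn in _PATTERNS:
        m = rx.fullmatch(surface)
        if m:
            return fn(m)
    # fall back: a scan that covers the string up to surrounding context
    hits = scan_text(surface)
    if len(hits) == 1:
        return hits[0][1]
    raise NormalizationError(f"unrecognized mutation mention {surface!r}")


def extract_mentions(doc: Document) -> list[MutationMention]:
    """Extract all recognized mutation mentions from a document, aggregating
    counts per identical normalized form."""
    per_form: dict[str, int] = Counter()
    first_surface: dict[str, str] = {}
    variant_of: dict[str, NormalizedVariant] = {}
    for surface, var in scan_text(doc.text):
        key = var.serialize()
        per_form[key] += 1
        first_surface.setdefault(key, surface)
        variant_of.setdefault(key, var)
    return [
        MutationMention(doc_id=doc.doc_id, surface=first_surface[k],
                        count=c, variant=variant_of[k])
        for k, c in per_form.items()
    ]


# ---------------------------------------------------------------------------
# Cleaning

_REQUIRED_FIELDS = {
    # operation -> fields that must be non-empty
    "SUB": ("seq_level", "wild", "position", "mutant"),
    "DEL": ("seq_level", "position"),
    "DUP": ("seq_level", "position"),
    "INS": ("seq_level", "position", "mutant"),
    "FS": ("seq_level", "wild", "position"),
    "INDEL": ("seq_level", "position", "mutant"),
}

REASON_FREQUENCY = "frequency_threshold"
REASON_POSITION = "invalid_position"
REASON_FIELDS = "missing_fields"


def _rule_violation(var: NormalizedVariant) -> str | None:
    """Position and field-completeness rules (frequency is corpus-level)."""
    if var.rs_id:
        return None
    required = _REQUIRED_FIELDS.get(var.operation)
    if required is None:
        return REASON_FIELDS
    if any(not getattr(var, f) for f in required):
        return REASON_FIELDS
    if not var.position_ok():
        return REASON_POSITION
    return None


def clean_mentions(
    mentions: Iterable[MutationMention],
    freq_threshold: int = DEFAULT_FREQ_THRESHOLD,
) -> tuple[list[MutationMention], list[tuple[MutationMention, str]]]:
    """Partition mentions into (kept, rejected-with-reason).

    Rejection rules, applied in order per mention:

    1. ``frequency_threshold`` — the normalized form occurs more than
       ``freq_threshold`` times corpus-wide (summed mention counts);
    2. ``invalid_position`` — alphabetic or non-positive position;
    3. ``missing_fields`` — a required field for the operation is empty
       (a substitution needs sequence level, wild type, position, mutant).
    """
    mentions = list(mentions)
    form_freq: Counter[str] = Counter()
    for m in mentions:
        form_freq[m.variant.serialize()] += m.count
    kept: list[MutationMention] = []
    rejected: list[tuple[MutationMention, str]] = []
    for m in mentions:
        if form_freq[m.variant.serialize()] > freq_threshold:
            rejected.append((m, REASON_FREQUENCY))
            continue
        reason = _rule_violation(m.variant)
        if reason == REASON_FIELDS:
            rejected.append((m, REASON_FIELDS))
        elif reason == REASON_POSITION:
            rejected.append((m, REASON_POSITION))
        else:
            kept.append(m)
    return kept, rejected


# ---------------------------------------------------------------------------
# Catalog validation


@dataclass(frozen=True)
class CatalogRecord:
    """One row of a variant catalog (dbSNP/ClinVar-like export)."""

    rs_id: str = ""
    seq_level: str = ""
    operation: str = ""
    wild: str = ""
    position: str = ""
    mutant: str = ""


@dataclass
class ValidationReport:
    n_rs: int = 0
    n_rs_validated: int = 0
    n_other: int = 0
    n_other_validated: int = 0

    @property
    def n_total_validated(self) -> int:
        return self.n_rs_validated + self.n_other_validated

    @property
    def rs_fraction(self) -> float | None:
        return self.n_rs_validated / self.n_rs if self.n_rs else None

    @property
    def other_fraction(self) -> float | None:
        return self.n_other_validated / self.n_other if self.n_other else None


def read_catalog(path: str | Path) -> list[CatalogRecord]:
    """Tab-delimited catalog: rs_id, seq_level, operation, wild, position,
    mutant (header row optional, detected on the first column name)."""
    out: list[CatalogRecord] = []
    with Path(path).open() as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].strip().lower() == "rs_id":
                continue
            row = (row + [""] * 6)[:6]
            out.append(CatalogRecord(*[c.strip() for c in row]))
    return out


def validate_against_catalog(
    kept: Iterable[MutationMention],
    catalog: Iterable[CatalogRecord],
) -> tuple[list[MutationMention], ValidationReport]:
    """Validate mentions against a variant catalog.

    rs-mentions validate iff the rs id is present; other mentions validate
    iff the (operation, wild, position, mutant) tuple matches a catalog
    row. The report gives validated fractions per class.
    """
    catalog = list(catalog)
    rs_set = {c.rs_id.lower() for c in catalog if c.rs_id}
    tuple_set = {
        (c.operation.upper(), c.wild.upper(), c.position, c.mutant.upper())
        for c in catalog
        if c.operation
    }
    if not catalog:
        warnings.warn("empty variant catalog: nothing can validate", stacklevel=2)
    report = ValidationReport()
    validated: list[MutationMention] = []
    for m in kept:
        v = m.variant
        if v.rs_id:
            report.n_rs += 1
            if v.rs_id.lower() in rs_set:
                report.n_rs_validated += 1
                validated.append(m)
        else:
            report.n_other += 1
            key = (v.operation, v.wild.upper(), v.position, v.mutant.upper())
            if key in tuple_set:
                report.n_other_validated += 1
                validated.append(m)
    return validated, report


# ---------------------------------------------------------------------------
# Mention table I/O (PMID, Mutation Mention, Count, Normalized Form, Type)

_MENTION_HEADER = ["PMID", "Mutation Mention", "Count", "Normalized Form", "Type"]


def write_mention_table(mentions: Iterable[MutationMention], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_MENTION_HEADER)
        for m in mentions:
            w.writerow([m.doc_id, m.surface, m.count, m.variant.serialize(), m.category])


def read_mention_table(path: str | Path) -> list[MutationMention]:
    out: list[MutationMention] = []
    with Path(path).open() as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].strip() in ("PMID", ""):
                continue
            doc_id, surface, count, form = row[0], row[1], row[2], row[3]
            out.append(
                MutationMention(
                    doc_id=doc_id.strip(),
                    surface=surface,
                    count=int(count),
                    variant=parse_normalized_form(form),
                )
            )
    return out
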