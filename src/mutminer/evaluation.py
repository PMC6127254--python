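"""Comparison of two mutation annotations and curation-precision arithmetic.

Two extraction systems rarely agree on the delimiters of a mention, so
comparison happens at the level of normalized variants: every annotation
row is mapped to a :class:`CanonicalHit` keyed by (document, level, key)
where the level is RS / DNA / PROTEIN, and the key is the rs identifier
or the (wild, position, mutant) tuple. Hits are then partitioned into
A-only / common / B-only per (level, category) row, and precision, recall
and F-measure are computed under three reference conventions:

* ``union_reference`` — every hit from either system is a positive:
  TP = |A|, FP = 0, FN = |B-only|;
* ``intersection_reference`` — only agreed hits are positives:
  TP = common, FP = |A-only|, FN = 0;
* ``b_as_reference`` — system B is ground truth:
  TP = common, FP = |A-only|, FN = |B-only|.

Percentages are reported rounded half-up to integers (two decimals for
curation precision).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .mutations import AMINO3_TO_1, NormalizedVariant, parse_normalized_form

__all__ = [
    "CanonicalHit",
    "ComparisonResult",
    "Metrics",
    "CurationRow",
    "canonicalize",
    "canonicalize_pipe_row",
    "canonicalize_emu_row",
    "compare_annotations",
    "metrics_for_case",
    "curation_precision",
    "novelty_vs_reference",
    "read_curation_table",
    "pct",
]

_CATEGORY_OF_OP = {"SUB": "missense", "DEL": "indel", "INS": "indel",
                   "DUP": "indel", "INDEL": "indel", "FS": "FS"}

#: Table rows in presentation order
ROW_ORDER = [
    ("DNA", "indel"), ("DNA", "missense"),
    ("PROTEIN", "indel"), ("PROTEIN", "missense"), ("PROTEIN", "FS"),
    ("RS", None),
]


def pct(x: float, decimals: int = 0) -> float:
    """Percentage with half-up rounding (the convention used throughout)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x * 100)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CanonicalHit:
    doc_id: str
    level: str              # RS | DNA | PROTEIN
    category: str | None    # missense | indel | FS; None for RS
    key: tuple

    def identity(self) -> tuple:
        """Set identity for comparison: (doc, level, key)."""
        return (self.doc_id, self.level, self.key)


def _variant_to_hit(doc_id: str, var: NormalizedVariant) -> CanonicalHit:
    if var.rs_id:
        return CanonicalHit(doc_id=doc_id, level="RS", category=None,
                            key=(var.rs_id.lower(),))
    level = {"c": "DNA", "p": "PROTEIN"}.get(var.seq_level, var.seq_level.upper() or "DNA")
    category = _CATEGORY_OF_OP.get(var.operation, "missense")
    return CanonicalHit(doc_id=doc_id, level=level, category=category,
                        key=(var.wild.upper(), var.position, var.mutant.upper()))


def canonicalize_pipe_row(row: Sequence[str] | Mapping[str, str]) -> CanonicalHit:
    """Canonicalize a pipe-form annotation row
    (PMID, Mutation Mention, Count, Normalized Form, Type)."""
    if isinstance(row, Mapping):
        doc_id, form = str(row["PMID"]), row["Normalized Form"]
    else:
        doc_id, form = str(row[0]), str(row[3])
    return _variant_to_hit(doc_id, parse_normalized_form(form))


_EMU_CONCAT3 = re.compile(r"^([A-Z]{3})([A-Z]{3})([0-9]+)$")
_EMU_SINGLE = re.compile(r"^([A-Z])([0-9]+)([A-Z])$")
_EMU_DNA = re.compile(r"^([0-9]+)([ACGT])>?([ACGT])$")
_EMU_RS = re.compile(r"^(rs|ss)([0-9]+)$", re.IGNORECASE)


def canonicalize_emu_row(row: Sequence[str] | Mapping[str, str]) -> CanonicalHit:
    """Canonicalize a concatenated-residue annotation row
    (PMID, Mutation, Level, Type, Mention, Position).

    The wild/mutant order in concatenated forms is wild-then-mutant:
    SERGLY325 denotes serine (wild) to glycine (mutant) at position 325.
    """
    if isinstance(row, Mapping):
        doc_id = str(row["PMID"])
        mutation = row["Mutation"].strip()
        level = row.get("Level", "").strip().upper()
        mtype = row.get("Type", "").strip().upper()
    else:
        doc_id = str(row[0])
        mutation = str(row[1]).strip()
        level = str(row[2]).strip().upper() if len(row) > 2 else ""
        mtype = str(row[3]).strip().upper() if len(row) > 3 else ""

    m = _EMU_RS.match(mutation)
    if m or mtype == "RSID":
        if not m:
            raise ValueError(f"unparseable rs identifier {mutation!r}")
        return CanonicalHit(doc_id=doc_id, level="RS", category=None,
                            key=(m.group(1).lower() + m.group(2),))
    category = {"MISSENSE": "missense", "INDEL": "indel", "FS": "FS"}.get(mtype)
    m = _EMU_CONCAT3.match(mutation)
    if m:
        wild = AMINO3_TO_1.get(m.group(1))
        mut = AMINO3_TO_1.get(m.group(2))
        if wild is None or mut is None:
            raise ValueError(f"unmappable residues in {mutation!r}")
        return CanonicalHit(doc_id=doc_id, level=level or "PROTEIN",
                            category=category or "missense",
                            key=(wild, m.group(3), mut))
    m = _EMU_SINGLE.match(mutation)
    if m:
        return CanonicalHit(doc_id=doc_id, level=level or "PROTEIN",
                            category=category or "missense",
                            key=(m.group(1), m.group(2), m.group(3)))
    m = _EMU_DNA.match(mutation)
    if m:
        return CanonicalHit(doc_id=doc_id, level="DNA",
                            category=category or "missense",
                            key=(m.group(2), m.group(1), m.group(3)))
    raise ValueError(f"unparseable annotation row {mutation!r}")


def canonicalize(row, layout: str = "pipe") -> CanonicalHit:
    """Dispatch on annotation layout: ``pipe`` (pipe-delimited normalized forms) or
    ``emu`` (concatenated residue forms)."""
    if layout == "pipe":
        return canonicalize_pipe_row(row)
    if layout == "emu":
        return canonicalize_emu_row(row)
    raise ValueError(f"unknown layout {layout!r}")


@dataclass
class ComparisonResult:
    """Per-(level, category) partition of two canonicalized hit sets."""

    rows: dict[tuple, dict[str, int]] = field(default_factory=dict)

    @classmethod
    def from_hits(cls, a: Iterable[CanonicalHit], b: Iterable[CanonicalHit]) -> "ComparisonResult":
        a_map = {h.identity(): h for h in a}
        b_map = {h.identity(): h for h in b}
        res = cls()

        def bump(h: CanonicalHit, col: str) -> None:
            row = (h.level, h.category if h.level != "RS" else None)
            res.rows.setdefault(row, {"a_only": 0, "common": 0, "b_only": 0})[col] += 1

        for ident, h in a_map.items():
            bump(h, "common" if ident in b_map else "a_only")
        for ident, h in b_map.items():
            if ident not in a_map:
                bump(h, "b_only")
        return res

    @classmethod
    def from_totals(cls, a_only: int, common: int, b_only: int,
                    row: tuple = ("ALL", None)) -> "ComparisonResult":
        """Build a result directly from printed grand totals."""
        res = cls()
        res.rows[row] = {"a_only": a_only, "common": common, "b_only": b_only}
        return res

    def _total(self, col: str) -> int:
        return sum(r[col] for r in self.rows.values())

    @property
    def a_only(self) -> int:
        return self._total("a_only")

    @property
    def common(self) -> int:
        return self._total("common")

    @property
    def b_only(self) -> int:
        return self._total("b_only")

    @property
    def a_total(self) -> int:
        return self.a_only + self.common

    @property
    def b_total(self) -> int:
        return self.b_only + self.common

    @property
    def union_total(self) -> int:
        return self.a_only + self.common + self.b_only

    def as_table(self) -> list[dict]:
        """Rows in presentation order plus a grand-total row."""
        out = []
        ordered = [r for r in ROW_ORDER if r in self.rows]
        ordered += [r for r in sorted(self.rows, key=repr) if r not in ROW_ORDER]
        for row in ordered:
            c = self.rows[row]
            out.append({
                "level": row[0], "category": row[1] or "",
                "a_total": c["a_only"] + c["common"], **c,
                "b_total": c["b_only"] + c["common"],
                "union": c["a_only"] + c["common"] + c["b_only"],
            })
        out.append({
            "level": "Total", "category": "",
            "a_total": self.a_total, "a_only": self.a_only, "common": self.common,
            "b_only": self.b_only, "b_total": self.b_total, "union": self.union_total,
        })
        return out


def compare_annotations(a: Iterable[CanonicalHit], b: Iterable[CanonicalHit]) -> ComparisonResult:
    """Set-based partition of two canonicalized annotations into
    a-only / common / b-only, per (level, category) row."""
    return ComparisonResult.from_hits(a, b)


@dataclass(frozen=True)
class Metrics:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float | None:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else None

    @property
    def recall(self) -> float | None:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else None

    @property
    def f_measure(self) -> float | None:
        p, r = self.precision, self.recall
        if p is None or r is None or (p + r) == 0:
            return None
        return 2 * p * r / (p + r)

    @property
    def precision_pct(self) -> float | None:
        return None if self.precision is None else pct(self.precision)

    @property
    def recall_pct(self) -> float | None:
        return None if self.recall is None else pct(self.recall)

    @property
    def f_measure_pct(self) -> float | None:
        return None if self.f_measure is None else pct(self.f_measure)


def metrics_for_case(cmp: ComparisonResult, case: str) -> Metrics:
    """TP/FP/FN under one of the three reference conventions (see module
    docstring); undefined ratios are reported as None, never 0."""
    if case == "union_reference":
        return Metrics(tp=cmp.a_total, fp=0, fn=cmp.b_only)
    if case == "intersection_reference":
        return Metrics(tp=cmp.common, fp=cmp.a_only, fn=0)
    if case == "b_as_reference":
        return Metrics(tp=cmp.common, fp=cmp.a_only, fn=cmp.b_only)
    raise ValueError(f"unknown case {case!r}")


# ---------------------------------------------------------------------------
# Curation precision and novelty


@dataclass(frozen=True)
class CurationRow:
    variant_key: str
    disease: str
    correct: bool           # False encodes the curators' N/A verdict
    n_support: int          # number of supporting publications

    @property
    def association(self) -> tuple[str, str]:
        return (self.variant_key, self.disease)


def read_curation_table(path: str | Path) -> list[CurationRow]:
    """Tab-delimited: variant, disease, correct_flag, supporting_pmids
    (pipe-separated PMIDs or a bare count)."""
    out: list[CurationRow] = []
    with Path(path).open() as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].strip().lower() in ("variant", ""):
                continue
            flag = row[2].strip().lower()
            support_cell = row[3].strip() if len(row) > 3 else ""
            if re.fullmatch(r"[0-9]+", support_cell):
                n_support = int(support_cell)
            else:
                n_support = len([p for p in support_cell.split("|") if p])
            out.append(CurationRow(
                variant_key=row[0].strip(), disease=row[1].strip(),
                correct=flag in ("1", "true", "correct", "yes"),
                n_support=n_support,
            ))
    return out


def curation_precision(rows: Iterable[CurationRow]) -> tuple[float, dict[int, float]]:
    """Overall and per-support-count curation precision.

    Returns (precision, {n_support: precision}); overall precision is
    correct/total on the raw fractions (callers format via :func:`pct`).
    """
    rows = list(rows)
    if not rows:
        raise ValueError("empty curation table")
    correct = sum(r.correct for r in rows)
    by_support: dict[int, float] = {}
    strata: dict[int, list[CurationRow]] = {}
    for r in rows:
        strata.setdefault(r.n_support, []).append(r)
    for s, rs in sorted(strata.items()):
        by_support[s] = sum(r.correct for r in rs) / len(rs)
    return correct / len(rows), by_support


def novelty_vs_reference(
    correct_associations: Iterable[tuple[str, str]],
    reference_pairs: Iterable[tuple[str, str]],
) -> tuple[float, float]:
    """Fractions of curated-correct associations that are already in the
    reference vs novel; computed over the correct set only and summing
    to 1."""
    correct = set(correct_associations)
    if not correct:
        raise ValueError("empty correct set")
    ref = set(reference_pairs)
    common = len(correct & ref) / len(correct)
    return common, 1.0 - common
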