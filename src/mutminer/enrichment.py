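"""Concept and concept-pair enrichment with Benjamini-Hochberg FDR control.

The null model: a concept present in |C| of the |B| background documents
appears in a size-|K| random sample with expectation K * |C|/|B|. The
enrichment p-value is the inclusive upper tail P(X >= x) where x is the
observed sample frequency, under either a hypergeometric null (sampling
documents without replacement — the default, exact for small corpora) or
a binomial null (with replacement; converges to the hypergeometric as
|B| grows). P-values are adjusted jointly with the Benjamini-Hochberg
step-up procedure and concepts or pairs with FDR above the significance
level (default 0.05) are cut.

Pair enrichment treats the documents containing concept A as a biased
sample and tests concept B for enrichment within it; at sentence scope
the counting unit is a sentence of a full-text body (title+abstract
counting as one unit) instead of a document.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dictionaries import AnnotationIndex

__all__ = [
    "EnrichmentInput",
    "EnrichmentResult",
    "PairAssociation",
    "expected_count",
    "enrichment_pvalue",
    "bh_fdr",
    "enrich_concepts",
    "enrich_pairs",
]

Model = Literal["hypergeometric", "binomial"]


@dataclass(frozen=True)
class EnrichmentInput:
    """Counts for one enrichment test: background |B|, concept document
    frequency |C|, sample size |K|, and the observed overlap x."""

    background_size: int
    concept_doc_count: int
    sample_size: int
    observed: int

    def __post_init__(self) -> None:
        b, c, k, x = (self.background_size, self.concept_doc_count,
                      self.sample_size, self.observed)
        if not (0 <= c <= b and 0 <= k <= b):
            raise ValueError(f"need 0 <= |C|,|K| <= |B|; got |C|={c} |K|={k} |B|={b}")
        if not (0 <= x <= min(c, k)):
            raise ValueError(f"need 0 <= x <= min(|C|,|K|); got x={x}")


@dataclass(frozen=True)
class EnrichmentResult:
    concept_id: str
    dictionary_name: str
    observed: int
    expected: float
    p_value: float
    fdr: float
    significant: bool


@dataclass(frozen=True)
class PairAssociation:
    concept_a: str
    concept_b: str
    co_doc_count: int
    p_value: float
    fdr: float
    significant: bool


def expected_count(inp: EnrichmentInput) -> float:
    """E[|C ∩ K|] = |K| * |C| / |B|."""
    if inp.background_size == 0:
        raise ValueError("background_size must be positive")
    return inp.sample_size * inp.concept_doc_count / inp.background_size


def enrichment_pvalue(inp: EnrichmentInput, model: Model = "hypergeometric") -> float:
    """Inclusive upper-tail probability P(X >= observed) under the null.

    Implemented as the survival function at observed-1 so the observation
    itself is included in the tail; the value is always in (0, 1].
    """
    b, c, k, x = (inp.background_size, inp.concept_doc_count,
                  inp.sample_size, inp.observed)
    if x == 0:
        return 1.0
    if model == "hypergeometric":
        p = float(stats.hypergeom.sf(x - 1, b, c, k))
    elif model == "binomial":
        if b == 0:
            raise ValueError("background_size must be positive")
        p = float(stats.binom.sf(x - 1, k, c / b))
    else:
        raise ValueError(f"unknown model {model!r}")
    # clip numerical noise; an observed event can never have p == 0
    return min(1.0, max(p, math.ulp(0.0)))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order.

    adjusted_i = min_{j: p_(j) >= p_i} m * p_(j) / rank(j), capped at 1;
    the largest p-value is returned unchanged.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_concepts(
    index: AnnotationIndex,
    sample_doc_ids: Iterable[str],
    alpha: float = 0.05,
    model: Model = "hypergeometric",
) -> list[EnrichmentResult]:
    """Test every concept observed at least once in the sample for
    enrichment against the background; FDR-adjust jointly over all tested
    concepts and flag those with FDR <= alpha.
    """
    sample = set(sample_doc_ids)
    if not sample:
        raise ValueError("empty sample")
    b = index.doc_count
    k = len(sample)
    tested: list[tuple[str, int, float, float]] = []  # id, x, expected, p
    for cid, docs in sorted(index.postings.items()):
        x = len(docs & sample)
        if x == 0:
            continue
        inp = EnrichmentInput(background_size=b, concept_doc_count=len(docs),
                              sample_size=k, observed=x)
        tested.append((cid, x, expected_count(inp), enrichment_pvalue(inp, model)))
    if not tested:
        return []
    fdrs = bh_fdr([t[3] for t in tested])
    results = [
        EnrichmentResult(
            concept_id=cid,
            dictionary_name=index.dictionary_of.get(cid, ""),
            observed=x,
            expected=exp,
            p_value=p,
            fdr=float(q),
            significant=bool(q <= alpha),
        )
        for (cid, x, exp, p), q in zip(tested, fdrs)
    ]
    results.sort(key=lambda r: (r.fdr, r.p_value, r.concept_id))
    return results


def _units(index: AnnotationIndex, cid: str, scope: str):
    if scope == "sentence":
        return index.unit_postings.get(cid, set())
    return index.postings.get(cid, set())


def enrich_pairs(
    index: AnnotationIndex,
    enriched_concepts: Iterable[EnrichmentResult | str],
    alpha: float = 0.05,
    scope: str = "document",
) -> list[PairAssociation]:
    """Pair enrichment among concepts that passed the concept-level cut.

    For each ordered pair (A, B) co-occurring at least once, the units
    containing A form a biased sample within which B is tested exactly as
    in :func:`enrich_concepts`. Ordered tests are FDR-adjusted jointly,
    pairs with FDR > alpha are cut, and the survivors are de-duplicated to
    unordered pairs keeping the smaller FDR.
    """
    if scope not in ("document", "sentence"):
        raise ValueError(f"unknown scope {scope!r}")
    if scope == "sentence" and index.scope != "sentence":
        raise ValueError("sentence-scope pairs need an index built with scope='sentence'")
    concept_ids = sorted(
        c.concept_id if isinstance(c, EnrichmentResult) else str(c)
        for c in enriched_concepts
    )
    total_units = index.unit_count if scope == "sentence" else index.doc_count
    unit_sets = {cid: _units(index, cid, scope) for cid in concept_ids}

    ordered: list[tuple[str, str, int, float]] = []  # a, b, co, p
    for a in concept_ids:
        sample = unit_sets[a]
        if not sample:
            continue
        k = len(sample)
        for b_id in concept_ids:
            if b_id == a:
                continue
            c_units = unit_sets[b_id]
            co = len(sample & c_units)
            if co == 0:
                continue
            inp = EnrichmentInput(background_size=total_units,
                                  concept_doc_count=len(c_units),
                                  sample_size=k, observed=co)
            ordered.append((a, b_id, co, enrichment_pvalue(inp, "hypergeometric")))
    if not ordered:
        return []
    fdrs = bh_fdr([t[3] for t in ordered])
    best: dict[tuple[str, str], PairAssociation] = {}
    for (a, b_id, co, p), q in zip(ordered, fdrs):
        if q > alpha:
            continue
        key = (a, b_id) if a < b_id else (b_id, a)
        cand = PairAssociation(concept_a=key[0], concept_b=key[1], co_doc_count=co,
                               p_value=p, fdr=float(q), significant=True)
        prev = best.get(key)
        if prev is None or (cand.fdr, cand.p_value) < (prev.fdr, prev.p_value):
            best[key] = cand
    out = list(best.values())
    out.sort(key=lambda r: (r.fdr, r.p_value, r.concept_a, r.concept_b))
    return out
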