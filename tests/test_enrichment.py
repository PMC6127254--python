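"""Enrichment p-values, BH-FDR, and concept/pair enrichment."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mutminer.dictionaries import AnnotationIndex
from mutminer.enrichment import (
    EnrichmentInput,
    bh_fdr,
    enrich_concepts,
    enrich_pairs,
    enrichment_pvalue,
    expected_count,
)


def exhaustive_tail_probability(b, c, k, x):
    """Oracle: enumerate all C(b, k) samples of a b-document background in
    which c documents carry the concept; count samples with >= x hits."""
    concept_docs = set(range(c))
    total = hits = 0
    for sample in itertools.combinations(range(b), k):
        total += 1
        if len(concept_docs & set(sample)) >= x:
            hits += 1
    return hits / total


class TestExpectedCount:
    def test_zero_concept(self):
        assert expected_count(EnrichmentInput(100, 0, 20, 0)) == 0.0

    def test_full_sample_identity(self):
        assert expected_count(EnrichmentInput(50, 7, 50, 7)) == 7.0

    def test_direct_arithmetic(self):
        assert expected_count(EnrichmentInput(100, 10, 20, 2)) == pytest.approx(2.0)

    def test_zero_background_rejected(self):
        with pytest.raises(ValueError):
            expected_count(EnrichmentInput(0, 0, 0, 0))


class TestEnrichmentPvalue:
    def test_observed_zero_gives_one(self):
        assert enrichment_pvalue(EnrichmentInput(100, 10, 20, 0)) == 1.0

    def test_degenerate_full_sample(self):
        # K = |B|: the only outcome is x = |C|, so P(X >= |C|) = 1
        assert enrichment_pvalue(EnrichmentInput(10, 4, 10, 4)) == pytest.approx(1.0)

    def test_small_instance_matches_enumeration(self):
        p = enrichment_pvalue(EnrichmentInput(10, 4, 5, 3))
        assert p == pytest.approx(exhaustive_tail_probability(10, 4, 5, 3), rel=1e-12)

    def test_all_small_instances_match_enumeration(self):
        """Hypergeometric tail equals full sample-space enumeration for
        every instance with |B| <= 8 (the |B| <= 12 sweep runs in the
        acceptance suite)."""
        for b in range(1, 9):
            for c in range(0, b + 1):
                for k in range(1, b + 1):
                    for x in range(0, min(c, k) + 1):
                        p = enrichment_pvalue(EnrichmentInput(b, c, k, x))
                        oracle = exhaustive_tail_probability(b, c, k, x)
                        assert p == pytest.approx(oracle, rel=1e-10, abs=1e-12), (b, c, k, x)

    def test_binomial_converges_to_hypergeometric(self):
        """For fixed |K| and |C|/|B|, the two nulls agree as |B| grows."""
        diffs = []
        for b in (100, 1000, 10000):
            c = b // 10
            inp = EnrichmentInput(b, c, 50, 8)
            ph = enrichment_pvalue(inp, "hypergeometric")
            pb = enrichment_pvalue(inp, "binomial")
            diffs.append(abs(ph - pb) / ph)
        assert diffs[0] > diffs[1] > diffs[2]
        assert diffs[2] < 1e-2

    def test_inclusive_tail(self):
        # P(X >= x) must include the observation: strictly larger than
        # the exclusive tail P(X > x) whenever x is attainable
        inp = EnrichmentInput(50, 10, 20, 5)
        p_incl = enrichment_pvalue(inp)
        p_excl = enrichment_pvalue(EnrichmentInput(50, 10, 20, 6))
        assert p_incl > p_excl

    def test_invariant_violation_rejected(self):
        with pytest.raises(ValueError):
            EnrichmentInput(10, 4, 5, 5)  # x > min(|C|, |K|)
        with pytest.raises(ValueError):
            EnrichmentInput(10, 11, 5, 2)  # |C| > |B|


class TestBhFdr:
    def test_single_p_identity(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_hand_computed_step_up(self):
        # min over j>=i of m * p_(j) / j
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
        assert bh_fdr([0.01, 0.04, 0.9]) == pytest.approx([0.03, 0.06, 0.9])

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_largest_p_unchanged(self):
        p = [0.2, 0.5, 0.8, 0.04]
        adj = bh_fdr(p)
        assert adj[2] == pytest.approx(0.8)

    def test_order_preserved(self):
        p = [0.5, 0.01, 0.3]
        adj = bh_fdr(p)
        assert adj[1] == min(adj)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    def test_empty(self):
        assert len(bh_fdr([])) == 0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(p=st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    def test_pointwise_dominance_and_monotone(self, p):
        adj = bh_fdr(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)


def _index(postings, doc_count, dictionary_of=None):
    idx = AnnotationIndex(doc_count=doc_count)
    for cid, docs in postings.items():
        idx.postings[cid] = set(docs)
        idx.dictionary_of[cid] = (dictionary_of or {}).get(cid, "d")
    return idx


class TestEnrichConcepts:
    def test_saturated_concept_not_significant(self):
        docs = {f"d{i}" for i in range(20)}
        idx = _index({"C": docs}, 20)
        (r,) = enrich_concepts(idx, {"d0", "d1", "d2"})
        assert r.p_value == pytest.approx(1.0)
        assert not r.significant

    def test_identical_postings_identical_stats(self):
        postings = {"A": {"d0", "d1"}, "B": {"d0", "d1"}}
        idx = _index(postings, 50)
        ra, rb = sorted(enrich_concepts(idx, {"d0", "d1"}), key=lambda r: r.concept_id)
        assert ra.p_value == rb.p_value and ra.fdr == rb.fdr

    def test_expected_value_reported(self):
        # |B|=100, |C|=10, |K|=20 -> expected 2.0
        idx = _index({"A": {f"d{i}" for i in range(10)}}, 100)
        sample = {f"d{i}" for i in range(20)}
        (r,) = enrich_concepts(idx, sample)
        assert r.expected == pytest.approx(2.0)
        assert r.observed == 10

    def test_concept_absent_from_sample_not_tested(self):
        idx = _index({"A": {"d0"}, "B": {"d9"}}, 10)
        results = enrich_concepts(idx, {"d0"})
        assert [r.concept_id for r in results] == ["A"]

    def test_empty_sample_rejected(self):
        idx = _index({"A": {"d0"}}, 10)
        with pytest.raises(ValueError):
            enrich_concepts(idx, set())

    def test_planted_concept_detected(self):
        # 10x rate in the sample: 50% of sample docs vs 5% background
        rng = np.random.default_rng(7)
        background = [f"b{i}" for i in range(900)]
        sample = [f"s{i}" for i in range(100)]
        postings = {
            "planted": {d for d in sample if rng.random() < 0.5}
            | {d for d in background if rng.random() < 0.05},
            "null": {d for d in background + sample if rng.random() < 0.1},
        }
        idx = _index(postings, 1000)
        results = {r.concept_id: r for r in enrich_concepts(idx, set(sample))}
        assert results["planted"].significant
        assert results["planted"].fdr <= 0.05


class TestEnrichPairs:
    def test_never_cooccurring_pair_not_emitted(self):
        idx = _index({"A": {"d0"}, "B": {"d1"}}, 10)
        assert enrich_pairs(idx, ["A", "B"]) == []

    def test_saturated_partner_cut(self):
        docs = {f"d{i}" for i in range(30)}
        idx = _index({"A": {"d0", "d1"}, "B": docs}, 30)
        assert enrich_pairs(idx, ["A", "B"]) == []

    def test_strong_pair_significant_and_direction_consistent(self):
        co = {f"c{i}" for i in range(10)}
        idx = _index({
            "A": co | {"a1"},
            "B": co | {"b1"},
            "C": {f"x{i}" for i in range(40)},
        }, 200)
        pairs = enrich_pairs(idx, ["A", "B", "C"])
        (p,) = pairs
        assert {p.concept_a, p.concept_b} == {"A", "B"}
        assert p.co_doc_count == 10
        assert p.significant and p.fdr <= 0.05

    def test_unordered_dedup_keeps_smaller_fdr(self):
        co = {f"c{i}" for i in range(8)}
        idx = _index({"A": co | {f"a{i}" for i in range(20)}, "B": co}, 300)
        pairs = enrich_pairs(idx, ["A", "B"])
        assert len(pairs) == 1
        # the reported FDR is the better of the two orderings
        from mutminer.enrichment import EnrichmentInput as EI, enrichment_pvalue as pv
        p_ab = pv(EI(300, 8, 28, 8))    # sample=A docs, concept=B
        p_ba = pv(EI(300, 28, 8, 8))    # sample=B docs, concept=A
        assert pairs[0].p_value == pytest.approx(min(p_ab, p_ba))

    def test_sentence_scope_requires_sentence_index(self):
        idx = _index({"A": {"d0"}}, 10)
        with pytest.raises(ValueError):
            enrich_pairs(idx, ["A"], scope="sentence")

    def test_sentence_scope_counts_units(self):
        idx = AnnotationIndex(scope="sentence", doc_count=3, unit_count=60)
        co_units = {(f"d{i}", j) for i in range(2) for j in range(5)}
        idx.postings = {"A": {"d0", "d1"}, "B": {"d0", "d1"}}
        idx.unit_postings = {"A": co_units, "B": co_units}
        (p,) = enrich_pairs(idx, ["A", "B"], scope="sentence")
        assert p.co_doc_count == 10  # ten co-mentioning sentences
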