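# Methods

This note documents the models, rules and numerical choices behind
mutminer, and what the synthetic-data experiments do and do not show.

## Corpus model and query filtering

A corpus is an ordered list of documents, each with a unique identifier,
title, abstract, and optionally a full-text body. The document — never
the mention — is the counting unit for every statistic: background size
|B|, concept document frequency |C|, and sample size |K|.

The boolean retrieval filter keeps a document iff its combined text
contains at least one topic term AND at least one organism term. Matching
is whole-word and case-insensitive; quoted multi-word phrases ("homo
sapiens") match as contiguous token sequences. Hyphen, slash and
underscore act as token separators throughout, so "iron-overload" matches
the two-token term "iron overload". Full-text bodies are segmented into
sentences at load time with a deliberately simple rule — sentence-final
punctuation followed by whitespace and an uppercase letter or digit —
abbreviation-aware segmentation is out of scope and only affects
sentence-scope pair counting, not any document-level statistic.

The corpus reader exposes both the retrieved count and the annotated
count (documents with at least one dictionary hit,
`AnnotationIndex.annotated_doc_ids`); which of the two a downstream
consumer treats as "the corpus" is left to the caller, since the
retrieval and annotation stages are separable.

## Dictionary annotation

Term matching is leftmost-longest and non-overlapping over the token
sequence. Two policies deserve note:

* **Case.** Terms of ≤3 characters match exact-case only; longer terms
  match case-insensitively. Short gene symbols (NS1, TF) are the
  motivating case: lowercase prose collisions are a dominant
  false-positive source for them, while longer terms are safe to fold.
* **Ambiguity is kept.** If two dictionaries claim the identical winning
  span (a gene and a disease both named NS1), both concepts are posted.
  Resolution is deferred to enrichment: an incidental sense will not be
  statistically enriched.

Concept document frequency |C| counts distinct documents, not mentions;
mention counts are retained per (concept, document) so mention-weighted
variants remain recomputable. The scanning matcher is validated against a
quadratic try-every-substring oracle on randomized short texts.

## Mutation mention extraction and normalization

The extractor is a prioritized rule/regex recognizer, not a sequence
labeler and not a full HGVS grammar. Recognized styles: single-letter and
three-letter protein missense (with or without `p.`), verbose prose
("lysine to methionine at position 227"), DNA substitutions (`c.76A>T`,
`76A>T`), deletions, insertions, duplications, frameshifts,
deletion-insertions, and rs/ss identifiers (normalized to lowercase
prefix + digits). Positionless substitution artifacts ("A > C") are
deliberately recognized too: they normalize with empty fields and exist
so the cleaning stage has the false positives it is designed to delete.
More specific patterns take priority (`c.76_78delinsTT` is an indel, not
a deletion), then matches resolve left to right without overlap.

Normalization is the pipe form `level|OP|wild|position|mutant`. Position
is stored as a string so that malformed values arriving from external
mention tables (alphabetic, negative) survive parsing and are rejected by
cleaning with an explicit reason rather than crashing the reader.
Positional ranges (`76_77`) are stored by their start coordinate with the
end kept in an auxiliary field excluded from equality; the serialized
form shows the start only.

### Cleaning rules

Applied in order per mention, each rejection carrying a machine-readable
reason:

1. `frequency_threshold` — the normalized form's summed corpus-wide
   occurrence count exceeds 50,000 (default). The count is total
   occurrences, not distinct documents: the artifacts this rule targets
   are high-frequency surface patterns. Duplicating a corpus can
   therefore never un-reject a form (tested).
2. `missing_fields` / `invalid_position` — field-completeness per
   operation and position sanity. Required fields: SUB needs all five;
   DEL/DUP need level and position (wild optional); INS and INDEL
   additionally need the inserted material; FS needs level, wild and
   position. These are the minimal fields that make a variant locatable.

### Catalog validation

rs-mentions validate by identifier lookup; other mentions by exact
(operation, wild, position, mutant) match, case-normalized on residues.
Fractions are reported per class and are `None` (not 0) when a class is
empty. An empty catalog warns rather than erroring, since zero validation
is a meaningful (if suspicious) outcome.

## Enrichment

The null: a concept with background document frequency |C| out of |B|
appears in each document of a size-|K| random sample with probability
|C|/|B|; expected overlap K·|C|/|B|. The p-value is the inclusive tail
P(X ≥ x) = 1 − CDF(x−1) — implemented as the survival function at x−1 so
the observation itself is in the tail; the exclusive 1 − CDF(x) would
understate every p-value and can reach 0, which an observed event never
should. x = 0 gives p = 1 by construction.

The hypergeometric model (sampling without replacement) is the default:
it is exact for small corpora, which is where the two models differ. The
binomial is selectable and converges to it as |B| grows (tested at
|B| = 10², 10³, 10⁴). The hypergeometric implementation is verified
against full sample-space enumeration on every instance with |B| ≤ 12.

Multiplicity correction is Benjamini–Hochberg step-up (via
`statsmodels`), applied **jointly over all concepts tested in a run**
rather than per dictionary — joint correction is more conservative and
does not depend on how concepts happen to be partitioned into
dictionaries. Significance is FDR ≤ α, default α = 0.05. Ties in FDR are
preserved; no re-ranking.

Pair enrichment scores each ordered pair (A, B) with co-occurrence ≥ 1 by
treating the units containing A as a biased sample; ordered tests are
FDR-adjusted jointly, survivors de-duplicated to unordered pairs keeping
the smaller FDR. The co-occurrence count is symmetric, so both orderings
agree on the reported publication count. Only concepts that passed the
concept-level cut enter pair enrichment. Sentence scope (title+abstract
as one unit, each body sentence as one unit) applies to full-text
documents; document scope is the default.

## Networks

Edges carry the pair's co-occurrence document count ("publications
linking the nodes") and FDR. Expansion adds at most `max_children = 10`
partners per call, ranked by publication count descending, FDR ascending,
then lexicographic id; the cap counts selected partners (not only new
nodes), which makes repeated expansion of a node idempotent. Whether to
rank by count or by enrichment score is genuinely open; count-first is
the default because edge labels show counts, and `rank_by="fdr"` provides
the alternative. Pruning removes non-seed nodes of degree < `min_links`
iteratively to a fixpoint; the seed is never removed. DNA-level and
protein-level forms of one variant are distinct nodes by default;
`collapse_levels` merges nodes sharing (wild, position, mutant) as a
convenience.

## Annotation comparison and evaluation arithmetic

Mention spans from different extractors rarely align, so comparison is at
the level of normalized variants: hits are keyed by (document, level,
key) with level RS / DNA / PROTEIN and key the rs id or the
(wild, position, mutant) tuple, case-normalized. In concatenated
three-letter forms (SERGLY325) the order is wild-then-mutant, consistent
with the accompanying verbose gloss ("serine to glycine"). Rows are
partitioned into A-only / common / B-only per (level, category) with
categories missense / indel / FS.

Metrics: precision = TP/(TP+FP), recall = TP/(TP+FN), F = harmonic mean,
under three reference conventions — union (TP = |A|, FP = 0,
FN = B-only), intersection (TP = common, FP = A-only, FN = 0), and
B-as-truth (TP = common, FP = A-only, FN = B-only). Division by zero is
reported as undefined, never 0. Percentages round half-up to integers
(two decimals for curation precision), matching the convention of
reporting such tables.

Curation precision is correct/total over a curated association table,
with per-support-count strata. Novelty fractions are computed **over the
curated-correct set only** (common + novel = 1); other denominators one
might imagine (all extracted associations, all curated rows) are ambiguous
and not reported. Association keys are exact variant key + exact disease
concept id, with no ontology-ancestor expansion.

## Synthetic corpus generator

The generator is the package's source of ground truth and emulates
exactly the structure the enrichment null assumes:

* concept occurrences are independent Bernoulli per document at the
  concept's background probability (default 0.05 over a 20-concept
  disease/gene vocabulary);
* a planted concept's probability is multiplied by its lift (default:
  one concept at lift 5) inside the designated sample (default 500 of
  2,000 documents);
* a planted pair shares a latent indicator with rate
  r = (L−1)·p_a·p_b / (1−p_a·p_b), giving joint probability L·p_a·p_b
  while perturbing the marginals only slightly;
* mutation mentions are rendered at one per document on average
  (Poisson), in surface styles drawn uniformly from the supported set,
  with every mention's canonical form recorded; optional noise injects
  malformed strings from the known-artifact list ("A > C" variants);
* every document carries a filler sentence containing "mutation" and
  "human", so generated corpora pass the default boolean query.

Defaults (2,000 background / 500 sample / 5% base rate / lift 5) were
chosen as a desk-scale setting where a lift-5 signal is comfortably but
not trivially detectable — expected 54 vs observed ≈ 140 sample hits —
and are used unchanged by the acceptance experiments.

What passing synthetic tests does **not** show: robustness to natural
language (negation, hedging, coordination), abbreviation ambiguity,
correlated concept usage beyond the planted pairs, realistic mention-style
frequencies, or corpus-scale behaviour (the real corpora behind such
knowledgebases are two to three orders of magnitude larger). The
synthetic experiments validate the statistical machinery and the
extraction/normalization rules, not linguistic coverage.

## Problem sizes and numerical choices

* Acceptance experiments use 100 seeded replicates of the default
  generator configuration for recovery/false-positive rates, full
  enumeration up to |B| = 12 for the hypergeometric check, and 1,000
  randomized sentences (≤30 tokens) for the extractor-vs-oracle check —
  sizes chosen so the whole suite runs in well under a minute per check
  on one CPU.
* p-values are clipped to (0, 1]: the survival function can underflow to
  0 for extreme observations, and an observed event is never assigned
  probability 0.
* Seeds: every stochastic component takes an explicit integer seed;
  replicate seeds are spawned from a base seed via `numpy`'s generator
  and stay below 2³¹.
* Known limitation: the extractor's single-letter missense pattern will
  fire on mutation-like tokens that are not variants (cell-line names);
  no special lexicon filters them, by design — the frequency rule and
  enrichment cut-off are the intended defenses, and genuinely ambiguous
  hits are kept.
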