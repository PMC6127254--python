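"""Seeded synthetic corpora with known ground truth.

The generator emulates the statistical structure the enrichment model
assumes: each concept occurs in a document as an independent Bernoulli
event at its background probability; inside a designated topical sample
the probability of a *planted* concept is multiplied by its lift; a
planted pair (a, b) shares a latent indicator that raises their joint
probability to lift * P(a) * P(b) while leaving the marginals nearly
unchanged. Documents also carry mutation mentions rendered in randomized
surface styles, plus (optionally) malformed mutation-like noise strings
drawn from the catalog of known extractor false positives ("A > C" and
friends), so that extraction, normalization and cleaning are all testable
against recorded truth.

Every document contains the filler sentence "Study of mutation effects in
human subjects", so a generated corpus passes the default topic/organism
boolean query. What the generator does NOT emulate: natural language
context, negation, abbreviation ambiguity, or correlated concept usage
beyond the planted pairs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .corpus import Document
from .dictionaries import DictionaryEntry
from .mutations import CatalogRecord, NormalizedVariant
from .evaluation import CurationRow

__all__ = [
    "ConceptSpec",
    "GeneratorConfig",
    "SyntheticCorpus",
    "generate_corpus",
    "generate_curation_fixture",
    "MUTATION_STYLES",
    "NOISE_STRINGS",
    "DEFAULT_CURATION_STRATA",
]

#: renderers for a protein missense variant, keyed by style name
MUTATION_STYLES = ("single_letter", "three_letter", "verbose", "dna", "rsid")

#: malformed mutation-like strings modelled on known extractor false
#: positives: positionless substitutions that normalize with empty fields
NOISE_STRINGS = ("A > C", "G > T", "C > A", "T > G")

_AA1 = "ACDEFGHIKLMNPQRSTVWY"
_AA_1TO3 = {
    "A": "Ala", "C": "Cys", "D": "Asp", "E": "Glu", "F": "Phe", "G": "Gly",
    "H": "His", "I": "Ile", "K": "Lys", "L": "Leu", "M": "Met", "N": "Asn",
    "P": "Pro", "Q": "Gln", "R": "Arg", "S": "Ser", "T": "Thr", "V": "Val",
    "W": "Trp", "Y": "Tyr",
}
_AA_1TONAME = {
    "A": "alanine", "C": "cysteine", "D": "aspartate", "E": "glutamate",
    "F": "phenylalanine", "G": "glycine", "H": "histidine", "I": "isoleucine",
    "K": "lysine", "L": "leucine", "M": "methionine", "N": "asparagine",
    "P": "proline", "Q": "glutamine", "R": "arginine", "S": "serine",
    "T": "threonine", "V": "valine", "W": "tryptophan", "Y": "tyrosine",
}


@dataclass(frozen=True)
class ConceptSpec:
    """One mock dictionary concept with its background occurrence rate."""

    concept_id: str
    term: str
    dictionary_name: str = "disease"
    background_prob: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 <= self.background_prob <= 1.0):
            raise ValueError(f"{self.concept_id}: probability outside [0,1]")


def _default_vocabulary() -> tuple[ConceptSpec, ...]:
    diseases = ["thalassemia", "hemochromatosis", "iron overload", "anemia",
                "cystic fibrosis", "breast cancer", "prostate cancer",
                "alzheimer disease", "parkinson disease", "tuberculosis"]
    genes = ["HFE", "TF", "TMPRSS6", "HBB", "CFTR", "BRCA1", "TP53", "FGFR3",
             "TLR4", "KRAS"]
    vocab = [
        ConceptSpec(concept_id=f"DIS:{i:03d}", term=t, dictionary_name="disease",
                    background_prob=0.05)
        for i, t in enumerate(diseases)
    ]
    vocab += [
        ConceptSpec(concept_id=f"GENE:{i:03d}", term=t, dictionary_name="gene",
                    background_prob=0.05)
        for i, t in enumerate(genes)
    ]
    return tuple(vocab)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic corpus.

    Defaults: a 2,000-document background containing a 500-document
    topical sample, a 20-concept vocabulary at 5% background occurrence,
    planted enrichment lift 5 and planted pair lift 5, one mutation
    mention per document on average, no malformed noise.
    """

    n_background_docs: int = 2000
    n_sample_docs: int = 500
    vocabulary: tuple[ConceptSpec, ...] = field(default_factory=_default_vocabulary)
    planted_concepts: Mapping[str, float] = field(default_factory=lambda: {"DIS:000": 5.0})
    planted_pairs: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {("DIS:002", "GENE:000"): 5.0})
    mutation_styles: tuple[str, ...] = MUTATION_STYLES
    mention_rate: float = 1.0
    noise_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sample_docs > self.n_background_docs:
            raise ValueError("sample cannot exceed background")
        for c, lift in self.planted_concepts.items():
            if lift < 1:
                raise ValueError(f"lift for {c} must be >= 1")
        for pair, lift in self.planted_pairs.items():
            if lift < 1:
                raise ValueError(f"lift for {pair} must be >= 1")
        if not (0.0 <= self.noise_rate <= 1.0):
            raise ValueError("noise_rate outside [0,1]")
        unknown = set(self.mutation_styles) - set(MUTATION_STYLES)
        if unknown:
            raise ValueError(f"unknown mutation styles {sorted(unknown)}")


@dataclass
class SyntheticCorpus:
    """Generated corpus plus every piece of ground truth."""

    documents: list[Document]
    sample_doc_ids: set[str]
    dictionary: list[DictionaryEntry]
    catalog: list[CatalogRecord]
    # truth tables
    concept_occurrences: dict[str, set[str]]        # concept -> doc ids
    planted_concepts: dict[str, float]
    planted_pairs: dict[tuple[str, str], float]
    mention_truth: list[tuple[str, str, str]]       # (doc_id, surface, normalized form)
    noise_truth: list[tuple[str, str]]              # (doc_id, noise surface)

    def write(self, outdir: str | Path) -> None:
        from .corpus import write_corpus
        from .dictionaries import write_dictionary

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_corpus(self.documents, outdir / "corpus.jsonl")
        write_dictionary(self.dictionary, outdir / "dictionary.tsv")
        with (outdir / "catalog.tsv").open("w") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["rs_id", "seq_level", "operation", "wild", "position", "mutant"])
            for c in self.catalog:
                w.writerow([c.rs_id, c.seq_level, c.operation, c.wild, c.position, c.mutant])
        with (outdir / "truth_mentions.tsv").open("w") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            for row in self.mention_truth:
                w.writerow(row)
        with (outdir / "sample_doc_ids.txt").open("w") as fh:
            fh.write("\n".join(sorted(self.sample_doc_ids)) + "\n")


def _render_mutation(rng: np.random.Generator, style: str) -> tuple[str, NormalizedVariant]:
    pos = int(rng.integers(10, 999))
    if style == "rsid":
        rsnum = int(rng.integers(1_000, 9_999_999))
        return f"rs{rsnum}", NormalizedVariant(rs_id=f"rs{rsnum}")
    if style == "dna":
        wild, mut = rng.choice(list("ACGT"), size=2, replace=False)
        return (f"c.{pos}{wild}>{mut}",
                NormalizedVariant(seq_level="c", operation="SUB", wild=str(wild),
                                  position=str(pos), mutant=str(mut)))
    wild, mut = rng.choice(list(_AA1), size=2, replace=False)
    var = NormalizedVariant(seq_level="p", operation="SUB", wild=str(wild),
                            position=str(pos), mutant=str(mut))
    if style == "single_letter":
        return f"{wild}{pos}{mut}", var
    if style == "three_letter":
        return f"{_AA_1TO3[wild]}{pos}{_AA_1TO3[mut]}", var
    if style == "verbose":
        return (f"{_AA_1TONAME[wild]} to {_AA_1TONAME[mut]} at position {pos}", var)
    raise ValueError(f"unknown style {style!r}")


def generate_corpus(cfg: GeneratorConfig) -> SyntheticCorpus:
    """Generate a corpus under ``cfg``; a fixed seed gives byte-identical
    output."""
    rng = np.random.default_rng(cfg.seed)
    vocab = {c.concept_id: c for c in cfg.vocabulary}
    for cid in cfg.planted_concepts:
        if cid not in vocab:
            raise ValueError(f"planted concept {cid!r} not in vocabulary")
    for a, b in cfg.planted_pairs:
        if a not in vocab or b not in vocab:
            raise ValueError(f"planted pair ({a}, {b}) not in vocabulary")

    n = cfg.n_background_docs
    doc_ids = [f"PMID:{i + 1:06d}" for i in range(n)]
    sample_ids = set(doc_ids[: cfg.n_sample_docs])

    occurrences: dict[str, set[str]] = {cid: set() for cid in vocab}
    paired = {c for pair in cfg.planted_pairs for c in pair}

    # independent Bernoulli occurrences, lifted inside the sample for
    # planted concepts; planted pairs get a shared latent indicator chosen
    # so that P(both) = lift * pa * pb
    for i, doc_id in enumerate(doc_ids):
        in_sample = doc_id in sample_ids
        present: set[str] = set()
        for cid, spec in vocab.items():
            if cid in paired:
                continue
            p = spec.background_prob
            if in_sample and cid in cfg.planted_concepts:
                p = min(1.0, p * cfg.planted_concepts[cid])
            if rng.random() < p:
                present.add(cid)
        for (a, b), lift in cfg.planted_pairs.items():
            pa, pb = vocab[a].background_prob, vocab[b].background_prob
            target = min(1.0, lift * pa * pb)
            r = max(0.0, (target - pa * pb) / (1.0 - pa * pb))
            if rng.random() < r:
                present |= {a, b}
            else:
                if rng.random() < pa:
                    present.add(a)
                if rng.random() < pb:
                    present.add(b)
        for cid in present:
            occurrences[cid].add(doc_id)

    # render documents
    documents: list[Document] = []
    mention_truth: list[tuple[str, str, str]] = []
    noise_truth: list[tuple[str, str]] = []
    catalog_rows: list[CatalogRecord] = []
    styles = list(cfg.mutation_styles)
    for doc_id in doc_ids:
        terms = sorted(cid for cid in vocab if doc_id in occurrences[cid])
        sentences = ["Study of mutation effects in human subjects."]
        for cid in terms:
            sentences.append(f"The report discusses {vocab[cid].term} in detail.")
        n_mentions = rng.poisson(cfg.mention_rate)
        for _ in range(n_mentions):
            style = styles[int(rng.integers(len(styles)))]
            surface, var = _render_mutation(rng, style)
            sentences.append(f"We observed the variant {surface} in patients.")
            mention_truth.append((doc_id, surface, var.serialize()))
            if var.rs_id:
                catalog_rows.append(CatalogRecord(rs_id=var.rs_id))
            else:
                catalog_rows.append(CatalogRecord(
                    seq_level=var.seq_level, operation=var.operation,
                    wild=var.wild, position=var.position, mutant=var.mutant))
        if rng.random() < cfg.noise_rate:
            noise = NOISE_STRINGS[int(rng.integers(len(NOISE_STRINGS)))]
            sentences.append(f"Signal ratio {noise} was recorded.")
            noise_truth.append((doc_id, noise))
        documents.append(Document(
            doc_id=doc_id,
            title=f"Synthetic report {doc_id}",
            abstract=" ".join(sentences),
        ))

    dictionary = [
        DictionaryEntry(concept_id=cid, preferred_name=spec.term,
                        synonyms=frozenset({spec.term}),
                        dictionary_name=spec.dictionary_name)
        for cid, spec in sorted(vocab.items())
    ]
    return SyntheticCorpus(
        documents=documents,
        sample_doc_ids=sample_ids,
        dictionary=dictionary,
        catalog=catalog_rows,
        concept_occurrences=occurrences,
        planted_concepts=dict(cfg.planted_concepts),
        planted_pairs=dict(cfg.planted_pairs),
        mention_truth=mention_truth,
        noise_truth=noise_truth,
    )


# ---------------------------------------------------------------------------
# Curation fixture

#: sampling strata: (rank window label, support count or range, rows) —
#: six blocks of 100 associations at decreasing support, mirroring a
#: rank-stratified draw from an association table sorted by supporting
#: publications
DEFAULT_CURATION_STRATA: tuple[tuple[tuple[int, int], int], ...] = (
    ((16, 27), 100),
    ((8, 8), 100),
    ((5, 5), 100),
    ((3, 3), 100),
    ((2, 2), 100),
    ((1, 1), 100),
)

#: default per-stratum probability that curators confirm an association;
#: increasing with support, overall mean near the low seventies
DEFAULT_CORRECT_PROBS: tuple[float, ...] = (0.90, 0.84, 0.75, 0.70, 0.66, 0.62)


def generate_curation_fixture(
    seed: int = 0,
    strata: Sequence[tuple[tuple[int, int], int]] = DEFAULT_CURATION_STRATA,
    correct_probs: Sequence[float] | None = None,
) -> list[CurationRow]:
    """Emit a stratified curation table: for each stratum, ``rows``
    associations each supported by a publication count drawn from the
    stratum's range, flagged correct with the stratum's probability."""
    if correct_probs is None:
        correct_probs = DEFAULT_CORRECT_PROBS[: len(strata)]
    if len(correct_probs) != len(strata):
        raise ValueError("one correctness probability per stratum required")
    rng = np.random.default_rng(seed)
    rows: list[CurationRow] = []
    k = 0
    for ((lo, hi), count), p_correct in zip(strata, correct_probs):
        for _ in range(count):
            k += 1
            support = int(rng.integers(lo, hi + 1))
            rows.append(CurationRow(
                variant_key=f"p|SUB|K|{100 + k}|M",
                disease=f"DIS:{k % 17:03d}",
                correct=bool(rng.random() < p_correct),
                n_support=support,
            ))
    return rows
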