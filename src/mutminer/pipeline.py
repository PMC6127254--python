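"""End-to-end pipeline: filter -> annotate -> extract -> clean -> validate
-> enrich -> pairs, with a manifest of effective parameters and a
plain-text log so that every run is a pure function of (inputs, config,
seed)."""

from __future__ import annotations

import csv
import json
import logging
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import corpus as corpus_mod
from .corpus import CorpusQuery, DEFAULT_QUERY, read_corpus, filter_by_query
from .dictionaries import annotate, load_dictionary
from .enrichment import enrich_concepts, enrich_pairs
from .mutations import (
    DEFAULT_FREQ_THRESHOLD,
    clean_mentions,
    extract_mentions,
    read_catalog,
    validate_against_catalog,
    write_mention_table,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("mutminer")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    corpus_path: str
    dictionary_paths: list[str] = field(default_factory=list)
    catalog_path: str | None = None
    outdir: str = "mutminer_out"
    topic_terms: list[str] = field(default_factory=lambda: sorted(DEFAULT_QUERY.topic_terms))
    organism_terms: list[str] = field(default_factory=lambda: sorted(DEFAULT_QUERY.organism_terms))
    alpha: float = 0.05
    model: str = "hypergeometric"
    scope: str = "document"
    freq_threshold: int = DEFAULT_FREQ_THRESHOLD
    max_children: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.freq_threshold <= 0 or self.max_children <= 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        with Path(path).open() as fh:
            data = json.load(fh)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def _setup_logging(outdir: Path) -> None:
    if not any(isinstance(h, logging.FileHandler)
               and Path(getattr(h, "baseFilename", "")) == outdir / "run.log"
               for h in log.handlers):
        fh = logging.FileHandler(outdir / "run.log", mode="w")
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(fh)
    log.setLevel(logging.INFO)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full workflow; returns (and writes) a summary report."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    manifest = asdict(cfg)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("run parameters: %s", json.dumps(manifest, sort_keys=True))

    docs = _stage("read_corpus")(read_corpus)(cfg.corpus_path)
    query = CorpusQuery(cfg.topic_terms, cfg.organism_terms)
    retained = _stage("filter")(filter_by_query)(docs, query)
    corpus_mod.write_corpus(retained, outdir / "retained_corpus.jsonl")
    log.info("corpus: %d documents, %d retained by query", len(docs), len(retained))

    entries = []
    for p in cfg.dictionary_paths:
        entries.extend(_stage("load_dictionary")(load_dictionary)(p))
    if not entries:
        raise PipelineError("stage 'annotate' failed: no dictionary entries loaded")
    index = _stage("annotate")(annotate)(docs, entries, scope=cfg.scope)
    annotated_ids = index.annotated_doc_ids()
    log.info("annotated: %d of %d documents have >=1 dictionary hit",
             len(annotated_ids), index.doc_count)

    mentions = []
    for d in docs:
        mentions.extend(_stage("extract")(extract_mentions)(d))
    kept, rejected = _stage("clean")(clean_mentions)(mentions, cfg.freq_threshold)
    write_mention_table(kept, outdir / "mentions_kept.tsv")
    with (outdir / "mentions_rejected.tsv").open("w") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for m, reason in rejected:
            w.writerow([m.doc_id, m.surface, m.count, m.variant.serialize(), reason])

    validation = None
    if cfg.catalog_path:
        catalog = _stage("validate")(read_catalog)(cfg.catalog_path)
        validated, report = _stage("validate")(validate_against_catalog)(kept, catalog)
        write_mention_table(validated, outdir / "mentions_validated.tsv")
        validation = {
            "n_rs": report.n_rs, "n_rs_validated": report.n_rs_validated,
            "n_other": report.n_other, "n_other_validated": report.n_other_validated,
            "n_total_validated": report.n_total_validated,
        }

    sample_ids = {d.doc_id for d in retained}
    results = _stage("enrich")(enrich_concepts)(index, sample_ids, cfg.alpha, cfg.model)
    significant = [r for r in results if r.significant]
    with (outdir / "enrichment.tsv").open("w") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["concept_id", "dictionary", "observed", "expected",
                    "p_value", "fdr", "significant"])
        for r in results:
            w.writerow([r.concept_id, r.dictionary_name, r.observed,
                        f"{r.expected:.4f}", repr(r.p_value), repr(r.fdr),
                        int(r.significant)])

    pairs = _stage("pairs")(enrich_pairs)(index, significant, cfg.alpha, cfg.scope)
    with (outdir / "pairs.tsv").open("w") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["concept_a", "concept_b", "co_count", "p_value", "fdr"])
        for p in pairs:
            w.writerow([p.concept_a, p.concept_b, p.co_doc_count,
                        repr(p.p_value), repr(p.fdr)])

    category_counts = Counter(m.category for m in kept)
    summary = {
        "n_documents": len(docs),
        "n_retained": len(retained),
        "n_annotated": len(annotated_ids),
        "n_mentions_raw": len(mentions),
        "n_mentions_kept": len(kept),
        "n_mentions_rejected": len(rejected),
        "mention_categories": dict(sorted(category_counts.items())),
        "validation": validation,
        "n_concepts_tested": len(results),
        "n_concepts_enriched": len(significant),
        "n_pairs_enriched": len(pairs),
        "enriched_concepts": [r.concept_id for r in significant],
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    log.info("summary: %s", json.dumps(summary, sort_keys=True))
    return summary
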