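import json

import pytest

from mutminer.corpus import CorpusQuery, Document
from mutminer.dictionaries import DictionaryEntry


@pytest.fixture
def six_docs():
    """Small corpus exercising both halves of the boolean query."""
    return [
        Document("d1", title="A mutation in human TP53", abstract="Functional study."),
        Document("d2", title="Bridge vibration analysis", abstract="Modal frequencies."),
        Document("d3", title="Mutations only, no organism term", abstract=""),
        Document("d4", title="Homo sapiens genome", abstract="No topic word here."),
        Document("d5", title="Indel calling in bacteria", abstract="Pipeline."),
        Document("d6", title="", abstract="Deletions observed in viruses."),
    ]


@pytest.fixture
def default_query():
    return CorpusQuery(
        topic_terms=["mutation", "mutations", "indel", "indels", "deletion",
                     "deletions", "insertion", "insertions", "mutagenesis"],
        organism_terms=["human", "homo sapiens", "bacterium", "bacteria",
                        "virus", "viruses", "fungi", "fungus"],
    )


@pytest.fixture
def disease_entries():
    return [
        DictionaryEntry("DIS:1", "thalassemia", frozenset({"thalassaemia"}), "disease"),
        DictionaryEntry("DIS:2", "iron overload", frozenset(), "disease"),
        DictionaryEntry("GENE:1", "HFE", frozenset(), "gene"),
        DictionaryEntry("GENE:2", "iron", frozenset(), "gene"),
    ]


@pytest.fixture
def corpus_file(tmp_path):
    def make(records):
        p = tmp_path / "corpus.jsonl"
        with p.open("w") as fh:
            for r in records:
                fh.write(json.dumps(r) + "\n")
        return p

    return make
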