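"""Mention extraction, pipe-form normalization, cleaning, and catalog
validation."""

import re

import pytest
from hypothesis import given, settings, strategies as st

from mutminer.corpus import Document
from mutminer.mutations import (
    _PATTERNS,
    CatalogRecord,
    MutationMention,
    NormalizationError,
    NormalizedVariant,
    REASON_FIELDS,
    REASON_FREQUENCY,
    REASON_POSITION,
    clean_mentions,
    extract_mentions,
    normalize_mention,
    parse_normalized_form,
    read_mention_table,
    validate_against_catalog,
    write_mention_table,
)


NORMALIZATION_CASES = [
    ("lysine to methionine at position 227", "p|SUB|K|227|M"),
    ("Y151M", "p|SUB|Y|151|M"),
    ("rs4986790", "SNP: rs4986790"),
    ("Tyr151Met", "p|SUB|Y|151|M"),
    ("P249R", "p|SUB|P|249|R"),
    ("p.Lys227Met", "p|SUB|K|227|M"),
    ("76A>T", "c|SUB|A|76|T"),
    ("c.76A>T", "c|SUB|A|76|T"),
    ("c.76delA", "c|DEL|A|76|"),
    ("p.K227del", "p|DEL|K|227|"),
    ("delK227", "p|DEL|K|227|"),
    ("c.76_77insG", "c|INS||76|G"),
    ("c.76dupA", "c|DUP|A|76|"),
    ("K227fs", "p|FS|K|227|"),
    ("p.Lys227fsTer10", "p|FS|K|227|"),
    ("c.76_78delinsTT", "c|INDEL||76|TT"),
    ("ss1234567", "SNP: ss1234567"),
    ("serine to glycine at position 325", "p|SUB|S|325|G"),
]


class TestNormalizeMention:
    @pytest.mark.parametrize("surface,expected", NORMALIZATION_CASES)
    def test_surface_forms(self, surface, expected):
        assert normalize_mention(surface).serialize() == expected

    def test_unrecognized_rejected_with_reason(self):
        with pytest.raises(NormalizationError):
            normalize_mention("not a mutation at all")

    def test_rs_prefix_lowercased(self):
        assert normalize_mention("RS4986790").rs_id == "rs4986790"

    def test_categories(self):
        assert normalize_mention("Y151M").category == "Substitution"
        assert normalize_mention("rs123").category == "SNP"
        assert normalize_mention("c.76delA").category == "Deletion"
        assert normalize_mention("c.76_77insG").category == "Insertion"
        assert normalize_mention("c.76dupA").category == "Duplication"
        assert normalize_mention("K227fs").category == "Frameshift"
        assert normalize_mention("c.76_78delinsTT").category == "InDels"

    def test_range_position_stored_by_start(self):
        v = normalize_mention("c.76_77insG")
        assert v.position == "76" and v.span_end == "77"


class TestRoundTrip:
    @pytest.mark.parametrize("surface,form", NORMALIZATION_CASES)
    def test_parse_inverts_serialize(self, surface, form):
        v = normalize_mention(surface)
        assert parse_normalized_form(v.serialize()) == v

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        level=st.sampled_from(["c", "p"]),
        op=st.sampled_from(["SUB", "DEL", "INS", "DUP", "FS", "INDEL"]),
        wild=st.sampled_from(["", "A", "K", "TT"]),
        pos=st.integers(min_value=1, max_value=99999),
        mut=st.sampled_from(["", "M", "G", "CC"]),
    )
    def test_round_trip_any_tuple(self, level, op, wild, pos, mut):
        v = NormalizedVariant(seq_level=level, operation=op, wild=wild,
                              position=str(pos), mutant=mut)
        assert parse_normalized_form(v.serialize()) == v

    def test_malformed_pipe_form_rejected(self):
        with pytest.raises(NormalizationError):
            parse_normalized_form("p|SUB|K")


def _mention(form, doc_id="d1", count=1, surface=None):
    v = parse_normalized_form(form)
    return MutationMention(doc_id=doc_id, surface=surface or form, count=count, variant=v)


class TestExtractMentions:
    def test_counts_aggregate_per_normalized_form(self):
        doc = Document("d1", abstract="Y151M was seen; later Tyr151Met again and Y151M.")
        (m,) = extract_mentions(doc)
        assert m.variant.serialize() == "p|SUB|Y|151|M"
        assert m.count == 3

    def test_multiple_styles_in_one_doc(self):
        doc = Document("d1", abstract="rs4986790 and c.76A>T plus K227fs were found")
        forms = {m.variant.serialize() for m in extract_mentions(doc)}
        assert forms == {"SNP: rs4986790", "c|SUB|A|76|T", "p|FS|K|227|"}

    def test_unrecognized_text_yields_nothing(self):
        assert extract_mentions(Document("d1", abstract="plain prose only")) == []

    def test_positionless_artifact_extracted_with_empty_fields(self):
        (m,) = extract_mentions(Document("d1", abstract="ratio A > C increased"))
        assert m.variant.operation == "SUB" and m.variant.position == ""

    def test_delins_not_double_counted_as_del(self):
        doc = Document("d1", abstract="the c.76_78delinsTT variant")
        (m,) = extract_mentions(doc)
        assert m.variant.operation == "INDEL"


def _brute_force_scan(text):
    """Oracle: run every pattern at every character offset with match()."""
    hits = []
    for prio, (style, rx, fn) in enumerate(_PATTERNS):
        for i in range(len(text) + 1):
            m = rx.match(text, i)
            if m and m.start() == i:
                try:
                    var = fn(m)
                except NormalizationError:
                    continue
                hits.append((m.start(), m.end(), prio, var))
    hits.sort(key=lambda h: (h[2], h[0], -(h[1] - h[0])))
    taken, out = [], []
    for s, e, _p, var in hits:
        if any(s < te and ts < e for ts, te in taken):
            continue
        taken.append((s, e))
        out.append(var.serialize())
    return sorted(out)


SURFACES = [c[0] for c in NORMALIZATION_CASES]
FILLER = ["the", "variant", "was", "observed", "in", "all", "patients", "cohort"]


@settings(max_examples=150, deadline=None, derandomize=True)
@given(
    parts=st.lists(
        st.one_of(st.sampled_from(SURFACES), st.sampled_from(FILLER)),
        min_size=1, max_size=12,
    )
)
def test_extractor_equals_regex_at_every_offset_oracle(parts):
    text = " ".join(parts)
    doc = Document("d", abstract=text)
    got = sorted(
        f for m in extract_mentions(doc) for f in [m.variant.serialize()] * m.count)
    assert got == _brute_force_scan(doc.text)


class TestCleanMentions:
    def test_missing_fields_rejected(self):
        kept, rejected = clean_mentions([_mention("|SUB|A||")])
        assert kept == []
        assert rejected[0][1] == REASON_FIELDS

    def test_frequency_threshold(self):
        # a short pattern occurring 60,000 times corpus-wide
        noisy = [_mention("c|SUB|A|7|C", doc_id=f"d{i}", count=6000) for i in range(10)]
        ok = _mention("p|SUB|K|227|M", count=2)
        kept, rejected = clean_mentions(noisy + [ok])
        assert {m.variant.serialize() for m in kept} == {"p|SUB|K|227|M"}
        assert all(r == REASON_FREQUENCY for _m, r in rejected)

    def test_alphabetic_position_rejected(self):
        kept, rejected = clean_mentions([_mention("p|SUB|K|22a|M")])
        assert rejected[0][1] == REASON_POSITION

    def test_zero_position_rejected(self):
        _kept, rejected = clean_mentions([_mention("p|SUB|K|0|M")])
        assert rejected[0][1] == REASON_POSITION

    def test_well_formed_kept(self):
        kept, rejected = clean_mentions([_mention("p|SUB|K|227|M", count=2)])
        assert len(kept) == 1 and rejected == []

    def test_rs_mentions_always_pass_field_rules(self):
        kept, _ = clean_mentions([_mention("SNP: rs4986790")])
        assert len(kept) == 1

    @pytest.mark.parametrize("form,required_ok", [
        ("c|DEL||76|", True),        # DEL: wild optional
        ("|DEL||76|", False),        # DEL: seq_level required
        ("c|INS||76|G", True),
        ("c|INS||76|", False),       # INS: mutant required
        ("p|FS|K|227|", True),
        ("p|FS||227|", False),       # FS: wild required
        ("c|INDEL||76|TT", True),
        ("c|INDEL||76|", False),
        ("c|DUP|A|76|", True),
        ("c|DUP|A||", False),        # DUP: position required
    ])
    def test_required_fields_per_operation(self, form, required_ok):
        kept, rejected = clean_mentions([_mention(form)])
        assert bool(kept) == required_ok

    def test_partition_and_no_false_rejects(self):
        mentions = [
            _mention("p|SUB|K|227|M"), _mention("|SUB|A||"),
            _mention("p|SUB|K|22a|M"), _mention("SNP: rs1"),
            _mention("c|DEL||76|"),
        ]
        kept, rejected = clean_mentions(mentions)
        assert len(kept) + len(rejected) == len(mentions)
        # re-running the rules on rejects never passes them
        for m, _r in rejected:
            k2, r2 = clean_mentions([m])
            assert k2 == []

    def test_duplicating_corpus_cannot_unreject(self):
        mentions = [_mention("c|SUB|A|7|C", doc_id=f"d{i}", count=30000) for i in range(2)]
        _k1, r1 = clean_mentions(mentions)
        doubled = mentions + [
            _mention("c|SUB|A|7|C", doc_id=f"e{i}", count=30000) for i in range(2)]
        _k2, r2 = clean_mentions(doubled)
        rejected_forms_1 = {m.variant.serialize() for m, _ in r1}
        rejected_forms_2 = {m.variant.serialize() for m, _ in r2}
        assert rejected_forms_1 <= rejected_forms_2


class TestCatalogValidation:
    def test_rs_and_tuple_matching(self):
        mentions = [_mention("SNP: rs1"), _mention("SNP: rs2"),
                    _mention("p|SUB|K|227|M"), _mention("p|SUB|Y|151|M")]
        catalog = [CatalogRecord(rs_id="rs1"),
                   CatalogRecord(seq_level="p", operation="SUB", wild="K",
                                 position="227", mutant="M")]
        validated, report = validate_against_catalog(mentions, catalog)
        assert report.n_rs == 2 and report.n_rs_validated == 1
        assert report.n_other == 2 and report.n_other_validated == 1
        assert report.n_total_validated == 2
        assert {m.variant.serialize() for m in validated} == {"SNP: rs1", "p|SUB|K|227|M"}

    def test_empty_catalog_warns_and_validates_nothing(self):
        with pytest.warns(UserWarning, match="empty"):
            validated, report = validate_against_catalog([_mention("SNP: rs1")], [])
        assert validated == [] and report.n_total_validated == 0

    def test_empty_mentions_fractions_not_applicable(self):
        _v, report = validate_against_catalog([], [CatalogRecord(rs_id="rs1")])
        assert report.rs_fraction is None and report.other_fraction is None


class TestMentionTableIO:
    def test_round_trip(self, tmp_path):
        mentions = [_mention("p|SUB|K|227|M", count=2),
                    _mention("SNP: rs4986790", doc_id="d2")]
        p = tmp_path / "mentions.tsv"
        write_mention_table(mentions, p)
        back = read_mention_table(p)
        assert [(m.doc_id, m.count, m.variant.serialize()) for m in back] == [
            ("d1", 2, "p|SUB|K|227|M"), ("d2", 1, "SNP: rs4986790")]

    def test_header_layout(self, tmp_path):
        p = tmp_path / "mentions.tsv"
        write_mention_table([_mention("p|SUB|K|227|M")], p)
        header = p.read_text().splitlines()[0].split("\t")
        assert header == ["PMID", "Mutation Mention", "Count", "Normalized Form", "Type"]
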