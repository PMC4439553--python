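"""Corpus data model and serialization round-trips."""

import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from connectomine.io import (
    CorpusFormatError,
    load_lexicon,
    read_corpus,
    write_corpus,
    _document_to_dict,
)
from connectomine.model import (
    CandidatePair,
    Corpus,
    CorpusValidationError,
    Document,
    LexiconSchemaError,
    Mention,
    Sentence,
)
from connectomine.synthetic import SynthConfig, generate_corpus


def corpus_fingerprint(corpus: Corpus):
    return [json.dumps(_document_to_dict(d), sort_keys=True) for d in corpus]


class TestJsonl:
    def test_round_trip_synthetic_corpus(self, small_corpus, tmp_path):
        path = tmp_path / "corpus.jsonl"
        write_corpus(small_corpus, path)
        back = read_corpus(path)
        assert corpus_fingerprint(back) == corpus_fingerprint(small_corpus)

    def test_unicode_text_preserved(self, tmp_path):
        text = "The nucleus raphé dorsalis was studied."
        doc = Document(doc_id="d1", text=text)
        doc.sentences = [Sentence(start=0, end=len(text))]
        doc.sentences[0].mentions = [
            Mention(start=4, end=26, surface=text[4:26])
        ]
        path = tmp_path / "u.jsonl"
        write_corpus(Corpus([doc]), path)
        back = read_corpus(path)
        assert back.documents[0].text == text
        assert back.documents[0].sentences[0].mentions[0].surface == "nucleus raphé dorsalis"

    def test_corpus_with_no_pairs_rereadable(self, tmp_path):
        doc = Document(doc_id="d1", text="Alpha beta.")
        doc.sentences = [Sentence(start=0, end=11)]
        path = tmp_path / "nopairs.jsonl"
        write_corpus(Corpus([doc]), path)
        back = read_corpus(path)
        assert len(back) == 1
        assert back.documents[0].sentences[0].pairs == []

    def test_empty_file_is_empty_corpus(self, tmp_path):
        path = tmp_path / "empty.jsonl"
        path.write_text("")
        assert len(read_corpus(path)) == 0

    def test_malformed_record_names_field(self, tmp_path):
        path = tmp_path / "bad.jsonl"
        path.write_text('{"text": "no id"}\n')
        with pytest.raises(CorpusFormatError, match="id"):
            read_corpus(path)

    def test_span_outside_text_rejected(self, tmp_path):
        record = {
            "id": "d1",
            "text": "short",
            "sentences": [{"span": [0, 50], "tokens": [], "mentions": [], "pairs": []}],
            "species": [],
        }
        path = tmp_path / "span.jsonl"
        path.write_text(json.dumps(record) + "\n")
        with pytest.raises(CorpusValidationError):
            read_corpus(path)

    def test_mention_surface_matches_text_slice_after_read(self, small_corpus, tmp_path):
        path = tmp_path / "c.jsonl"
        write_corpus(small_corpus, path)
        back = read_corpus(path)
        for doc, _si, sent in back.iter_sentences():
            for m in sent.mentions:
                assert doc.text[m.start : m.end] == m.surface

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_round_trip_identity_random_corpora(self, seed, tmp_path_factory):
        corpus = generate_corpus(SynthConfig(n_documents=3, seed=seed))
        path = tmp_path_factory.mktemp("rt") / "c.jsonl"
        write_corpus(corpus, path)
        assert corpus_fingerprint(read_corpus(path)) == corpus_fingerprint(corpus)


class TestAirolaXml:
    def test_hand_built_file(self, tmp_path):
        xml = """<?xml version="1.0" encoding="UTF-8"?>
<corpus source="toy">
 <document id="toy.d0" origId="pmid1">
  <sentence id="toy.d0.s0" text="The SNc projects to the striatum.">
   <entity id="toy.d0.s0.e0" charOffset="4-6" text="SNc" type="brain_region"/>
   <entity id="toy.d0.s0.e1" charOffset="24-31" text="striatum" type="brain_region"/>
   <pair id="toy.d0.s0.p0" e1="toy.d0.s0.e0" e2="toy.d0.s0.e1" interaction="True"/>
  </sentence>
 </document>
</corpus>
"""
        path = tmp_path / "toy.xml"
        path.write_text(xml)
        corpus = read_corpus(path, format="airola_xml")
        assert len(corpus) == 1
        sent = corpus.documents[0].sentences[0]
        assert [m.surface for m in sent.mentions] == ["SNc", "striatum"]
        assert len(sent.pairs) == 1
        assert sent.pairs[0].gold_label is True
        assert sent.pairs[0].mention_a.surface == "SNc"

    def test_round_trip_preserves_pairs_and_spans(self, small_corpus, tmp_path):
        path = tmp_path / "c.xml"
        write_corpus(small_corpus, path, format="airola_xml")
        back = read_corpus(path, format="airola_xml")
        assert len(back) == len(small_corpus)
        for orig, got in zip(small_corpus, back):
            assert got.doc_id == orig.doc_id
            assert got.text == orig.text
            for so, sg in zip(orig.sentences, got.sentences):
                assert [m.span for m in sg.mentions] == [m.span for m in so.mentions]
                assert [p.gold_label for p in sg.pairs] == [
                    bool(p.gold_label) for p in so.pairs
                ]

    def test_empty_file_is_empty_corpus(self, tmp_path):
        path = tmp_path / "e.xml"
        path.write_text("")
        assert len(read_corpus(path, format="airola_xml")) == 0

    def test_entity_text_offset_mismatch_rejected(self, tmp_path):
        xml = """<corpus source="toy"><document id="toy.d0" origId="p">
<sentence id="toy.d0.s0" text="The SNc projects.">
<entity id="toy.d0.s0.e0" charOffset="4-6" text="WRONG" type="brain_region"/>
</sentence></document></corpus>"""
        path = tmp_path / "bad.xml"
        path.write_text(xml)
        with pytest.raises(CorpusValidationError):
            read_corpus(path, format="airola_xml")


class TestCandidatePair:
    def test_mentions_ordered_by_start(self):
        a = Mention(start=10, end=14, surface="left")
        b = Mention(start=0, end=5, surface="right")
        pair = CandidatePair(mention_a=a, mention_b=b)
        assert pair.mention_a.start < pair.mention_b.start

    def test_identical_spans_rejected(self):
        a = Mention(start=0, end=5, surface="same")
        b = Mention(start=0, end=5, surface="same")
        with pytest.raises(CorpusValidationError):
            CandidatePair(mention_a=a, mention_b=b)


class TestLexicon:
    def _write(self, tmp_path, name, rows):
        path = tmp_path / name
        lines = ["concept_id\tname\tsource\tis_preferred"]
        lines += ["\t".join(r) for r in rows]
        path.write_text("\n".join(lines) + "\n")
        return path

    def test_rows_and_concepts_counted(self, tmp_path):
        path = self._write(
            tmp_path,
            "a.tsv",
            [
                ("C1", "dorsal raphe nucleus", "x", "true"),
                ("C1", "nucleus raphe dorsalis", "x", "false"),
                ("C2", "red nucleus", "x", "true"),
            ],
        )
        lex = load_lexicon(path)
        assert len(lex) == 3
        assert lex.concept_ids == ["C1", "C2"]

    def test_same_name_two_concepts_both_kept(self, tmp_path):
        p1 = self._write(tmp_path, "a.tsv", [("C1", "dentate nucleus", "a", "true")])
        p2 = self._write(tmp_path, "b.tsv", [("C2", "dentate nucleus", "b", "true")])
        lex = load_lexicon([p1, p2])
        assert sorted(lex.indexes["exact"]["dentate nucleus"]) == ["C1", "C2"]

    def test_is_preferred_flag(self, tmp_path):
        path = self._write(tmp_path, "a.tsv", [("C1", "red nucleus", "x", "true")])
        lex = load_lexicon(path)
        assert lex.entries[0].is_preferred is True
        assert lex.preferred_name("C1") == "red nucleus"

    def test_duplicate_rows_collapsed(self, tmp_path):
        path = self._write(
            tmp_path,
            "a.tsv",
            [("C1", "red nucleus", "x", "true"), ("C1", "red nucleus", "y", "false")],
        )
        assert len(load_lexicon(path)) == 1

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("concept_id\tname\nC1\tred nucleus\n")
        with pytest.raises(LexiconSchemaError):
            load_lexicon(path)

    def test_index_rebuild_is_deterministic(self, toy_lexicon):
        first = {k: dict(v) for k, v in toy_lexicon.indexes.items()}
        toy_lexicon.rebuild_indexes()
        second = {k: dict(v) for k, v in toy_lexicon.indexes.items()}
        assert first == second
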