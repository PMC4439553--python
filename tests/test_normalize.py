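"""Mention standardization cascade: ladder rungs and modifiers."""

import pytest

from connectomine.model import Lexicon, LexiconEntry
from connectomine.normalize import (
    DEFAULT_MODIFIERS,
    MatchResult,
    apply_modifiers,
    evaluate_normalization,
    get_modifiers,
    match_bag_of_stems,
    match_bag_of_words,
    match_exact,
    match_stem,
    normalize_mention,
)
from connectomine.stem import stem_phrase
from connectomine.synthetic import SynthConfig, corrupt_region_name
import numpy as np


@pytest.fixture(scope="module")
def lexicon():
    return Lexicon(
        [
            LexiconEntry("C1", "thalamic reticular nucleus", "x", True),
            LexiconEntry("C2", "dorsal raphe nucleus", "x", True),
            LexiconEntry("C2", "nucleus raphe dorsalis", "x", False),
            LexiconEntry("C3", "Substantia nigra pars compacta", "x", True),
            LexiconEntry("C4", "cochlear nucleus", "x", True),
        ]
    )


class TestLadderRungs:
    def test_exact_is_case_insensitive(self, lexicon):
        assert match_exact("substantia NIGRA pars compacta", lexicon) == ["C3"]

    def test_bag_of_words_ignores_order(self, lexicon):
        assert match_bag_of_words("reticular thalamic nucleus", lexicon) == ["C1"]

    def test_stem_rungs_depend_on_stemmer(self, lexicon):
        # oracle: brute-force the shipped stemmer over the fixture lexicon
        query = "nucleus raphé dorsalis"
        q_stems = stem_phrase(query)
        expected_stem = [
            e.concept_id
            for e in lexicon.entries
            if stem_phrase(e.name) == q_stems
        ]
        expected_bos = sorted(
            {
                e.concept_id
                for e in lexicon.entries
                if sorted(stem_phrase(e.name)) == sorted(q_stems)
            }
        )
        assert match_stem(query, lexicon) == expected_stem
        assert sorted(match_bag_of_stems(query, lexicon)) == expected_bos
        # the latinized form does not share stems with "dorsal raphe nucleus"
        # ("dorsali" != "dorsal") but does match its own synonym entry
        assert match_bag_of_stems(query, lexicon) == ["C2"]

    def test_unknown_string_misses_every_rung(self, lexicon):
        for matcher in (match_exact, match_bag_of_words, match_stem, match_bag_of_stems):
            assert matcher("flux capacitor", lexicon) == []


class TestCascade:
    def test_word_reorder_matches_at_bag_of_words(self, lexicon):
        r = normalize_mention("reticular thalamic nucleus", lexicon)
        assert r.concept_ids == ("C1",)
        assert r.match_stage == "bag_of_words"

    def test_case_variant_matches_at_exact(self, lexicon):
        r = normalize_mention("substantia nigra pars compacta", lexicon)
        assert r.match_stage == "exact"
        assert r.concept_ids == ("C3",)

    def test_hemisphere_qualifier_stripped(self, lexicon):
        r = normalize_mention("left dorsal raphe nucleus", lexicon)
        assert r.concept_ids == ("C2",)
        assert r.match_stage == "modified:strip_hemisphere_qualifiers"
        assert r.edited_text == "dorsal raphe nucleus"

    def test_contralateral_qualifier_stripped(self, lexicon):
        r = normalize_mention("contralateral cochlear nucleus", lexicon)
        assert r.concept_ids == ("C4",)

    def test_failure_is_empty_result(self, lexicon):
        r = normalize_mention("flux capacitor", lexicon)
        assert not r.matched
        assert r.match_stage is None

    def test_determinism(self, lexicon):
        a = normalize_mention("left dorsal raphe nucleus", lexicon)
        b = normalize_mention("left dorsal raphe nucleus", lexicon)
        assert a == b

    def test_every_lexicon_name_matches_itself_exactly(self, toy_lexicon):
        for entry in toy_lexicon.entries:
            r = normalize_mention(entry.name, toy_lexicon)
            assert r.match_stage == "exact"
            assert entry.concept_id in r.concept_ids

    def test_permuted_names_match_at_bag_of_words_or_earlier(self, toy_lexicon):
        rng = np.random.default_rng(3)
        multi = [e for e in toy_lexicon.entries if len(e.name.split()) > 1]
        for entry in multi:
            words = entry.name.split()
            perm = [words[i] for i in rng.permutation(len(words))]
            r = normalize_mention(" ".join(perm), toy_lexicon)
            assert r.matched
            assert r.match_stage in ("exact", "bag_of_words")
            assert entry.concept_id in r.concept_ids


class TestModifiers:
    def test_bracketed_text_removed(self):
        mods = get_modifiers(["strip_bracketed_text"])
        assert apply_modifiers("dorsal raphe (DR) nucleus", mods) == [
            "dorsal raphe nucleus"
        ]

    def test_hemisphere_words_removed(self):
        mods = get_modifiers(["strip_hemisphere_qualifiers"])
        assert apply_modifiers("contralateral cochlear nucleus", mods) == [
            "cochlear nucleus"
        ]

    def test_directional_prefix_removed_at_start_only(self):
        mods = get_modifiers(["strip_directional_prefixes"])
        assert apply_modifiers("lateral geniculate body", mods) == ["geniculate body"]
        # not at phrase start: untouched
        assert apply_modifiers("nucleus lateralis", mods) == ["nucleus lateralis"]

    def test_terminal_plural_singularized(self):
        mods = get_modifiers(["singularize_terminal_plural"])
        assert apply_modifiers("pontine nuclei", mods) == ["pontine nucleus"]
        assert apply_modifiers("mammillary bodies", mods) == ["mammillary body"]

    def test_untouched_text_yields_identical_sequence(self):
        out = apply_modifiers("hippocampus", DEFAULT_MODIFIERS)
        assert set(out) == {"hippocampus"}

    def test_edits_are_cumulative(self):
        out = apply_modifiers("left dorsal raphe (DR) nucleus", DEFAULT_MODIFIERS)
        assert "dorsal raphe nucleus" in out[1]  # after brackets + hemisphere
        assert out[2] == "raphe nucleus"  # directional prefix then stripped

    def test_modifiers_never_return_empty(self):
        mods = get_modifiers(["strip_hemisphere_qualifiers"])
        assert apply_modifiers("left", mods) == ["left"]

    def test_modifier_coverage_monotonicity(self, toy_lexicon):
        """Enabling modifiers never loses a match that the bare ladder found."""
        rng = np.random.default_rng(11)
        config = SynthConfig(
            n_documents=1, p_reorder=0.5, p_qualifier=0.5, p_bracket=0.5
        )
        names = toy_lexicon.all_names()
        with_mods = without_mods = 0
        for _ in range(200):
            name = names[int(rng.integers(len(names)))]
            variant, _ops = corrupt_region_name(name, config, rng)
            bare = normalize_mention(variant, toy_lexicon, modifiers=[])
            full = normalize_mention(variant, toy_lexicon)
            without_mods += bare.matched
            with_mods += full.matched
            if bare.matched:
                assert full.matched  # a modifier can only add coverage
        assert with_mods >= without_mods


class TestEvaluation:
    def test_hand_counted_coverage_precision_recall(self):
        gold = {f"m{i}": "C1" for i in range(10)}
        results = {}
        for i in range(10):
            if i < 5:  # correct matches
                results[f"m{i}"] = MatchResult(("C1",), "exact", "x")
            elif i == 5:  # wrong match
                results[f"m{i}"] = MatchResult(("C9",), "exact", "x")
            else:
                results[f"m{i}"] = MatchResult()
        report = evaluate_normalization(gold, results)
        assert report["coverage"] == 0.6
        assert report["precision"] == pytest.approx(5 / 6)
        assert report["recall"] == 0.5

    def test_all_correct(self):
        gold = {"a": "C1"}
        results = {"a": MatchResult(("C1",), "exact", "a")}
        report = evaluate_normalization(gold, results)
        assert report["precision"] == report["recall"] == report["coverage"] == 1.0

    def test_none_matched_precision_null(self):
        gold = {"a": "C1"}
        report = evaluate_normalization(gold, {"a": MatchResult()})
        assert report["coverage"] == 0.0
        assert report["precision"] is None

    def test_mismatched_keys_rejected(self):
        with pytest.raises(ValueError):
            evaluate_normalization({"a": "C1"}, {"b": MatchResult()})
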