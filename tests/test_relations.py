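"""Pair generation, entity blinding, the shallow linguistic kernel, SVM."""

import numpy as np
import pytest
from sklearn.svm import SVC

from connectomine.model import Mention, Sentence
from connectomine.preprocess import tokenize
from connectomine.relations import (
    BlindedInstance,
    ENTITY,
    OTHER_ENTITY,
    SlkConfig,
    TokenAttrs,
    blind_entities,
    cross_validate_relations,
    explicit_features,
    generate_pairs,
    sentence_length_by_decile,
    slk_features,
    slk_kernel,
    train_relation_classifier,
)
from connectomine.synthetic import SynthConfig, generate_corpus


def make_sentence(text, mention_spans):
    sent = Sentence(start=0, end=len(text), tokens=tokenize(text))
    sent.mentions = [
        Mention(start=s, end=e, surface=text[s:e]) for s, e in mention_spans
    ]
    return sent


def random_instance(rng, vocab=("project", "to", "the", "from", "via", "tract")):
    n = int(rng.integers(4, 12))
    tokens = [
        TokenAttrs(w, w, "x", "NOUN")
        for w in (vocab[int(rng.integers(len(vocab)))] for _ in range(n))
    ]
    ai, bi = sorted(rng.choice(n, size=2, replace=False))
    tokens[ai] = TokenAttrs(ENTITY, ENTITY, "ENT", "ENT")
    tokens[bi] = TokenAttrs(ENTITY, ENTITY, "ENT", "ENT")
    return BlindedInstance(tokens=tuple(tokens), entity_a_index=int(ai), entity_b_index=int(bi))


class TestGeneratePairs:
    def test_three_mentions_three_pairs(self):
        sent = make_sentence("alpha beta gamma", [(0, 5), (6, 10), (11, 16)])
        assert len(generate_pairs(sent)) == 3

    def test_single_mention_no_pairs(self):
        sent = make_sentence("alpha beta", [(0, 5)])
        assert generate_pairs(sent) == []

    def test_identical_surfaces_distinct_spans_pair(self):
        sent = make_sentence("caudate and caudate", [(0, 7), (12, 19)])
        pairs = generate_pairs(sent)
        assert len(pairs) == 1
        assert pairs[0].mention_a.span != pairs[0].mention_b.span

    def test_pair_count_combinatorial(self, small_corpus):
        for _doc, _si, sent in small_corpus.iter_sentences():
            m = len(sent.mentions)
            assert len(generate_pairs(sent)) == m * (m - 1) // 2


class TestBlinding:
    def test_simple_pair(self):
        text = "the SNc projects to the striatum"
        sent = make_sentence(text, [(4, 7), (24, 32)])
        pair = generate_pairs(sent)[0]
        inst = blind_entities(sent, pair)
        surfaces = [t.surface for t in inst.tokens]
        assert surfaces == ["the", ENTITY, "projects", "to", "the", ENTITY]
        assert inst.entity_a_index == 1
        assert inst.entity_b_index == 5

    def test_third_mention_becomes_other_placeholder(self):
        text = "alpha beta gamma"
        sent = make_sentence(text, [(0, 5), (6, 10), (11, 16)])
        pair = [
            p for p in generate_pairs(sent)
            if p.mention_a.start == 0 and p.mention_b.start == 6
        ][0]
        inst = blind_entities(sent, pair)
        assert [t.surface for t in inst.tokens] == [ENTITY, ENTITY, OTHER_ENTITY]

    def test_multi_token_mention_single_placeholder(self):
        text = "the dorsal raphe nucleus innervates the striatum"
        sent = make_sentence(text, [(4, 24), (40, 48)])
        inst = blind_entities(sent, generate_pairs(sent)[0])
        assert [t.surface for t in inst.tokens] == [
            "the", ENTITY, "innervates", "the", ENTITY,
        ]


class TestSlkFeatures:
    def test_between_window_unigrams(self):
        text = "SNc projects to striatum"
        sent = make_sentence(text, [(0, 3), (16, 24)])
        inst = blind_entities(sent, generate_pairs(sent)[0])
        feats = slk_features(inst)
        assert feats["global"]["g:B:project"] == 1
        assert feats["global"]["g:B:to"] == 1
        assert feats["global"]["g:B:project|to"] == 1

    def test_adjacent_entities_empty_between_window(self):
        text = "SNc striatum together"
        sent = make_sentence(text, [(0, 3), (4, 12)])
        inst = blind_entities(sent, generate_pairs(sent)[0])
        feats = slk_features(inst)
        assert not any(k.startswith("g:B:") for k in feats["global"])
        assert feats["local"]  # still a valid instance

    def test_identical_instances_identical_vectors(self, small_corpus):
        doc = small_corpus.documents[0]
        sent = [s for s in doc.sentences if len(s.mentions) >= 2][0]
        pair = generate_pairs(sent)[0]
        f1 = explicit_features(blind_entities(sent, pair))
        f2 = explicit_features(blind_entities(sent, pair))
        assert f1 == f2

    def test_blinding_order_invariance(self):
        """Swapping which mention is called A or B changes nothing."""
        text = "the SNc projects to the striatum"
        sent = make_sentence(text, [(4, 7), (24, 32)])
        pair = generate_pairs(sent)[0]
        from connectomine.model import CandidatePair

        swapped = CandidatePair(mention_a=pair.mention_b, mention_b=pair.mention_a)
        assert explicit_features(blind_entities(sent, pair)) == explicit_features(
            blind_entities(sent, swapped)
        )


class TestKernel:
    def test_self_kernel_is_two(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            x = random_instance(rng)
            assert slk_kernel(x, x) == pytest.approx(2.0, abs=1e-12)

    def test_kernel_equals_explicit_dot_product(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            x, y = random_instance(rng), random_instance(rng)
            fx, fy = explicit_features(x), explicit_features(y)
            dot = sum(v * fy.get(k, 0.0) for k, v in fx.items())
            assert slk_kernel(x, y) == pytest.approx(dot, abs=1e-9)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x, y = random_instance(rng), random_instance(rng)
            kxy, kyx = slk_kernel(x, y), slk_kernel(y, x)
            assert kxy == pytest.approx(kyx, abs=1e-12)
            assert -1e-12 <= kxy <= 2 + 1e-12

    def test_disjoint_features_give_zero(self):
        x = random_instance(np.random.default_rng(3), vocab=("alpha",))
        y = random_instance(np.random.default_rng(4), vocab=("omega",))
        # local shape/POS features may still overlap; compare global only
        fx, fy = slk_features(x), slk_features(y)
        shared = set(fx["global"]) & set(fy["global"])
        shared_grams = {k for k in shared if "alpha" in k or "omega" in k}
        assert not shared_grams

    def test_gram_matrix_positive_semidefinite(self):
        rng = np.random.default_rng(5)
        instances = [random_instance(rng) for _ in range(30)]
        gram = np.array(
            [[slk_kernel(a, b) for b in instances] for a in instances]
        )
        eigenvalues = np.linalg.eigvalsh(gram)
        assert eigenvalues.min() >= -1e-8


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(8)
    instances, labels = [], []
    for _ in range(60):
        positive = bool(rng.random() < 0.5)
        mid = (
            [TokenAttrs("project", "project", "x", "VERB"),
             TokenAttrs("to", "to", "x", "PREP")]
            if positive
            else [TokenAttrs("and", "and", "x", "CONJ")]
        )
        tokens = (
            [TokenAttrs("the", "the", "x", "DET"),
             TokenAttrs(ENTITY, ENTITY, "ENT", "ENT")]
            + mid
            + [TokenAttrs(ENTITY, ENTITY, "ENT", "ENT"),
               TokenAttrs(".", ".", "p", "PUNCT")]
        )
        instances.append(
            BlindedInstance(tuple(tokens), 1, len(tokens) - 2)
        )
        labels.append(positive)
    return instances, labels


class TestClassifier:

    def test_separable_data_fit_perfectly(self, separable):
        instances, labels = separable
        model = train_relation_classifier(instances, labels)
        _scores, preds = model.predict(instances)
        assert list(preds) == labels

    def test_same_seed_same_support_vectors(self, separable):
        instances, labels = separable
        m1 = train_relation_classifier(instances, labels, seed=1)
        m2 = train_relation_classifier(instances, labels, seed=1)
        assert (m1.svm.n_support_ == m2.svm.n_support_).all()

    def test_invalid_hyperparameter_rejected(self, separable):
        instances, labels = separable
        with pytest.raises(ValueError):
            train_relation_classifier(instances, labels, C=0)

    def test_single_class_rejected(self, separable):
        instances, _ = separable
        with pytest.raises(ValueError):
            train_relation_classifier(instances, [True] * len(instances))

    def test_explicit_features_reproduce_kernel_svm(self, separable):
        """Dual route: the linear SVM on explicit normalized blocks makes
        the same decisions as an SVM on the precomputed kernel matrix."""
        instances, labels = separable
        instances, labels = instances[:50], labels[:50]
        explicit_model = train_relation_classifier(instances, labels, C=1.0)
        _s, explicit_preds = explicit_model.predict(instances)
        gram = np.array(
            [[slk_kernel(a, b) for b in instances] for a in instances]
        )
        kernel_svm = SVC(kernel="precomputed", C=1.0).fit(gram, np.array(labels, int))
        kernel_preds = kernel_svm.decision_function(gram) > 0
        assert (explicit_preds == kernel_preds).all()


class TestCrossValidation:
    def test_every_pair_predicted_exactly_once(self, clean_corpus):
        result = cross_validate_relations(clean_corpus, k=5, seed=2)
        n_gold = sum(
            1
            for _d, _si, s in clean_corpus.iter_sentences()
            for p in s.pairs
            if p.gold_label is not None
        )
        assert len(result["ranked"]) == n_gold

    def test_same_seed_same_metrics(self, clean_corpus):
        a = cross_validate_relations(clean_corpus, k=5, seed=2)
        b = cross_validate_relations(clean_corpus, k=5, seed=2)
        assert a["pooled"].to_dict() == b["pooled"].to_dict()

    def test_templated_positives_recovered(self, clean_corpus):
        result = cross_validate_relations(clean_corpus, k=5, seed=2)
        pooled = result["pooled"]
        assert pooled.recall >= 0.8
        assert pooled.precision >= 0.8

    def test_length_report_has_deciles(self, clean_corpus):
        result = cross_validate_relations(clean_corpus, k=5, seed=2)
        deciles = result["length_by_decile"]
        assert len(deciles) == 10
        assert all(d > 0 for d in deciles)

    def test_decile_report_empty_input(self):
        assert sentence_length_by_decile([]) == []
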