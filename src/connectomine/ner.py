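"""Brain-region mention recognition as BIO sequence labeling.

Mentions are encoded per token as B (first token of a mention),
I (inside) or O (outside); a linear-chain CRF is trained over windowed
lexical features.  The most informative feature families — surrounding
words, word base forms (stems) and abbreviation expansions — are each
switchable in :class:`NerFeatureConfig`, with optional lexicon-lookup
flags and orthographic shape features.

Evaluation supports exact span matching and a partial regime in which
any character overlap counts, with greedy one-to-one assignment.
Cross-validation partitions *documents*, never sentences, so an
abstract is never split between training and testing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .crf import LinearChainCRF
from .metrics import Metrics, pool
from .model import Corpus, Document, Lexicon, Mention, Sentence
from .preprocess import extract_abbreviations, token_expansions
from .stem import stem_phrase

logger = logging.getLogger(__name__)

LABELS = ["O", "B", "I"]


@dataclass
class NerFeatureConfig:
    window: int = 2
    use_stems: bool = True
    use_abbrev_expansion: bool = True
    lexicon: Lexicon | None = None
    orthographic: bool = True

    def __post_init__(self) -> None:
        if self.window < 0:
            raise ValueError("window must be >= 0")


# ---------------------------------------------------------------------------
# BIO encoding


def _snap_to_tokens(sentence: Sentence, mention: Mention) -> tuple[int, int] | None:
    """Token index range [i, j) covering the mention, snapped outward."""
    idx = [
        i
        for i, tok in enumerate(sentence.tokens)
        if tok.start < mention.end and tok.end > mention.start
    ]
    if not idx:
        return None
    if (
        sentence.tokens[idx[0]].start != mention.start
        or sentence.tokens[idx[-1]].end != mention.end
    ):
        warnings.warn(
            f"mention {mention.surface!r} snapped outward to token boundaries",
            stacklevel=2,
        )
    return idx[0], idx[-1] + 1


def encode_bio(
    sentence: Sentence, gold_mentions: list[Mention] | None = None
) -> list[str]:
    """Per-token B/I/O labels for the sentence's (or given) mentions."""
    mentions = sentence.mentions if gold_mentions is None else gold_mentions
    labels = ["O"] * len(sentence.tokens)
    ranges = []
    for m in sorted(mentions, key=lambda m: m.start):
        r = _snap_to_tokens(sentence, m)
        if r is not None:
            ranges.append(r)
    prev_end = -1
    for lo, hi in ranges:
        if lo < prev_end:
            raise ValueError("overlapping gold mentions cannot be BIO-encoded")
        prev_end = hi
        labels[lo] = "B"
        for i in range(lo + 1, hi):
            labels[i] = "I"
    return labels


def decode_bio(sentence: Sentence, labels: list[str], document_text: str) -> list[Mention]:
    """BIO labels -> mention spans; an I after O (or at start) opens a
    new mention, the repair for illegal decoded sequences."""
    mentions: list[Mention] = []
    open_start: int | None = None
    open_end: int | None = None
    for tok, lab in zip(sentence.tokens, labels):
        if lab == "B" or (lab == "I" and open_start is None):
            if open_start is not None and lab == "B":
                mentions.append(_make_mention(open_start, open_end, document_text))
            open_start, open_end = tok.start, tok.end
        elif lab == "I":
            open_end = tok.end
        else:
            if open_start is not None:
                mentions.append(_make_mention(open_start, open_end, document_text))
                open_start = None
    if open_start is not None:
        mentions.append(_make_mention(open_start, open_end, document_text))
    return mentions


def _make_mention(start: int, end: int, text: str) -> Mention:
    return Mention(start=start, end=end, surface=text[start:end])


# ---------------------------------------------------------------------------
# Features


def _shape(surface: str) -> str:
    out = []
    for ch in surface:
        if ch.isupper():
            out.append("X")
        elif ch.islower():
            out.append("x")
        elif ch.isdigit():
            out.append("d")
        else:
            out.append("p")
    shape = "".join(out)
    # collapse runs so shapes generalize ("Xxxx" vs "Xx")
    collapsed = []
    for ch in shape:
        if not collapsed or collapsed[-1] != ch:
            collapsed.append(ch)
    return "".join(collapsed)


def _lexicon_token_flags(sentence: Sentence, lexicon: Lexicon) -> list[bool]:
    """True for tokens inside a longest dictionary match of any name."""
    flags = [False] * len(sentence.tokens)
    token_stems = [t.stem for t in sentence.tokens]
    name_stems = {tuple(stem_phrase(n)) for n in lexicon.all_names()}
    max_len = max((len(s) for s in name_stems), default=0)
    i = 0
    while i < len(token_stems):
        matched = 0
        for n in range(min(max_len, len(token_stems) - i), 0, -1):
            if tuple(token_stems[i : i + n]) in name_stems:
                matched = n
                break
        if matched:
            for j in range(i, i + matched):
                flags[j] = True
            i += matched
        else:
            i += 1
    return flags


def featurize_token(
    sentence: Sentence,
    index: int,
    config: NerFeatureConfig,
    expansions: dict[int, str] | None = None,
    lexicon_flags: list[bool] | None = None,
) -> list[str]:
    """String feature set for one token (position-tagged neighbors)."""
    feats = ["bias"]
    tokens = sentence.tokens
    for off in range(-config.window, config.window + 1):
        j = index + off
        tag = f"[{off:+d}]" if off else ""
        if j < 0:
            feats.append(f"BOS{tag}" if off else "BOS")
            continue
        if j >= len(tokens):
            feats.append(f"EOS{tag}" if off else "EOS")
            continue
        tok = tokens[j]
        feats.append(f"w{tag}={tok.surface.lower()}")
        if config.use_stems:
            feats.append(f"s{tag}={tok.stem}")
        if config.orthographic and off == 0:
            feats.append(f"shape={_shape(tok.surface)}")
            if tok.surface.isupper() and len(tok.surface) > 1:
                feats.append("allcaps")
            if tok.surface[:1].isupper():
                feats.append("initcap")
            if any(c.isdigit() for c in tok.surface):
                feats.append("hasdigit")
            if not tok.surface[:1].isalnum():
                feats.append("punct")
    if config.use_abbrev_expansion and expansions and index in expansions:
        for word in expansions[index].lower().split():
            feats.append(f"exp={word}")
        feats.append("has_expansion")
    if config.lexicon is not None and lexicon_flags is not None:
        if lexicon_flags[index]:
            feats.append("in_lexicon")
        if index > 0 and lexicon_flags[index - 1]:
            feats.append("in_lexicon[-1]")
        if index + 1 < len(lexicon_flags) and lexicon_flags[index + 1]:
            feats.append("in_lexicon[+1]")
    return feats


def _featurize_sentence(
    doc: Document,
    sentence: Sentence,
    config: NerFeatureConfig,
    abbrevs: list | None = None,
) -> list[list[str]]:
    expansions = None
    if config.use_abbrev_expansion:
        if abbrevs is None:
            abbrevs = extract_abbreviations(doc.text)
        expansions = token_expansions(sentence, abbrevs)
    flags = None
    if config.lexicon is not None:
        flags = _lexicon_token_flags(sentence, config.lexicon)
    return [
        featurize_token(sentence, i, config, expansions=expansions, lexicon_flags=flags)
        for i in range(len(sentence.tokens))
    ]


# ---------------------------------------------------------------------------
# Model


@dataclass
class NerModel:
    crf: LinearChainCRF
    config: NerFeatureConfig

    def save(self, path) -> None:
        import json
        from pathlib import Path

        d = self.crf.to_dict()
        d["ner_config"] = {
            "window": self.config.window,
            "use_stems": self.config.use_stems,
            "use_abbrev_expansion": self.config.use_abbrev_expansion,
            "orthographic": self.config.orthographic,
        }
        Path(path).write_text(json.dumps(d))

    @classmethod
    def load(cls, path) -> "NerModel":
        import json
        from pathlib import Path

        d = json.loads(Path(path).read_text())
        cfg = NerFeatureConfig(**d.pop("ner_config"))
        return cls(crf=LinearChainCRF.from_dict(d), config=cfg)


def train_ner(
    corpus: Corpus,
    config: NerFeatureConfig | None = None,
    c2: float = 1.0,
    max_iter: int = 200,
    seed: int = 0,
) -> NerModel:
    """Train the CRF on a corpus with gold mentions.

    Deterministic given data order; ``seed`` is accepted for interface
    symmetry with cross-validation but the optimizer itself is
    deterministic from a zero initialization.
    """
    config = config or NerFeatureConfig()
    sequences, labels = [], []
    n_mentions = 0
    for doc in corpus:
        abbrevs = extract_abbreviations(doc.text) if config.use_abbrev_expansion else []
        for sent in doc.sentences:
            if not sent.tokens:
                continue
            sequences.append(_featurize_sentence(doc, sent, config, abbrevs))
            labels.append(encode_bio(sent))
            n_mentions += len(sent.mentions)
    if not sequences:
        raise ValueError("corpus has no tokenized sentences")
    if n_mentions == 0:
        raise ValueError("corpus has no gold mentions to train on")
    crf = LinearChainCRF(LABELS, c2=c2, max_iter=max_iter)
    crf.fit(sequences, labels)
    return NerModel(crf=crf, config=config)


def predict_mentions(
    model: NerModel, sentence: Sentence, doc: Document
) -> list[Mention]:
    if not sentence.tokens:
        return []
    seq = _featurize_sentence(doc, sentence, model.config)
    labels = model.crf.predict([seq])[0]
    return decode_bio(sentence, labels, doc.text)


def predict_corpus(model: NerModel, corpus: Corpus) -> dict[tuple[str, int], list[Mention]]:
    """(doc_id, sentence index) -> predicted mentions, batch-decoded."""
    keys, sequences, sents, texts = [], [], [], []
    abbrev_cache: dict[str, list] = {}
    for doc, si, sent in corpus.iter_sentences():
        if not sent.tokens:
            continue
        if model.config.use_abbrev_expansion and doc.doc_id not in abbrev_cache:
            abbrev_cache[doc.doc_id] = extract_abbreviations(doc.text)
        keys.append((doc.doc_id, si))
        sequences.append(
            _featurize_sentence(doc, sent, model.config, abbrev_cache.get(doc.doc_id))
        )
        sents.append(sent)
        texts.append(doc.text)
    decoded = model.crf.predict(sequences)
    return {
        key: decode_bio(sent, labels, text)
        for key, sent, text, labels in zip(keys, sents, texts, decoded)
    }


# ---------------------------------------------------------------------------
# Evaluation


def _match_counts(
    gold: list[Mention], predicted: list[Mention], mode: str
) -> Metrics:
    if mode not in {"exact", "partial"}:
        raise ValueError("mode must be 'exact' or 'partial'")
    if mode == "exact":
        gold_spans = {m.span for m in gold}
        pred_spans = {m.span for m in predicted}
        tp = len(gold_spans & pred_spans)
        return Metrics(tp=tp, fp=len(pred_spans) - tp, fn=len(gold_spans) - tp)
    # partial: greedy one-to-one by overlap size, ties to leftmost
    candidates = []
    for gi, g in enumerate(gold):
        for pi, p in enumerate(predicted):
            overlap = min(g.end, p.end) - max(g.start, p.start)
            if overlap > 0:
                candidates.append((-overlap, min(g.start, p.start), gi, pi))
    candidates.sort()
    used_g: set[int] = set()
    used_p: set[int] = set()
    tp = 0
    for _neg, _left, gi, pi in candidates:
        if gi in used_g or pi in used_p:
            continue
        used_g.add(gi)
        used_p.add(pi)
        tp += 1
    return Metrics(tp=tp, fp=len(predicted) - tp, fn=len(gold) - tp)


def evaluate_ner(
    gold: list[Mention] | dict,
    predicted: list[Mention] | dict,
    mode: str = "exact",
) -> Metrics:
    """Span-level metrics; pass dicts keyed by sentence to pool across
    sentences, or plain lists for mentions of a single sentence."""
    if isinstance(gold, dict) or isinstance(predicted, dict):
        keys = set(gold) | set(predicted)
        return pool(
            [
                _match_counts(gold.get(k, []), predicted.get(k, []), mode)
                for k in sorted(keys)
            ]
        )
    return _match_counts(gold, predicted, mode)


def assign_folds(n_documents: int, k: int, seed: int) -> np.ndarray:
    """Uniform random partition of document indices into k folds."""
    if k > n_documents:
        raise ValueError(f"k={k} exceeds number of documents ({n_documents})")
    rng = np.random.default_rng(seed)
    folds = np.arange(n_documents) % k
    rng.shuffle(folds)
    return folds


def cross_validate_ner(
    corpus: Corpus,
    k: int = 8,
    config: NerFeatureConfig | None = None,
    seed: int = 0,
    c2: float = 1.0,
    max_iter: int = 200,
) -> dict:
    """Abstract-level k-fold cross-validation.

    Returns per-fold and pooled metrics for both exact and partial
    matching; pooled numbers are micro-averages over the concatenated
    held-out predictions.
    """
    config = config or NerFeatureConfig()
    folds = assign_folds(len(corpus), k, seed)
    per_fold = {"exact": [], "partial": []}
    for fold in range(k):
        train_docs = [d for d, f in zip(corpus.documents, folds) if f != fold]
        test_docs = [d for d, f in zip(corpus.documents, folds) if f == fold]
        model = train_ner(Corpus(train_docs), config, c2=c2, max_iter=max_iter)
        predictions = predict_corpus(model, Corpus(test_docs))
        gold = {
            (doc.doc_id, si): sent.mentions
            for doc, si, sent in Corpus(test_docs).iter_sentences()
        }
        for mode in ("exact", "partial"):
            per_fold[mode].append(evaluate_ner(gold, predictions, mode))
        logger.info("fold %d: exact %s", fold, per_fold["exact"][-1].to_dict())
    return {
        "folds": folds,
        "per_fold": per_fold,
        "pooled": {mode: pool(ms) for mode, ms in per_fold.items()},
    }
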