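"""Connected / not-connected classification of mention pairs.

A candidate is two brain-region mentions in one sentence.  Following
the shallow-linguistic-kernel approach from protein–protein interaction
extraction, no parse tree is used: the two candidate entities are
*blinded* to placeholder tokens and the classifier sees

* a **global context** kernel — counts of stem n-grams (n <= 3) in the
  fore-between, between, and between-after token windows, and
* a **local context** kernel — position-tagged token attributes
  (surface, stem, shape, coarse POS) in a +/-2 window around each
  entity.

Each block is L2-normalized and the two are summed, so K(x, x) = 2 for
any instance with non-empty blocks.  Training uses an SVM on the
explicit normalized feature representation, whose linear kernel is
exactly the summed normalized kernel; decision scores are exposed for
confidence ranking.  The relation is undirected (no efferent/afferent
distinction): both placeholders map to one symbol, so predictions are
invariant under swapping the two entities.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from sklearn.feature_extraction import DictVectorizer
from sklearn.svm import SVC

from .metrics import Metrics, pool
from .model import CandidatePair, Corpus, Document, Sentence
from .ner import assign_folds

logger = logging.getLogger(__name__)

ENTITY = "entityx"        # blinded symbol for both candidate entities
OTHER_ENTITY = "entityo"  # other region mentions in the sentence


@dataclass(frozen=True)
class TokenAttrs:
    surface: str
    stem: str
    shape: str
    coarse_pos: str


@dataclass(frozen=True)
class BlindedInstance:
    tokens: tuple[TokenAttrs, ...]
    entity_a_index: int
    entity_b_index: int

    def __post_init__(self) -> None:
        n = len(self.tokens)
        if not (0 <= self.entity_a_index < self.entity_b_index < n):
            raise ValueError("entity indexes invalid or out of order")


@dataclass
class SlkConfig:
    ngram_max: int = 3
    local_window: int = 2


# ---------------------------------------------------------------------------
# Pair generation and blinding

_DETERMINERS = {"the", "a", "an", "this", "that", "these", "those", "each", "both"}
_PREPOSITIONS = {
    "of", "in", "to", "from", "with", "within", "between", "into", "onto",
    "through", "via", "at", "on", "by", "for", "upon", "toward", "towards",
}
_CONJUNCTIONS = {"and", "or", "but", "nor", "while", "whereas"}
_VERBS = {
    "is", "are", "was", "were", "be", "been", "has", "have", "had",
    "send", "sends", "sent", "receive", "receives", "received",
}


def coarse_pos(surface: str) -> str:
    """Rule-based coarse part-of-speech from shape and suffix — a shallow
    stand-in for a full tagger, enough for local-context features."""
    w = surface.lower()
    if not surface[:1].isalnum():
        return "PUNCT"
    if surface.isdigit():
        return "NUM"
    if w in _DETERMINERS:
        return "DET"
    if w in _PREPOSITIONS:
        return "PREP"
    if w in _CONJUNCTIONS:
        return "CONJ"
    if w in _VERBS or w.endswith(("ates", "ized", "izes", "ects", "ifies")):
        return "VERB"
    if w.endswith(("ing", "ed")):
        return "VPART"
    if w.endswith(("al", "ic", "ous", "ar", "ive")):
        return "ADJ"
    if w.endswith("ly"):
        return "ADV"
    return "NOUN"


def generate_pairs(sentence: Sentence) -> list[CandidatePair]:
    """All unordered pairs of distinct mentions, by textual order."""
    mentions = sorted(sentence.mentions, key=lambda m: (m.start, m.end))
    pairs = []
    for i in range(len(mentions)):
        for j in range(i + 1, len(mentions)):
            pairs.append(CandidatePair(mention_a=mentions[i], mention_b=mentions[j]))
    return pairs


def _shape(surface: str) -> str:
    from .ner import _shape as shape

    return shape(surface)


def blind_entities(
    sentence: Sentence, pair: CandidatePair, document_text: str | None = None
) -> BlindedInstance:
    """Collapse each mention of the pair to a single placeholder token.

    Other region mentions in the sentence become a distinct placeholder
    so the classifier can see that competing regions are present.
    """
    a, b = pair.mention_a, pair.mention_b
    if a.end > b.start:
        raise ValueError("pair mentions overlap; cannot blind")
    others = [
        m
        for m in sentence.mentions
        if m.span != a.span and m.span != b.span
    ]
    covered = sorted(
        [(a.start, a.end, ENTITY), (b.start, b.end, ENTITY)]
        + [(m.start, m.end, OTHER_ENTITY) for m in others]
    )
    tokens: list[TokenAttrs] = []
    a_idx = b_idx = -1
    emitted_for_span: set[tuple[int, int]] = set()
    for tok in sentence.tokens:
        inside = None
        for s, e, sym in covered:
            if tok.start >= s and tok.end <= e:
                inside = (s, e, sym)
                break
        if inside is None:
            tokens.append(
                TokenAttrs(
                    surface=tok.surface.lower(),
                    stem=tok.stem,
                    shape=_shape(tok.surface),
                    coarse_pos=coarse_pos(tok.surface),
                )
            )
            continue
        s, e, sym = inside
        if (s, e) in emitted_for_span:
            continue  # further tokens of a multi-token mention
        emitted_for_span.add((s, e))
        tokens.append(TokenAttrs(surface=sym, stem=sym, shape="ENT", coarse_pos="ENT"))
        if (s, e) == (a.start, a.end):
            a_idx = len(tokens) - 1
        elif (s, e) == (b.start, b.end):
            b_idx = len(tokens) - 1
    if a_idx < 0 or b_idx < 0:
        raise ValueError("pair mentions do not align to sentence tokens")
    return BlindedInstance(
        tokens=tuple(tokens), entity_a_index=a_idx, entity_b_index=b_idx
    )


# ---------------------------------------------------------------------------
# Shallow linguistic kernel features


def _ngrams(stems: list[str], n_max: int) -> Counter:
    counts: Counter = Counter()
    for n in range(1, n_max + 1):
        for i in range(len(stems) - n + 1):
            counts["|".join(stems[i : i + n])] += 1
    return counts


def slk_features(
    instance: BlindedInstance, config: SlkConfig | None = None
) -> dict[str, Counter]:
    """Raw (unnormalized) global and local feature counts."""
    config = config or SlkConfig()
    stems = [t.stem for t in instance.tokens]
    ai, bi = instance.entity_a_index, instance.entity_b_index
    between = stems[ai + 1 : bi]
    fore_between = stems[:ai] + between
    between_after = between + stems[bi + 1 :]
    global_counts: Counter = Counter()
    for window_name, window in (
        ("FB", fore_between),
        ("B", between),
        ("BA", between_after),
    ):
        for gram, count in _ngrams(window, config.ngram_max).items():
            global_counts[f"g:{window_name}:{gram}"] += count
    local_counts: Counter = Counter()
    for ei in (ai, bi):
        for off in range(-config.local_window, config.local_window + 1):
            if off == 0:
                continue
            j = ei + off
            if not (0 <= j < len(instance.tokens)):
                continue
            tok = instance.tokens[j]
            local_counts[f"l:{off:+d}:w:{tok.surface}"] += 1
            local_counts[f"l:{off:+d}:s:{tok.stem}"] += 1
            local_counts[f"l:{off:+d}:sh:{tok.shape}"] += 1
            local_counts[f"l:{off:+d}:p:{tok.coarse_pos}"] += 1
    return {"global": global_counts, "local": local_counts}


def _normalize_block(counts: Counter) -> dict[str, float]:
    norm = math.sqrt(sum(v * v for v in counts.values()))
    if norm == 0:
        return {}
    return {k: v / norm for k, v in counts.items()}


def explicit_features(
    instance: BlindedInstance, config: SlkConfig | None = None
) -> dict[str, float]:
    """L2-normalized global block + L2-normalized local block, whose
    plain dot product equals :func:`slk_kernel`."""
    raw = slk_features(instance, config)
    out = _normalize_block(raw["global"])
    out.update(_normalize_block(raw["local"]))
    return out


def _dot(x: Counter, y: Counter) -> float:
    if len(y) < len(x):
        x, y = y, x
    return float(sum(v * y[k] for k, v in x.items() if k in y))


def slk_kernel(
    x: BlindedInstance, y: BlindedInstance, config: SlkConfig | None = None
) -> float:
    """Sum of the normalized global and local sub-kernels; K(x, x) = 2
    for any instance with non-empty global and local blocks."""
    fx = slk_features(x, config)
    fy = slk_features(y, config)
    total = 0.0
    for block in ("global", "local"):
        num = _dot(fx[block], fy[block])
        den = math.sqrt(_dot(fx[block], fx[block]) * _dot(fy[block], fy[block]))
        if den > 0:
            total += num / den
    return total


# ---------------------------------------------------------------------------
# SVM on explicit features


def _as_int32_csr(X):
    X = X.tocsr()
    X.indices = X.indices.astype(np.int32)
    X.indptr = X.indptr.astype(np.int32)
    return X


@dataclass
class RelationModel:
    vectorizer: DictVectorizer
    svm: SVC
    config: SlkConfig

    def decision_scores(self, instances: list[BlindedInstance]) -> np.ndarray:
        X = self.vectorizer.transform(
            [explicit_features(inst, self.config) for inst in instances]
        )
        return self.svm.decision_function(_as_int32_csr(X))

    def predict(self, instances: list[BlindedInstance], threshold: float = 0.0):
        scores = self.decision_scores(instances)
        return scores, scores > threshold


def train_relation_classifier(
    instances: list[BlindedInstance],
    labels: list[bool],
    C: float = 1.0,
    seed: int = 0,
    config: SlkConfig | None = None,
) -> RelationModel:
    if C <= 0:
        raise ValueError("C must be positive")
    if len(set(labels)) < 2:
        raise ValueError("training data must contain both classes")
    config = config or SlkConfig()
    vectorizer = DictVectorizer(sparse=True)
    X = vectorizer.fit_transform(
        [explicit_features(inst, config) for inst in instances]
    )
    svm = SVC(kernel="linear", C=C, random_state=seed)
    svm.fit(_as_int32_csr(X), np.asarray(labels, dtype=int))
    return RelationModel(vectorizer=vectorizer, svm=svm, config=config)


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass
class RankedPrediction:
    doc_id: str
    sentence_index: int
    pair: CandidatePair
    score: float
    predicted: bool
    gold: bool
    sentence_tokens: int


def _corpus_instances(documents) -> list[tuple[str, int, Sentence, CandidatePair, BlindedInstance]]:
    out = []
    for doc in documents:
        for si, sent in enumerate(doc.sentences):
            for pair in sent.pairs:
                if pair.gold_label is None:
                    continue
                out.append((doc.doc_id, si, sent, pair, blind_entities(sent, pair)))
    return out


def cross_validate_relations(
    corpus: Corpus,
    k: int = 10,
    seed: int = 0,
    C: float = 1.0,
    config: SlkConfig | None = None,
    threshold: float = 0.0,
) -> dict:
    """Document-partitioned k-fold CV over gold-labeled pairs.

    Returns pooled metrics over the concatenated held-out predictions
    and a score-ranked prediction list for confidence inspection.
    """
    folds = assign_folds(len(corpus), k, seed)
    doc_fold = {doc.doc_id: f for doc, f in zip(corpus.documents, folds)}
    records = _corpus_instances(corpus.documents)
    per_fold: list[Metrics] = []
    ranked: list[RankedPrediction] = []
    for fold in range(k):
        train = [r for r in records if doc_fold[r[0]] != fold]
        test = [r for r in records if doc_fold[r[0]] == fold]
        if not test:
            per_fold.append(Metrics())
            continue
        labels = [r[3].gold_label for r in train]
        model = train_relation_classifier(
            [r[4] for r in train], labels, C=C, seed=seed, config=config
        )
        scores, preds = model.predict([r[4] for r in test], threshold)
        tp = fp = fn = 0
        for (doc_id, si, sent, pair, _inst), score, pred in zip(test, scores, preds):
            pair.score = float(score)
            pair.predicted = bool(pred)
            if pred and pair.gold_label:
                tp += 1
            elif pred:
                fp += 1
            elif pair.gold_label:
                fn += 1
            ranked.append(
                RankedPrediction(
                    doc_id=doc_id,
                    sentence_index=si,
                    pair=pair,
                    score=float(score),
                    predicted=bool(pred),
                    gold=bool(pair.gold_label),
                    sentence_tokens=len(sent.tokens),
                )
            )
        per_fold.append(Metrics(tp=tp, fp=fp, fn=fn))
        logger.info("relation fold %d: %s", fold, per_fold[-1].to_dict())
    ranked.sort(key=lambda r: -r.score)
    return {
        "folds": folds,
        "per_fold": per_fold,
        "pooled": pool(per_fold),
        "ranked": ranked,
        "length_by_decile": sentence_length_by_decile(ranked),
    }


def sentence_length_by_decile(ranked: list[RankedPrediction]) -> list[float]:
    """Mean sentence length (tokens) per score decile, best decile first.

    Longer sentences drifting to the low-confidence end indicates the
    expected difficulty gradient with sentence complexity.
    """
    if not ranked:
        return []
    lengths = np.array([r.sentence_tokens for r in ranked], dtype=float)
    deciles = np.array_split(lengths, min(10, len(lengths)))
    return [float(d.mean()) for d in deciles]
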