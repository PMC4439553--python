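"""Rank abstracts by similarity to a connectivity-positive training set.

A Bernoulli Naïve Bayes over binary presence/absence features — title
and abstract words, journal name, MeSH terms (kept as opaque strings,
qualifiers included) — with add-one smoothing.  An abstract's score is
the class log-prior plus the sum of per-feature log-likelihood ratios
of the features *present* in it; the per-feature ratios are exposed so
the most class-discriminative words can be inspected.  This mirrors the
MScanner-style triage step that filters PubMed-scale input down to
abstracts likely to contain connectivity statements before the
extraction pipeline runs.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

_WORD = re.compile(r"\w+", re.UNICODE)

FEATURE_FAMILIES = ("words", "journal", "mesh")


@dataclass
class AbstractRecord:
    doc_id: str
    text: str                 # title + abstract
    journal: str = ""
    mesh_terms: list[str] = field(default_factory=list)


def record_features(record: AbstractRecord, flags: dict[str, bool]) -> set[str]:
    feats: set[str] = set()
    if flags.get("words", True):
        feats.update(f"w:{w.lower()}" for w in _WORD.findall(record.text))
    if flags.get("journal", True) and record.journal:
        feats.add(f"j:{record.journal.lower()}")
    if flags.get("mesh", True):
        feats.update(f"m:{t.lower()}" for t in record.mesh_terms)
    return feats


@dataclass
class NBModel:
    llr: dict[str, float]     # per-feature log-likelihood ratio
    prior: float              # log(n_pos / n_bg)
    flags: dict[str, bool]

    def top_features(self, n: int = 20) -> list[tuple[str, float]]:
        return sorted(self.llr.items(), key=lambda kv: -kv[1])[:n]


def train_triage(
    positives: list[AbstractRecord],
    background: list[AbstractRecord],
    feature_flags: dict[str, bool] | None = None,
) -> NBModel:
    """Fit presence/absence log-likelihood ratios with add-one smoothing.

    For feature f: llr(f) = log[(df_pos + 1)/(n_pos + 2)] -
    log[(df_bg + 1)/(n_bg + 2)], df being document frequency.
    """
    if not positives or not background:
        raise ValueError("both positive and background sets must be non-empty")
    flags = dict(feature_flags or {f: True for f in FEATURE_FAMILIES})
    pos_sets = [record_features(r, flags) for r in positives]
    bg_sets = [record_features(r, flags) for r in background]
    vocab = set().union(*pos_sets, *bg_sets)
    if not vocab:
        raise ValueError("no features enabled or present in the training data")
    n_pos, n_bg = len(positives), len(background)
    df_pos: dict[str, int] = {}
    df_bg: dict[str, int] = {}
    for s in pos_sets:
        for f in s:
            df_pos[f] = df_pos.get(f, 0) + 1
    for s in bg_sets:
        for f in s:
            df_bg[f] = df_bg.get(f, 0) + 1
    llr = {
        f: math.log((df_pos.get(f, 0) + 1) / (n_pos + 2))
        - math.log((df_bg.get(f, 0) + 1) / (n_bg + 2))
        for f in vocab
    }
    return NBModel(llr=llr, prior=math.log(n_pos / n_bg), flags=flags)


def score_abstract(model: NBModel, record: AbstractRecord) -> float:
    """Class prior plus summed ratios of the present known features;
    duplicate words count once (Bernoulli presence)."""
    feats = record_features(record, model.flags)
    return model.prior + sum(model.llr[f] for f in feats if f in model.llr)


def rank_abstracts(
    model: NBModel, records: list[AbstractRecord]
) -> list[tuple[AbstractRecord, float]]:
    scored = [(r, score_abstract(model, r)) for r in records]
    scored.sort(key=lambda rs: -rs[1])
    return scored
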