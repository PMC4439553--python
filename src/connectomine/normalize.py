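"""Standardize brain-region mention strings to lexicon concepts.

Matching is a four-rung ladder of decreasing stringency:

1. **exact** — case-insensitive full-string equality;
2. **bag_of_words** — equality of lowercase word multisets, so
   "reticular thalamic nucleus" matches "thalamic reticular nucleus";
3. **stem_exact** — equality after Porter stemming each word;
4. **bag_of_stems** — equality of stem multisets.

Every rung requires *all* words or stems of the mention to match the
lexicon name.  If the ladder fails on the raw text, mention-editing
modifiers (strip bracketed text, hemisphere qualifiers, directional
prefixes, ...) are applied cumulatively in registry order, re-running
the full ladder after each edit that changed the string.  Each modifier
sacrifices some information, so earlier matches are preferred and the
stage at which a mention matched is recorded.

Ambiguity — several concepts tied at the winning rung — is returned,
not resolved: choosing among atlases or species is downstream work.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Iterable

from .metrics import Metrics
from .model import Lexicon
from .stem import fold_diacritics, stem_phrase

_WORD = re.compile(r"\w+", re.UNICODE)

LADDER = ["exact", "bag_of_words", "stem_exact", "bag_of_stems"]


@dataclass(frozen=True)
class MatchResult:
    concept_ids: tuple[str, ...] = ()
    match_stage: str | None = None
    edited_text: str = ""

    def __post_init__(self) -> None:
        if bool(self.concept_ids) != (self.match_stage is not None):
            raise ValueError("match_stage must be present iff concept_ids non-empty")

    @property
    def matched(self) -> bool:
        return bool(self.concept_ids)

    @property
    def ambiguous(self) -> bool:
        return len(self.concept_ids) > 1


@dataclass(frozen=True)
class Modifier:
    name: str
    transform: Callable[[str], str]
    order: int

    def __call__(self, text: str) -> str:
        edited = self.transform(text)
        edited = re.sub(r"\s+", " ", edited).strip()
        return edited if edited else text  # never hand back an empty string


# ---------------------------------------------------------------------------
# Ladder rungs


def match_exact(text: str, lexicon: Lexicon) -> list[str]:
    return list(lexicon.indexes["exact"].get(text.lower(), []))


def match_bag_of_words(text: str, lexicon: Lexicon) -> list[str]:
    words = _WORD.findall(fold_diacritics(text.lower()))
    if not words:
        return []
    return list(lexicon.indexes["bow"].get(tuple(sorted(words)), []))


def match_stem(text: str, lexicon: Lexicon) -> list[str]:
    stems = stem_phrase(text)
    if not stems:
        return []
    return list(lexicon.indexes["stem"].get(" ".join(stems), []))


def match_bag_of_stems(text: str, lexicon: Lexicon) -> list[str]:
    stems = stem_phrase(text)
    if not stems:
        return []
    return list(lexicon.indexes["bos"].get(tuple(sorted(stems)), []))


_RUNGS: list[tuple[str, Callable[[str, Lexicon], list[str]]]] = [
    ("exact", match_exact),
    ("bag_of_words", match_bag_of_words),
    ("stem_exact", match_stem),
    ("bag_of_stems", match_bag_of_stems),
]


def _run_ladder(text: str, lexicon: Lexicon) -> tuple[str, list[str]] | None:
    for stage, matcher in _RUNGS:
        ids = matcher(text, lexicon)
        if ids:
            return stage, ids
    return None


# ---------------------------------------------------------------------------
# Modifiers

_HEMISPHERE = {"left", "right", "ipsilateral", "contralateral", "bilateral"}
_DIRECTIONAL = {
    "anterior", "posterior", "dorsal", "ventral",
    "medial", "lateral", "rostral", "caudal",
}


def _strip_bracketed(text: str) -> str:
    return re.sub(r"\s*[(\[][^()\[\]]*[)\]]", "", text)


def _strip_hemisphere(text: str) -> str:
    words = text.split()
    kept = [w for w in words if w.lower().strip(",") not in _HEMISPHERE]
    return " ".join(kept)


def _strip_directional_prefix(text: str) -> str:
    words = text.split()
    i = 0
    while i < len(words) and words[i].lower() in _DIRECTIONAL:
        i += 1
    return " ".join(words[i:]) if i < len(words) else text


def _strip_parenthetical_abbrev(text: str) -> str:
    # a trailing standalone short all-caps token left over after bracket
    # stripping, e.g. "dorsal raphe nucleus DR"
    return re.sub(r"\s+[A-Z][A-Z0-9]{1,9}$", "", text)


def _collapse_whitespace_punct(text: str) -> str:
    return re.sub(r"[-,;:/]+", " ", text)


def _singularize_terminal_plural(text: str) -> str:
    words = text.split()
    if not words:
        return text
    last = words[-1]
    lowered = last.lower()
    if lowered.endswith("nuclei"):
        last = last[:-1] + "us"
    elif lowered.endswith("ies") and len(lowered) > 4:
        last = last[:-3] + "y"
    elif lowered.endswith("s") and not lowered.endswith(("ss", "us", "is")):
        last = last[:-1]
    return " ".join(words[:-1] + [last])


DEFAULT_MODIFIERS: list[Modifier] = [
    Modifier("strip_bracketed_text", _strip_bracketed, 1),
    Modifier("strip_hemisphere_qualifiers", _strip_hemisphere, 2),
    Modifier("strip_directional_prefixes", _strip_directional_prefix, 3),
    Modifier("strip_parenthetical_abbrev", _strip_parenthetical_abbrev, 4),
    Modifier("collapse_whitespace_punct", _collapse_whitespace_punct, 5),
    Modifier("singularize_terminal_plural", _singularize_terminal_plural, 6),
]

_REGISTRY: dict[str, Modifier] = {m.name: m for m in DEFAULT_MODIFIERS}


def register_modifier(modifier: Modifier) -> None:
    """Add a custom mention editor to the registry (extensible design:
    the original cascade used twelve; six concrete ones ship here)."""
    _REGISTRY[modifier.name] = modifier


def get_modifiers(names: Iterable[str] | None = None) -> list[Modifier]:
    if names is None:
        return sorted(_REGISTRY.values(), key=lambda m: m.order)
    return [_REGISTRY[n] for n in names]


def apply_modifiers(text: str, modifiers: list[Modifier]) -> list[str]:
    """Successive cumulative edits (one entry per modifier, in order)."""
    out = []
    current = text
    for mod in modifiers:
        current = mod(current)
        out.append(current)
    return out


# ---------------------------------------------------------------------------
# Cascade


def normalize_mention(
    text: str,
    lexicon: Lexicon,
    modifiers: list[Modifier] | None = None,
) -> MatchResult:
    """Run the ladder on the raw text, then retry after each cumulative
    modifier edit; stop at the first rung with at least one concept."""
    if not text or not text.strip():
        return MatchResult()
    if modifiers is None:
        modifiers = DEFAULT_MODIFIERS
    hit = _run_ladder(text, lexicon)
    if hit is not None:
        stage, ids = hit
        return MatchResult(tuple(ids), stage, text)
    tried = {text}
    current = text
    for mod in modifiers:
        current = mod(current)
        if current in tried:  # edit changed nothing new: skip the ladder
            continue
        tried.add(current)
        hit = _run_ladder(current, lexicon)
        if hit is not None:
            stage, ids = hit
            return MatchResult(tuple(ids), f"modified:{mod.name}", current)
    return MatchResult()


def normalize_corpus(corpus, lexicon: Lexicon, modifiers=None) -> dict:
    """Normalize every mention in place; returns per-stage counts."""
    stage_counts: dict[str, int] = {}
    for _doc, _si, sent in corpus.iter_sentences():
        for m in sent.mentions:
            result = normalize_mention(m.expanded or m.surface, lexicon, modifiers)
            if result.matched and not result.ambiguous:
                m.concept_id = result.concept_ids[0]
            m.match_stage = result.match_stage
            key = result.match_stage or "unmatched"
            stage_counts[key] = stage_counts.get(key, 0) + 1
    return stage_counts


# ---------------------------------------------------------------------------
# Evaluation


def evaluate_normalization(
    gold: dict[str, str], results: dict[str, MatchResult]
) -> dict:
    """Coverage, precision, recall, and per-stage counts.

    ``gold`` maps a mention string to its true concept id; a matched
    mention counts as correct when the gold concept is among the
    returned ids.  Precision is null when nothing matched.
    """
    if set(gold) != set(results):
        raise ValueError("gold and results must be keyed identically")
    total = len(gold)
    matched = 0
    correct = 0
    stage_counts: dict[str, int] = {}
    for key, result in results.items():
        stage = result.match_stage or "unmatched"
        stage_counts[stage] = stage_counts.get(stage, 0) + 1
        if result.matched:
            matched += 1
            if gold[key] in result.concept_ids:
                correct += 1
    return {
        "total": total,
        "matched": matched,
        "correct": correct,
        "coverage": matched / total if total else None,
        "precision": correct / matched if matched else None,
        "recall": correct / total if total else None,
        "per_stage": stage_counts,
        "metrics": Metrics(tp=correct, fp=matched - correct, fn=total - correct),
    }
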