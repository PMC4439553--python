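"""Sentence splitting, tokenization, abbreviation handling, species tagging.

Abbreviation definitions of the form ``long form (SF)`` are detected
with the Schwartz–Hearst character-alignment algorithm and applied at
document scope: every standalone occurrence of a defined short form in
any sentence of the abstract is annotated with its long form.  Text is
never rewritten — expansion is an annotation layer, which matters
because later stages work sentence-by-sentence and would otherwise lose
definitions given in earlier sentences.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .model import Document, Mention, Sentence, SpeciesTag, Token
from .stem import fold_diacritics, porter_stem

logger = logging.getLogger(__name__)

# abbreviations that must not terminate a sentence
_NON_FINAL = {
    "e.g", "i.e", "cf", "vs", "et al", "fig", "figs", "ref", "refs",
    "approx", "ca", "no", "nos", "sp", "spp", "resp", "al",
}

_SENT_BOUNDARY = re.compile(r"[.!?]+(?=\s+|$)")
_TOKEN = re.compile(r"\w+|[^\w\s]", re.UNICODE)
_WORD = re.compile(r"\w+", re.UNICODE)


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Spans of sentences, splitting at sentence-final punctuation.

    Splits at ``. ! ?`` followed by whitespace, except after known
    non-final abbreviations ("e.g.", "et al.", single initials) or when
    the next alphabetic character is lowercase.  Returned spans are
    trimmed of surrounding whitespace, ordered and non-overlapping, and
    jointly cover all non-whitespace text.
    """
    if not text:
        return []
    spans: list[tuple[int, int]] = []
    start = 0
    for match in _SENT_BOUNDARY.finditer(text):
        end = match.end()
        if end < len(text):
            preceding = text[start : match.start()]
            last_word = preceding.rsplit(None, 1)[-1].lower() if preceding.split() else ""
            last_word = last_word.lstrip("([\"'")
            if last_word in _NON_FINAL:
                continue
            if last_word and "." in last_word[:-1]:  # internal dots: "e.g", "i.v"
                continue
            follow = text[end:].lstrip()
            if follow and follow[0].islower():
                continue
        piece = text[start:end]
        lstrip = len(piece) - len(piece.lstrip())
        rstrip = len(piece) - len(piece.rstrip())
        if piece.strip():
            spans.append((start + lstrip, end - rstrip))
        start = end
    tail = text[start:]
    if tail.strip():
        lstrip = len(tail) - len(tail.lstrip())
        rstrip = len(tail) - len(tail.rstrip())
        spans.append((start + lstrip, len(text) - rstrip))
    return spans


def tokenize(sentence_text: str, offset: int = 0) -> list[Token]:
    """Split on whitespace and punctuation; punctuation marks (including
    hyphens inside words like "cortico-thalamic") are their own tokens.

    Each token carries a Porter stem of its diacritic-folded lowercase
    surface; ``offset`` shifts spans into document coordinates.
    """
    tokens = []
    for match in _TOKEN.finditer(sentence_text):
        surface = match.group()
        tokens.append(
            Token(
                start=offset + match.start(),
                end=offset + match.end(),
                surface=surface,
                stem=porter_stem(surface) if _WORD.fullmatch(surface) else surface.lower(),
            )
        )
    return tokens


# ---------------------------------------------------------------------------
# Schwartz–Hearst abbreviation detection


@dataclass(frozen=True)
class Abbreviation:
    short_form: str
    long_form: str
    start: int  # span of the parenthesized short form
    end: int


def _valid_short_form(sf: str) -> bool:
    if not (2 <= len(sf) <= 10):
        return False
    if not sf[0].isalnum():
        return False
    if not any(ch.isalpha() for ch in sf):
        return False
    if len(sf.split()) > 2:
        return False
    return True


def _best_long_form(sf: str, candidate: str) -> str | None:
    """Shortest suffix of ``candidate`` in which every character of the
    short form appears in order, the first one at the start of a word."""
    s_index = len(sf) - 1
    l_index = len(candidate) - 1
    while s_index >= 0:
        ch = sf[s_index].lower()
        if not ch.isalnum():
            s_index -= 1
            continue
        while l_index >= 0 and (
            candidate[l_index].lower() != ch
            or (s_index == 0 and l_index > 0 and candidate[l_index - 1].isalnum())
        ):
            l_index -= 1
        if l_index < 0:
            return None
        s_index -= 1
        l_index -= 1
    l_index = candidate.rfind(" ", 0, l_index + 1) + 1
    return candidate[l_index:]


def extract_abbreviations(document_text: str) -> list[Abbreviation]:
    """Find ``long form (SF)`` definitions in a document."""
    out: list[Abbreviation] = []
    for match in re.finditer(r"\(([^()]+)\)", document_text):
        sf = match.group(1).strip()
        if not _valid_short_form(sf):
            continue
        before = document_text[: match.start()].rstrip()
        # candidate long form: up to min(|SF|+5, |SF|*2) preceding words,
        # not crossing a sentence boundary
        limit = min(len(sf) + 5, len(sf) * 2)
        words = before.split()
        candidate = " ".join(words[-limit:]) if words else ""
        candidate = candidate.split(". ")[-1]
        if not candidate:
            continue
        long_form = _best_long_form(sf, candidate)
        if long_form is None:
            continue
        long_form = long_form.strip(" ,;:")
        if not long_form or len(long_form) <= len(sf):
            continue
        if sf.lower() in long_form.lower().split():
            continue
        if len(long_form.split()) > limit:
            continue
        out.append(
            Abbreviation(
                short_form=sf,
                long_form=long_form,
                start=match.start(),
                end=match.end(),
            )
        )
    return out


_warned_conflicts: set[tuple[str, str, str]] = set()


def abbreviation_map(abbrevs: list[Abbreviation]) -> dict[str, str]:
    """Short form -> long form; conflicting later definitions are dropped."""
    mapping: dict[str, str] = {}
    for ab in abbrevs:
        if ab.short_form in mapping:
            key = (ab.short_form, mapping[ab.short_form], ab.long_form)
            if mapping[ab.short_form] != ab.long_form and key not in _warned_conflicts:
                _warned_conflicts.add(key)
                logger.warning(
                    "conflicting definitions for %r: keeping %r, ignoring %r",
                    ab.short_form, mapping[ab.short_form], ab.long_form,
                )
            continue
        mapping[ab.short_form] = ab.long_form
    return mapping


def token_expansions(
    sentence: Sentence, abbrevs: list[Abbreviation]
) -> dict[int, str]:
    """Token index -> long form, for standalone short-form tokens."""
    mapping = abbreviation_map(abbrevs)
    out: dict[int, str] = {}
    if not mapping:
        return out
    for i, tok in enumerate(sentence.tokens):
        if tok.surface in mapping:
            out[i] = mapping[tok.surface]
    return out


def expand_abbreviations(
    sentence: Sentence, abbrevs: list[Abbreviation]
) -> Sentence:
    """Annotate mentions whose surface is a defined short form.

    Spans are unchanged; only ``Mention.expanded`` is set.  A mention
    is expanded only when its surface equals a short form exactly
    (token-standalone, so "SNC" inside "SNCA" is untouched).
    """
    mapping = abbreviation_map(abbrevs)
    for m in sentence.mentions:
        if m.surface in mapping:
            m.expanded = mapping[m.surface]
    return sentence


# ---------------------------------------------------------------------------
# Species tagging


def load_species_lexicon(path: str | Path | None = None) -> dict[str, str]:
    """name (lowercase) -> NCBI-style taxon id.

    With no path, the bundled table of common laboratory species is used.
    """
    import pandas as pd

    if path is None:
        with resources.as_file(
            resources.files("connectomine.data") / "species.tsv"
        ) as p:
            frame = pd.read_csv(p, sep="\t", dtype=str)
    else:
        frame = pd.read_csv(path, sep="\t", dtype=str)
    if "name" not in frame.columns or "taxon_id" not in frame.columns:
        raise ValueError("species lexicon needs columns: name, taxon_id")
    return {
        str(row.name_).lower(): str(row.taxon_id)
        for row in frame.rename(columns={"name": "name_"}).itertuples(index=False)
    }


def tag_species(
    document: Document, species_lexicon: dict[str, str]
) -> list[SpeciesTag]:
    """Case-insensitive longest-match dictionary tagging over the text.

    Matches respect word boundaries; overlapping candidates resolve to
    the longest (then leftmost) match, so "rhesus monkey" wins over
    "monkey".  Returned tags are sorted and non-overlapping.
    """
    text_lower = document.text.lower()
    candidates: list[tuple[int, int, str, str]] = []
    for name, taxon_id in species_lexicon.items():
        start = 0
        while True:
            idx = text_lower.find(name, start)
            if idx == -1:
                break
            end = idx + len(name)
            left_ok = idx == 0 or not text_lower[idx - 1].isalnum()
            right_ok = end == len(text_lower) or not text_lower[end].isalnum()
            if left_ok and right_ok:
                candidates.append((idx, end, name, taxon_id))
            start = idx + 1
    # longest match first, then leftmost
    candidates.sort(key=lambda c: (-(c[1] - c[0]), c[0]))
    chosen: list[tuple[int, int, str, str]] = []
    for cand in candidates:
        if all(cand[1] <= c[0] or cand[0] >= c[1] for c in chosen):
            chosen.append(cand)
    chosen.sort()
    return [
        SpeciesTag(start=s, end=e, name=document.text[s:e], taxon_id=tid)
        for s, e, _name, tid in chosen
    ]


def preprocess_document(
    doc: Document, species_lexicon: dict[str, str] | None = None
) -> Document:
    """Populate sentences, tokens, abbreviation annotations and species."""
    doc.sentences = [
        Sentence(start=s, end=e, tokens=tokenize(doc.text[s:e], offset=s))
        for s, e in split_sentences(doc.text)
    ]
    abbrevs = extract_abbreviations(doc.text)
    for sent in doc.sentences:
        expand_abbreviations(sent, abbrevs)
    if species_lexicon is not None:
        doc.species = tag_species(doc, species_lexicon)
    return doc
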