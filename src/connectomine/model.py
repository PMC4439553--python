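"""Domain types for annotated connectivity corpora.

A :class:`Corpus` holds :class:`Document` objects — abstracts with their
title, written as ``title + " " + abstract`` in a single coordinate
system.  All spans are 0-based, half-open character intervals into
``Document.text``.  Sentences carry tokens, brain-region mentions and
candidate mention pairs (the unit classified as connected / not
connected); documents carry species tags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator


class CorpusValidationError(ValueError):
    """A span or structural invariant of the corpus data model is violated."""


class LexiconSchemaError(ValueError):
    """A lexicon file does not have the required columns."""


@dataclass
class Token:
    start: int
    end: int
    surface: str
    stem: str
    bio_label: str | None = None  # one of B, I, O when set


@dataclass
class Mention:
    """A contiguous span of text referring to a brain region.

    ``expanded`` is the abbreviation-expanded form and equals ``surface``
    unless the surface is a defined short form.  ``concept_id`` and
    ``match_stage`` are filled by normalization.
    """

    start: int
    end: int
    surface: str
    expanded: str = ""
    concept_id: str | None = None
    match_stage: str | None = None

    def __post_init__(self) -> None:
        if not self.expanded:
            self.expanded = self.surface

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class CandidatePair:
    """Two mentions co-occurring in one sentence.

    ``mention_a`` precedes ``mention_b`` in text.  The relation is
    undirected: no efferent/afferent distinction is represented.
    """

    mention_a: Mention
    mention_b: Mention
    gold_label: bool | None = None
    score: float | None = None
    predicted: bool | None = None

    def __post_init__(self) -> None:
        if self.mention_a.span == self.mention_b.span:
            raise CorpusValidationError("pair mentions must have distinct spans")
        if self.mention_a.start > self.mention_b.start:
            self.mention_a, self.mention_b = self.mention_b, self.mention_a


@dataclass
class SpeciesTag:
    start: int
    end: int
    name: str
    taxon_id: str


@dataclass
class Sentence:
    start: int
    end: int
    tokens: list[Token] = field(default_factory=list)
    mentions: list[Mention] = field(default_factory=list)
    pairs: list[CandidatePair] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def text(self, document_text: str) -> str:
        return document_text[self.start : self.end]


@dataclass
class Document:
    doc_id: str
    text: str
    sentences: list[Sentence] = field(default_factory=list)
    species: list[SpeciesTag] = field(default_factory=list)

    def validate(self) -> None:
        n = len(self.text)
        prev_end = 0
        for si, sent in enumerate(self.sentences):
            if not (0 <= sent.start < sent.end <= n):
                raise CorpusValidationError(
                    f"{self.doc_id}: sentence {si} span {sent.span} outside text"
                )
            if sent.start < prev_end:
                raise CorpusValidationError(
                    f"{self.doc_id}: sentence {si} overlaps previous sentence"
                )
            prev_end = sent.end
            tok_end = sent.start
            for tok in sent.tokens:
                if not (sent.start <= tok.start < tok.end <= sent.end):
                    raise CorpusValidationError(
                        f"{self.doc_id}: token span {tok.start, tok.end} outside "
                        f"sentence {si}"
                    )
                if tok.start < tok_end:
                    raise CorpusValidationError(
                        f"{self.doc_id}: overlapping tokens in sentence {si}"
                    )
                tok_end = tok.end
                if self.text[tok.start : tok.end] != tok.surface:
                    raise CorpusValidationError(
                        f"{self.doc_id}: token surface {tok.surface!r} does not "
                        f"match text slice"
                    )
            for m in sent.mentions:
                if not (sent.start <= m.start < m.end <= sent.end):
                    raise CorpusValidationError(
                        f"{self.doc_id}: mention span {m.span} outside sentence {si}"
                    )
                if self.text[m.start : m.end] != m.surface:
                    raise CorpusValidationError(
                        f"{self.doc_id}: mention surface {m.surface!r} does not "
                        f"match text slice {self.text[m.start:m.end]!r}"
                    )
        for tag in self.species:
            if not (0 <= tag.start < tag.end <= n):
                raise CorpusValidationError(
                    f"{self.doc_id}: species span outside text"
                )
            if not tag.taxon_id:
                raise CorpusValidationError(f"{self.doc_id}: species tag lacks taxon id")


@dataclass
class Corpus:
    documents: list[Document] = field(default_factory=list)

    def validate(self) -> None:
        seen: set[str] = set()
        for doc in self.documents:
            if doc.doc_id in seen:
                raise CorpusValidationError(f"duplicate doc_id {doc.doc_id}")
            seen.add(doc.doc_id)
            doc.validate()

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self) -> Iterator[Document]:
        return iter(self.documents)

    def iter_sentences(self) -> Iterator[tuple[Document, int, Sentence]]:
        for doc in self.documents:
            for si, sent in enumerate(doc.sentences):
                yield doc, si, sent


# ---------------------------------------------------------------------------
# Lexicon


@dataclass(frozen=True)
class LexiconEntry:
    concept_id: str
    name: str
    source: str = ""
    is_preferred: bool = False


class Lexicon:
    """Concept id <-> name/synonym table with matching indexes.

    Indexes (exact form, bag of words, stemmed form, bag of stems) are
    built lazily and deterministically from entry order; lookups return
    concept ids sorted by first appearance in the entry list.
    """

    def __init__(self, entries: list[LexiconEntry] | None = None):
        self.entries: list[LexiconEntry] = []
        self._seen: set[tuple[str, str]] = set()
        self._indexes: dict[str, dict] | None = None
        for e in entries or []:
            self.add(e)

    def add(self, entry: LexiconEntry) -> None:
        key = (entry.concept_id, entry.name)
        if key in self._seen:
            return
        self._seen.add(key)
        self.entries.append(entry)
        self._indexes = None

    @property
    def concept_ids(self) -> list[str]:
        out, seen = [], set()
        for e in self.entries:
            if e.concept_id not in seen:
                seen.add(e.concept_id)
                out.append(e.concept_id)
        return out

    def names(self, concept_id: str) -> list[str]:
        return [e.name for e in self.entries if e.concept_id == concept_id]

    def preferred_name(self, concept_id: str) -> str:
        names = [e.name for e in self.entries if e.concept_id == concept_id]
        pref = [e.name for e in self.entries
                if e.concept_id == concept_id and e.is_preferred]
        if pref:
            return pref[0]
        if not names:
            raise KeyError(concept_id)
        return names[0]

    # -- matching indexes ---------------------------------------------------

    def _build_indexes(self) -> dict[str, dict]:
        from .stem import fold_diacritics, stem_phrase

        exact: dict[str, list[str]] = {}
        bow: dict[tuple[str, ...], list[str]] = {}
        stem_exact: dict[str, list[str]] = {}
        bos: dict[tuple[str, ...], list[str]] = {}

        def put(index: dict, key, cid: str) -> None:
            bucket = index.setdefault(key, [])
            if cid not in bucket:
                bucket.append(cid)

        import re

        for e in self.entries:
            lowered = e.name.lower()
            put(exact, lowered, e.concept_id)
            words = re.findall(r"\w+", fold_diacritics(lowered), re.UNICODE)
            if words:
                put(bow, tuple(sorted(words)), e.concept_id)
            stems = stem_phrase(e.name)
            if stems:
                put(stem_exact, " ".join(stems), e.concept_id)
                put(bos, tuple(sorted(stems)), e.concept_id)
        return {"exact": exact, "bow": bow, "stem": stem_exact, "bos": bos}

    @property
    def indexes(self) -> dict[str, dict]:
        if self._indexes is None:
            self._indexes = self._build_indexes()
        return self._indexes

    def rebuild_indexes(self) -> None:
        self._indexes = None

    def all_names(self) -> list[str]:
        return [e.name for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)
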