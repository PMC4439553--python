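"""Readers and writers for corpora and lexicons.

Two corpus serializations are supported:

* **JSONL** — the canonical format: one document per line with all
  annotation layers (sentences, tokens, mentions, pairs, species).
* **AirolaXML** — the interchange format used by protein–protein
  interaction benchmarks, carried over here for relation corpora.  It
  stores sentences, entities and labeled pairs only (no tokens or
  species), with *inclusive* character offsets local to the sentence and
  ids namespaced ``corpus.dN.sN.eN``.

Lexicons are 4-column TSV (``concept_id  name  source  is_preferred``)
with a header row, merged across files in order.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd
from lxml import etree

from .model import (
    CandidatePair,
    Corpus,
    CorpusValidationError,
    Document,
    Lexicon,
    LexiconEntry,
    LexiconSchemaError,
    Mention,
    Sentence,
    SpeciesTag,
    Token,
)


class CorpusFormatError(ValueError):
    """Malformed corpus file; the message names the document and field."""


# ---------------------------------------------------------------------------
# JSONL


def _mention_to_dict(m: Mention) -> dict:
    d: dict = {"span": [m.start, m.end], "surface": m.surface, "expanded": m.expanded}
    if m.concept_id is not None:
        d["concept_id"] = m.concept_id
    if m.match_stage is not None:
        d["match_stage"] = m.match_stage
    return d


def _document_to_dict(doc: Document) -> dict:
    sentences = []
    for sent in doc.sentences:
        mention_index = {id(m): i for i, m in enumerate(sent.mentions)}
        pairs = []
        for p in sent.pairs:
            pd_: dict = {
                "a": mention_index[id(p.mention_a)],
                "b": mention_index[id(p.mention_b)],
            }
            if p.gold_label is not None:
                pd_["gold_label"] = p.gold_label
            if p.score is not None:
                pd_["score"] = p.score
            if p.predicted is not None:
                pd_["predicted"] = p.predicted
            pairs.append(pd_)
        sentences.append(
            {
                "span": [sent.start, sent.end],
                "tokens": [
                    {
                        "span": [t.start, t.end],
                        "surface": t.surface,
                        "stem": t.stem,
                        **({"bio": t.bio_label} if t.bio_label else {}),
                    }
                    for t in sent.tokens
                ],
                "mentions": [_mention_to_dict(m) for m in sent.mentions],
                "pairs": pairs,
            }
        )
    return {
        "id": doc.doc_id,
        "text": doc.text,
        "sentences": sentences,
        "species": [
            {"span": [s.start, s.end], "name": s.name, "taxon_id": s.taxon_id}
            for s in doc.species
        ],
    }


def _document_from_dict(d: dict) -> Document:
    try:
        doc = Document(doc_id=str(d["id"]), text=d["text"])
    except KeyError as exc:
        raise CorpusFormatError(f"document record missing field {exc}") from exc
    for si, sd in enumerate(d.get("sentences", [])):
        try:
            sent = Sentence(start=sd["span"][0], end=sd["span"][1])
            for td in sd.get("tokens", []):
                sent.tokens.append(
                    Token(
                        start=td["span"][0],
                        end=td["span"][1],
                        surface=td["surface"],
                        stem=td["stem"],
                        bio_label=td.get("bio"),
                    )
                )
            for md in sd.get("mentions", []):
                sent.mentions.append(
                    Mention(
                        start=md["span"][0],
                        end=md["span"][1],
                        surface=md["surface"],
                        expanded=md.get("expanded", ""),
                        concept_id=md.get("concept_id"),
                        match_stage=md.get("match_stage"),
                    )
                )
            for pdict in sd.get("pairs", []):
                sent.pairs.append(
                    CandidatePair(
                        mention_a=sent.mentions[pdict["a"]],
                        mention_b=sent.mentions[pdict["b"]],
                        gold_label=pdict.get("gold_label"),
                        score=pdict.get("score"),
                        predicted=pdict.get("predicted"),
                    )
                )
        except (KeyError, IndexError, TypeError) as exc:
            raise CorpusFormatError(
                f"doc {d.get('id')}: malformed sentence {si}: {exc!r}"
            ) from exc
        doc.sentences.append(sent)
    for spd in d.get("species", []):
        doc.species.append(
            SpeciesTag(
                start=spd["span"][0],
                end=spd["span"][1],
                name=spd["name"],
                taxon_id=spd["taxon_id"],
            )
        )
    return doc


def read_corpus(path: str | Path, format: str = "jsonl") -> Corpus:
    """Read a corpus, validating all character offsets against the text."""
    path = Path(path)
    if format == "jsonl":
        corpus = Corpus()
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    record = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusFormatError(f"line {lineno}: invalid JSON") from exc
                corpus.documents.append(_document_from_dict(record))
        corpus.validate()
        return corpus
    if format == "airola_xml":
        return _read_airola(path)
    raise ValueError(f"unknown corpus format {format!r}")


def write_corpus(corpus: Corpus, path: str | Path, format: str = "jsonl") -> None:
    corpus.validate()
    path = Path(path)
    if format == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for doc in corpus:
                fh.write(json.dumps(_document_to_dict(doc), ensure_ascii=False))
                fh.write("\n")
        return
    if format == "airola_xml":
        _write_airola(corpus, path)
        return
    raise ValueError(f"unknown corpus format {format!r}")


# ---------------------------------------------------------------------------
# AirolaXML


def _write_airola(corpus: Corpus, path: Path, corpus_id: str = "corpus") -> None:
    root = etree.Element("corpus", source=corpus_id)
    for di, doc in enumerate(corpus):
        delem = etree.SubElement(
            root, "document", id=f"{corpus_id}.d{di}", origId=doc.doc_id
        )
        for si, sent in enumerate(doc.sentences):
            sid = f"{corpus_id}.d{di}.s{si}"
            selem = etree.SubElement(
                delem, "sentence", id=sid, text=sent.text(doc.text),
                charOffset=f"{sent.start}-{sent.end - 1}",
            )
            eids = {}
            for ei, m in enumerate(sent.mentions):
                eid = f"{sid}.e{ei}"
                eids[id(m)] = eid
                # offsets are sentence-local and inclusive, per the PPI dialect
                etree.SubElement(
                    selem, "entity", id=eid, origId=eid,
                    charOffset=f"{m.start - sent.start}-{m.end - 1 - sent.start}",
                    text=m.surface, type="brain_region",
                )
            for pi, p in enumerate(sent.pairs):
                etree.SubElement(
                    selem, "pair", id=f"{sid}.p{pi}",
                    e1=eids[id(p.mention_a)], e2=eids[id(p.mention_b)],
                    interaction=str(bool(p.gold_label)),
                )
    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True)


def _read_airola(path: Path) -> Corpus:
    from .preprocess import tokenize

    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        # an empty file is an empty corpus, not an error
        if path.stat().st_size == 0:
            return Corpus()
        raise CorpusFormatError(f"{path}: not well-formed XML: {exc}") from exc
    corpus = Corpus()
    for delem in tree.getroot().iter("document"):
        doc_id = delem.get("origId") or delem.get("id")
        if doc_id is None:
            raise CorpusFormatError("document element lacks id/origId")
        pieces: list[str] = []
        sentences: list[Sentence] = []
        offset = 0
        for selem in delem.iter("sentence"):
            text = selem.get("text")
            if text is None:
                raise CorpusFormatError(f"doc {doc_id}: sentence lacks text attribute")
            if pieces:
                offset += 1  # single space between sentences
            start = offset
            pieces.append(text)
            offset += len(text)
            sent = Sentence(start=start, end=offset)
            entity_by_id: dict[str, Mention] = {}
            for eelem in selem.iter("entity"):
                off = eelem.get("charOffset", "")
                try:
                    lo_s, hi_s = off.split("-")[0], off.rsplit("-", 1)[-1]
                    lo, hi = int(lo_s), int(hi_s)
                except ValueError as exc:
                    raise CorpusFormatError(
                        f"doc {doc_id}: bad charOffset {off!r}"
                    ) from exc
                m = Mention(
                    start=start + lo,
                    end=start + hi + 1,
                    surface=text[lo : hi + 1],
                )
                if eelem.get("text") is not None and eelem.get("text") != m.surface:
                    raise CorpusValidationError(
                        f"doc {doc_id}: entity text {eelem.get('text')!r} does not "
                        f"match offset slice {m.surface!r}"
                    )
                entity_by_id[eelem.get("id")] = m
                sent.mentions.append(m)
            for pelem in selem.iter("pair"):
                try:
                    a = entity_by_id[pelem.get("e1")]
                    b = entity_by_id[pelem.get("e2")]
                except KeyError as exc:
                    raise CorpusFormatError(
                        f"doc {doc_id}: pair references unknown entity {exc}"
                    ) from exc
                label = (pelem.get("interaction") or "").lower() == "true"
                sent.pairs.append(
                    CandidatePair(mention_a=a, mention_b=b, gold_label=label)
                )
            sentences.append(sent)
        doc = Document(doc_id=doc_id, text=" ".join(pieces), sentences=sentences)
        for sent in doc.sentences:
            sent.tokens = tokenize(sent.text(doc.text), offset=sent.start)
        corpus.documents.append(doc)
    corpus.validate()
    return corpus


# ---------------------------------------------------------------------------
# Lexicon TSV

_LEXICON_COLUMNS = ["concept_id", "name", "source", "is_preferred"]


def load_lexicon(paths: Iterable[str | Path] | str | Path) -> Lexicon:
    """Merge one or more lexicon TSV files, preserving file order.

    Duplicate (concept_id, name) rows collapse to the first occurrence;
    the same name filed under different concept ids is kept under both —
    the ambiguity surfaces at match time.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    lexicon = Lexicon()
    for path in paths:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        missing = [c for c in _LEXICON_COLUMNS if c not in frame.columns]
        if missing:
            raise LexiconSchemaError(f"{path}: missing column(s) {missing}")
        for row in frame.itertuples(index=False):
            lexicon.add(
                LexiconEntry(
                    concept_id=row.concept_id,
                    name=row.name,
                    source=row.source,
                    is_preferred=str(row.is_preferred).strip().lower()
                    in {"true", "1", "yes"},
                )
            )
    return lexicon
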