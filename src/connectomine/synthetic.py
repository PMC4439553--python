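"""Fully annotated synthetic abstracts for end-to-end testing.

Each generated document is a templated abstract: a title mentioning a
region, a species sentence, optionally an abbreviation-defining
sentence ("<region> (<SF>)"), then content sentences that either state
a connection between two regions ("X projects to Y" and kin) or merely
co-mention two regions.  Every layer of gold annotation — sentence and
token spans, BIO-consistent mention spans, concept ids, abbreviation
expansions, species tags, and positive/negative pair labels — is
recorded at generation time, so recognizers and classifiers can be
scored without any external corpus.

Region surface forms are optionally corrupted with the lexical
variation the normalization cascade is meant to undo: word reordering,
prepended hemisphere qualifiers, appended bracketed abbreviations.

Templates are deliberately easier than real prose; evaluations on this
corpus demonstrate recovery of planted structure, not performance on
real text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .io import load_lexicon
from .model import (
    CandidatePair,
    Corpus,
    Document,
    Lexicon,
    Mention,
    Sentence,
    SpeciesTag,
)
from .preprocess import extract_abbreviations, load_species_lexicon, tokenize

_HEMISPHERE_QUALIFIERS = ["left", "right", "ipsilateral", "contralateral", "bilateral"]


def load_toy_lexicon() -> Lexicon:
    """~50 mammalian brain-region concepts with a few synonyms."""
    with resources.as_file(resources.files("connectomine.data") / "regions.tsv") as p:
        return load_lexicon(p)


def load_connective_phrases() -> list[str]:
    text = (resources.files("connectomine.data") / "connectives.txt").read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]


@dataclass
class SynthConfig:
    n_documents: int = 100
    region_lexicon: Lexicon | None = None
    connective_phrases: list[str] | None = None
    p_connective_sentence: float = 0.2
    p_abbreviation: float = 0.3
    p_reorder: float = 0.1
    p_qualifier: float = 0.1
    p_bracket: float = 0.1
    p_second_species: float = 0.2
    n_content_sentences: int = 4
    regions_per_document: int = 4
    species_pool: list[tuple[str, str]] | None = None  # (name, taxon_id)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_documents < 1:
            raise ValueError("n_documents must be >= 1")
        for p in (
            self.p_connective_sentence, self.p_abbreviation, self.p_reorder,
            self.p_qualifier, self.p_bracket, self.p_second_species,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.region_lexicon is None:
            self.region_lexicon = load_toy_lexicon()
        if len(self.region_lexicon) == 0:
            raise ValueError("region lexicon is empty")
        if self.connective_phrases is None:
            self.connective_phrases = load_connective_phrases()
        if self.species_pool is None:
            self.species_pool = sorted(load_species_lexicon().items())


def corrupt_region_name(
    name: str, config: SynthConfig, rng: np.random.Generator
) -> tuple[str, list[str]]:
    """Apply configured lexical corruptions; returns (variant, ops)."""
    ops: list[str] = []
    words = name.split()
    if len(words) > 1 and rng.random() < config.p_reorder:
        perm = rng.permutation(len(words))
        shuffled = [words[i] for i in perm]
        if shuffled != words:
            words = shuffled
            ops.append("reorder")
    variant = " ".join(words)
    if rng.random() < config.p_qualifier:
        qualifier = _HEMISPHERE_QUALIFIERS[rng.integers(len(_HEMISPHERE_QUALIFIERS))]
        variant = f"{qualifier} {variant}"
        ops.append("qualifier")
    if rng.random() < config.p_bracket:
        initials = "".join(w[0] for w in name.split()).upper()
        if len(initials) >= 2:
            variant = f"{variant} ({initials})"
            ops.append("bracket")
    return variant, ops


# -- sentence rendering ------------------------------------------------------

_MentionSpec = tuple[str, str, str]  # (surface, concept_id, expanded)


def _render(parts: list) -> tuple[str, list[tuple[int, int, str, str]]]:
    """Concatenate strings and mention specs, recording mention spans."""
    text = ""
    mentions = []
    for part in parts:
        if isinstance(part, str):
            text += part
        else:
            surface, concept_id, expanded = part
            mentions.append((len(text), len(text) + len(surface), concept_id, expanded))
            text += surface
    return text, mentions


_NEGATIVE_TEMPLATES = [
    ("Injections were placed in the ", " and the ", "."),
    ("Neurons in the ", " and the ", " express calbindin."),
    ("The ", " and the ", " were examined in separate experiments."),
    ("Cell counts differed between the ", " and the ", "."),
]


def generate_corpus(config: SynthConfig) -> Corpus:
    """Deterministic synthetic corpus with full gold annotations."""
    rng = np.random.default_rng(config.seed)
    lexicon = config.region_lexicon
    concept_ids = lexicon.concept_ids
    corpus = Corpus()
    for di in range(config.n_documents):
        doc = _generate_document(f"synth{di:04d}", config, lexicon, concept_ids, rng)
        corpus.documents.append(doc)
    corpus.validate()
    return corpus


def _pick_name(lexicon: Lexicon, concept_id: str, rng: np.random.Generator) -> str:
    names = lexicon.names(concept_id)
    return names[int(rng.integers(len(names)))]


def _generate_document(
    doc_id: str,
    config: SynthConfig,
    lexicon: Lexicon,
    concept_ids: list[str],
    rng: np.random.Generator,
) -> Document:
    k = min(config.regions_per_document, len(concept_ids))
    doc_concepts = [
        concept_ids[i] for i in rng.choice(len(concept_ids), size=k, replace=False)
    ]

    # optional document-scope abbreviation for one multi-word region
    abbrev: tuple[str, str, str] | None = None  # (concept, long form, SF)
    if rng.random() < config.p_abbreviation:
        multi = [c for c in doc_concepts if len(lexicon.preferred_name(c).split()) >= 2]
        if multi:
            concept = multi[int(rng.integers(len(multi)))]
            long_form = lexicon.preferred_name(concept)
            sf = "".join(w[0] for w in long_form.split()).upper()
            if 2 <= len(sf) <= 10:
                probe = f"The {long_form} ({sf}) was studied."
                found = extract_abbreviations(probe)
                if any(
                    a.short_form == sf and a.long_form.lower() == long_form.lower()
                    for a in found
                ):
                    abbrev = (concept, long_form, sf)

    def surface_for(concept: str) -> tuple[str, str, str]:
        """Mention spec for one rendering of a region."""
        if abbrev is not None and concept == abbrev[0] and rng.random() < 0.5:
            return (abbrev[2], concept, abbrev[1])  # use the short form
        name = _pick_name(lexicon, concept, rng)
        variant, _ops = corrupt_region_name(name, config, rng)
        return (variant, concept, variant)

    sentence_specs: list[tuple[list, list[tuple[int, int, bool]]]] = []

    # title
    title_concept = doc_concepts[0]
    title_name = _pick_name(lexicon, title_concept, rng)
    sentence_specs.append(
        ((["Organization of the ", (title_name, title_concept, title_name),
           ": an anatomical study."]), [])
    )

    # species sentence
    species_idx = [int(rng.integers(len(config.species_pool)))]
    if rng.random() < config.p_second_species and len(config.species_pool) > 1:
        second = int(rng.integers(len(config.species_pool)))
        if second != species_idx[0]:
            species_idx.append(second)
    species = [config.species_pool[i] for i in species_idx]
    if len(species) == 1:
        sentence_specs.append(
            ([f"Experiments were performed in the adult {species[0][0]}."], [])
        )
    else:
        sentence_specs.append(
            ([f"Experiments were performed in the adult {species[0][0]} "
              f"and the {species[1][0]}."], [])
        )

    # abbreviation definition sentence
    if abbrev is not None:
        concept, long_form, sf = abbrev
        sentence_specs.append(
            ((["The ", (long_form, concept, long_form), f" ({sf})",
               " was examined in detail."]), [])
        )

    # content sentences
    for _ in range(config.n_content_sentences):
        a, b = (
            doc_concepts[i]
            for i in rng.choice(len(doc_concepts), size=2, replace=False)
        )
        spec_a, spec_b = surface_for(a), surface_for(b)
        positive = bool(rng.random() < config.p_connective_sentence)
        if positive:
            phrase = config.connective_phrases[
                int(rng.integers(len(config.connective_phrases)))
            ]
            parts = ["The ", spec_a, f" {phrase} the ", spec_b, "."]
        else:
            pre, mid, post = _NEGATIVE_TEMPLATES[
                int(rng.integers(len(_NEGATIVE_TEMPLATES)))
            ]
            parts = [pre, spec_a, mid, spec_b, post]
        sentence_specs.append((parts, [(0, 1, positive)]))

    # assemble document text and spans
    text = ""
    sentences: list[Sentence] = []
    for parts, pair_specs in sentence_specs:
        if text:
            text += " "
        offset = len(text)
        stext, mention_spans = _render(parts)
        text += stext
        sent = Sentence(start=offset, end=offset + len(stext))
        sent.tokens = tokenize(stext, offset=offset)
        for mstart, mend, concept, expanded in mention_spans:
            sent.mentions.append(
                Mention(
                    start=offset + mstart,
                    end=offset + mend,
                    surface=stext[mstart:mend],
                    expanded=expanded,
                    concept_id=concept,
                )
            )
        for ai, bi, label in pair_specs:
            sent.pairs.append(
                CandidatePair(
                    mention_a=sent.mentions[ai],
                    mention_b=sent.mentions[bi],
                    gold_label=label,
                )
            )
        sentences.append(sent)

    doc = Document(doc_id=doc_id, text=text, sentences=sentences)

    # gold species tags: planted names located in the species sentence
    species_sentence = sentences[1]
    stext = species_sentence.text(text)
    for name, taxon in species:
        idx = stext.find(name)
        if idx >= 0:
            doc.species.append(
                SpeciesTag(
                    start=species_sentence.start + idx,
                    end=species_sentence.start + idx + len(name),
                    name=name,
                    taxon_id=taxon,
                )
            )
    doc.validate()
    return doc
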