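# Methods

This note documents the models and procedures implemented in
`connectomine`, the parameters that matter, the design choices made where
the design was genuinely open, and what the synthetic-data evaluations do
and do not show.

## Task and scope

The pipeline extracts *positive, within-sentence* statements of
neuroanatomical connectivity between two brain-region mentions.  Three
restrictions define the scope:

- **Single sentences.** Connections described across sentence boundaries
  (anaphora, "this region also receives...") are not captured.  A
  substantial fraction of connectivity reports in abstracts span sentences,
  so this is a deliberate recall sacrifice for tractability.
- **Undirected relations.** No efferent/afferent distinction is modeled;
  a candidate pair is "connected" or not.  Connectivity matrices are
  therefore symmetric with a zero diagonal.
- **Abstracts, not full text.** All coordinates refer to the string
  `title + " " + abstract`; the title is included in mention extraction.

## Corpus data model

Character offsets are 0-based and half-open throughout.  A `Document`
carries sentences; sentences carry tokens, mentions and candidate pairs;
documents carry species tags.  Every reader validates that stored surfaces
equal the text slice of their span, so offset corruption fails loudly at
I/O boundaries rather than deep in feature extraction.

JSONL is the canonical serialization (all layers).  AirolaXML — the
interchange dialect used by protein–protein interaction benchmarks — is
supported for relation corpora; it carries sentences, entities and labeled
pairs with sentence-local *inclusive* character offsets and loses tokens
and species tags by design.  The exact attribute vocabulary of that
dialect is not formally specified anywhere; the `charOffset`/`e1`/`e2`/
`interaction` convention of the public PPI corpora is assumed.

## Preprocessing

**Sentence splitting** is rule-based: split at `.!?` followed by
whitespace, except after known non-final abbreviations ("e.g.",
"et al.", "Fig.") or when the next alphabetic character is lowercase.

**Tokenization** splits at whitespace and punctuation; punctuation marks,
including intra-word hyphens ("cortico-thalamic" → `cortico`, `-`,
`thalamic`), are their own tokens.  Splitting at hyphens keeps CRF
features fine-grained: hyphenated region adjectives share stems with their
unhyphenated variants.

**Stemming** uses the Porter suffix-stripping algorithm, implemented in
`connectomine.stem` and checked against the classic published example
vectors.  Diacritics are folded to ASCII *before stemming only* (so
"raphé" stems to "raph"); stored text keeps its accents.

**Abbreviation handling** implements the Schwartz–Hearst character
alignment: for each "long form (SF)" candidate, the shortest long-form
suffix is found in which every short-form character appears in order with
the first character at the start of a word.  Valid short forms are 2–10
characters, start alphanumeric, contain at least one letter, and the long
form has at most min(|SF|+5, 2·|SF|) words.  Definitions apply at
document scope and expansion is an *annotation* (mentions keep their
spans; `Mention.expanded` carries the long form): later stages operate
sentence-by-sentence and would otherwise lose definitions made in earlier
sentences.  Conflicting re-definitions keep the first definition and log a
warning.

**Species tagging** is case-insensitive longest-match dictionary lookup
over word boundaries.  A small table of common laboratory species with
NCBI-style taxon ids ships with the package; larger dictionaries are
drop-in TSV replacements.  Tags that carry no taxon id are dropped.

## Mention recognition (NER)

Recognition is BIO sequence labeling with a linear-chain CRF implemented
in `connectomine.crf`: per-feature state weights, a 3×3 transition
matrix, and start/end label biases, trained by L-BFGS on

    NLL(θ) = Σ_seq [log Z(x) − score(x, y)] + ½ c2 ‖θ‖²

with c2 = 1.0 and at most 200 iterations by default.  The forward–
backward and Viterbi dynamic programs are batched across padded sequences
as dense numpy operations; with three labels this keeps an 8-fold
cross-validation over a few hundred abstracts in the tens of seconds on
one core.  The analytic gradient is verified against numerical
differentiation in development.  Training is deterministic (zero
initialization, fixed data order).

Feature families, each switchable in `NerFeatureConfig`: lowercase
surfaces and Porter stems of the token and of neighbors within a ±2
window (position-tagged); orthographic shape (collapsed case/digit/
punctuation pattern, all-caps, init-caps, has-digit); abbreviation
expansion words for defined short-form tokens; and optional binary
lexicon flags marking tokens inside a longest dictionary match.  The
window default of 2 is a conventional choice, exposed in config.

Mentions that do not align to token boundaries are snapped *outward* at
encode time (with a warning), preserving recallable spans.  Decoding
repairs illegal `I`-after-`O` by opening a new mention, so any label
sequence decodes to valid spans and `decode(encode(·))` is the identity
on valid input.

**Evaluation.**  Exact mode counts a true positive only for identical
spans.  Partial mode counts any character overlap, with greedy one-to-one
assignment by overlap size (ties to the leftmost pair); greedy matching is
our documented choice since partial-match bookkeeping has no single
standard definition.  By construction partial precision/recall are never
below exact.  Cross-validation assigns *documents* to folds uniformly at
random from the seed — abstracts are never split between training and
test — and pooled numbers are micro-averages of the concatenated held-out
confusion counts.

## Standardization

The matching ladder runs, in order: case-insensitive exact match;
bag-of-words (lowercase word multiset equality, after diacritic folding);
stemmed exact; bag-of-stems.  All words/stems of the mention must match
the lexicon name — there is no partial-phrase credit.  On failure,
mention-editing modifiers apply *cumulatively* in registry order, and the
full four-rung ladder re-runs after every edit that produced a new
string:

1. `strip_bracketed_text` — remove `(...)`/`[...]` spans;
2. `strip_hemisphere_qualifiers` — drop left/right/ipsilateral/
   contralateral/bilateral anywhere in the phrase;
3. `strip_directional_prefixes` — drop anterior/posterior/dorsal/ventral/
   medial/lateral/rostral/caudal at the phrase start only;
4. `strip_parenthetical_abbrev` — drop a trailing standalone all-caps
   token;
5. `collapse_whitespace_punct` — fold internal punctuation to spaces;
6. `singularize_terminal_plural` — "nuclei" → "nucleus", "bodies" →
   "body", terminal "-s".

Each edit sacrifices information, so earlier (cheaper) matches win and
the winning stage is recorded per mention.  The registry is extensible
for additional editors.  Cumulative application with a full-ladder re-run
after each edit is a documented design choice; applying modifiers
independently is a plausible alternative that recovers strictly fewer
variants.  Modifiers never return an empty string (the edit is skipped
instead), and enabling them can only add coverage — a property the tests
enforce.

Ambiguity (several concepts tied at the winning rung) is returned, not
resolved; resolving it properly requires species/atlas context that is
downstream of lexical matching.  Matrix assembly excludes ambiguous
normalizations (precision-first) and reports them.

## Relation extraction

Candidate generation enumerates all m(m−1)/2 unordered mention pairs per
sentence.  For each pair, both mentions collapse to a single shared
placeholder token and any other region mention in the sentence becomes a
distinct "other entity" placeholder (entity blinding): the classifier
must learn from context, not from region names, and the shared symbol
makes predictions exactly invariant under swapping the pair.

The shallow linguistic kernel is the sum of two L2-normalized sparse dot
products: a **global context** block of stem n-gram counts (n = 1..3) in
three token windows — fore-between (tokens before the first entity plus
between), between, and between-after (between plus tokens after the
second entity) — and a **local context** block of position-tagged token
attributes (surface, stem, shape, rule-based coarse POS) at relative
positions ±1, ±2 around each entity.  A rule-based coarse tagger
(closed-class word lists plus suffix/shape rules) stands in for a full
POS tagger, keeping the method parser-free.  n ≤ 3 and window ±2 are
config defaults (`SlkConfig`).

Because each block is explicitly normalized, the plain dot product of the
concatenated blocks equals the kernel, and K(x, x) = 2 for any instance
with non-empty blocks.  Training therefore uses a linear-kernel SVM
(C = 1.0 default, decision threshold 0) on the explicit representation;
a test verifies that its decisions reproduce an SVM trained on the
precomputed kernel matrix, and that Gram matrices are positive
semidefinite.  Negative examples are all co-mention pairs not labeled
positive.  Cross-validation partitions documents (10 folds by default),
pools held-out confusion counts, and emits a score-ranked prediction list
with mean sentence length per score decile — a cheap diagnostic of the
difficulty gradient with sentence complexity.

## Triage

The abstract ranker is Bernoulli Naïve Bayes with add-one smoothing over
binary presence features: title/abstract words, journal name, MeSH terms
(opaque strings, qualifiers included).  Each feature's log-likelihood
ratio log[(df⁺+1)/(n⁺+2)] − log[(df⁻+1)/(n⁻+2)] is exposed for
inspection; an abstract's score is the class log-prior plus the sum of
ratios of its present features, so duplicated words count once and
feature families can be ablated independently.

## Connectome assembly

Accepted predictions (both mentions normalized, unambiguous, distinct
concepts) contribute one supporting statement per (prediction × document
species tag) to the species matrices and exactly once to the pooled
matrix, so statements from multi-species documents appear under every
species studied without inflating the pooled counts.  `filter_by_support`
zeroes pairs below a support threshold — requiring a connection to recur
across the corpus trades recall for precision — and thresholds are
nested.  Exports: labeled TSV (round-trippable), RDF N-Triples (one
connects-with triple per supported pair, one evidence triple per
supporting statement), and a flat provenance TSV.

A bundled table (`data/corpus_summary.tsv`) records the published summary
statistics of the project's curated and predicted corpora (abstracts,
region pairs, connections); helper functions compute merged connection
counts and positive-pair percentages from it.

## Synthetic data: what it emulates and what it does not

The generator plants every structure the pipeline must recover: region
mentions drawn from a bundled ~50-concept lexicon (with synonyms),
connective sentences built from 20 connectivity phrases, negative
co-mention sentences, document-scope abbreviation definitions
"long form (SF)" verified recoverable by the Schwartz–Hearst rules,
one or two species per document, and lexical corruption of region names
(word reordering, hemisphere qualifiers, bracketed abbreviations) with
per-operation probabilities.  Defaults: 4 content sentences per document,
4 regions per document, P(connective sentence) = 0.2 — matching the
roughly one-in-five positive share seen in evaluated real-text region
pairs — corruption probabilities 0.1 each, P(abbreviation) = 0.3,
P(second species) = 0.2.  Corruption uses hemisphere (not directional)
qualifiers because directional words are part of many genuine region
names; the directional-prefix modifier is exercised by unit tests
instead.

Everything is deterministic given the seed, and all gold annotations
satisfy the corpus-model invariants by construction.

What passing synthetic evaluations shows: spans, labels and provenance
flow correctly end-to-end; the CRF and SVM can learn separable planted
signal under proper document-level cross-validation; the normalization
cascade inverts exactly the corruptions the modifiers were designed for.
What it does not show: performance on real abstracts, whose vocabulary,
syntax and annotation ambiguity are far harder — real-text accuracy for
this family of methods is substantially lower (roughly two-thirds recall
at half precision for relation extraction on curated corpora) and cannot
be reproduced without the external annotated corpus and full-size
neuroanatomical lexicons, which are optional drop-ins, never required.

## Numerical and implementation notes

- Metrics are computed with exact rational arithmetic from confusion
  counts; pooled cross-validation numbers are micro-averages (identical
  to metrics of summed counts), with macro-averaging behind a flag.
  Undefined ratios (empty denominators) are reported as null, never 0.
- CRF evaluation sizes: the packaged studies use 200-document corpora
  (≈1,400 sentences), where the full 8-fold CV runs in well under a
  minute on one core.
- The SVM receives CSR matrices with 32-bit indices (a scikit-learn
  requirement for sparse input).
- Lexicon indexes are built lazily and deterministically from entry
  order; concept ids at a rung are reported in first-appearance order.
- Degenerate inputs: empty text yields no sentences; a sentence with
  fewer than two mentions yields no pairs; adjacent blinded entities give
  an empty between-window but a valid instance; an empty corpus or a
  single-class training set raises immediately.

## Known limitations

- Sentence splitting and the coarse POS tagger are rule-based
  approximations; unusual abstracts (heavy initials, chemistry
  nomenclature) will produce occasional bad splits or tags.
- The modifier registry ships six editors; the extension mechanism exists
  precisely because real nomenclature variation is richer than any fixed
  list.
- Normalization precision is lexical: a correct string match may still be
  the wrong structure in a given species or atlas.
- Non-mammalian regions are underrepresented in the bundled lexicon and
  templates, mirroring a known weakness of corpus-trained recognizers on
  such text.
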