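# Methods

This note documents the models and procedures nmmkit implements, the
parameters that matter, what the synthetic fixtures do and do not
emulate, and the design choices made where the design was genuinely
open.

## Systematic nomenclature

A Natural Medicinal Material (NMM) is identified by four ordered
components: species origin, medicinal part, special description, and
processing method.  The rendered Systematic Name is the concatenation
of the non-empty component renderings, in that order, separated by
single spaces.

**Species origin (I).**  An ordered set of (genus, epithet) pairs.
Genera match `[A-Z][a-z]+`, epithets `[a-z-]+`; the reserved epithet
`unspecified` marks a historically unresolved origin and must be the
sole entry for its genus.  Rendering joins same-genus epithets with the
Latin conjunction `vel` after a single genus token
(`Ephedra equisetina vel intermedia vel sinica`).  Two choices here
were open:

* *Epithet order.*  Same-genus epithets are sorted case-insensitively
  ascending.  This matches every canonical multi-species example and
  makes the rendering a function of the component set rather than of
  input order.
* *Mixed genera.*  No canonical example mixes genera.  The toolkit
  renders full binomials joined by `vel`, genera sorted alphabetically
  (`Ephedra sinica vel Taraxacum unspecified`).  The grammar keeps this
  parseable because a capitalized token after `vel` must open a new
  binomial.

**Medicinal part (II).**  A main token with an optional qualifier,
rendered capitalized and hyphen-joined (`Stem-herbaceous`).

**Special description (III).**  Zero or more multi-word descriptors,
each rendered with the first word capitalized and words hyphen-joined
(`Freshly-sliced`).

**Processing method (IV).**  Zero or more (verb, adjunct) steps,
rendered `Verb[-adjunct]` and joined by `and`
(`Segmented and Aquafried-honey`).  Steps keep user-specified process
order — unlike species epithets they encode a sequence, not a set — and
all steps are joined by plain `and` with no Oxford-comma variant.

**Type inference.**  `processed` ⇔ component IV non-empty;
`agricultural` ⇔ part present without processing; `raw` otherwise.

**Lexicons.**  The part/special/processing vocabularies are data, not
code: construction against a lexicon rejects unknown tokens with an
error naming the offending component, mirroring an interactive
construction UI's failure display, while lexicon-free construction
accepts any structurally valid token.  A lexicon is rejected as
ambiguous if a single-word special descriptor doubles as a processing
verb — such a vocabulary would make rendered names unparseable (the
same surface token could belong to component III or IV).  This
constraint was added after a property test produced exactly that
collision.

**Parsing.**  The parser is the renderer's inverse over a lexicon:
species tokens are consumed until the first capitalized token whose
head is in the part vocabulary; remaining tokens are classified as
special descriptors (only before any processing step) or processing
steps, with `and` permitted only between steps.  Unknown tokens raise a
parse error carrying the 0-based token position.  The round-trip
`construct(parse(construct(c))) == construct(c)` is property-tested
over random component sets drawn from the default lexicon.

**NMM IDs.**  Strict base-36 positional semantics over the alphabet
`0–9A–Z`, zero-padded to 4 characters: `NMM-0006` is 6, `NMM-0016` is
42, `NMM-ZZZZ` is 36⁴−1 = 1,679,615.  Canonical display is uppercase
with the `NMM-` prefix; lookups accept lowercase and a missing prefix,
and storage keys are lowercase (`nmm-0006`), reconciling display text
with URL-style keys.  Whether real-world registries assign codes in
base-36 or mirror decimal numbering is not derivable from the printed
examples (`0006` and `0016` are consistent with both); the codec is
strictly positional base-36 and the exemplar records simply live at the
corresponding integers (6 and 42).

## Knowledge base

Five UTF-8 JSON array files per knowledge-base directory: `snnmm.json`
(identity records), `text.json` (per-language abstracts), `knowledge.json`
(section trees and contributors), `glossary.json` (standardized
translations keyed by primary term and language), `relation.json`
(coreference edges).  The exact production schema of such platforms is
not public; these fields are the minimal set the implemented features
require.  Files are written with sorted keys and fixed indentation, so
serialization is byte-deterministic and `load(save(kb))` is identity.

Load-time validation enforces: all five files present; unique record
ids; every record's stored English systematic name equal to the name
constructed from its components; no dangling relation targets.  A
relation target is considered resolved if it is a record key, a
glossary primary term, *or the source of another edge* — the last case
admits alias chains (`Ephedrae Herba → 麻黄 → nmm-0006`) whose
intermediate nodes are surface terms rather than primary terms, while
still rejecting genuinely dangling references.

The contribution workflow is a pure state machine: a submitted revision
is `pending` and leaves the record untouched; `accept` applies the body,
stores the prior body on the revision (history is append-only), and
credits the contributor; `reject` requires a reason; both transitions
are irreversible.

### Synthetic fixtures

`generate_fixture_kb(seed, n_records, out)` emulates a curated
knowledge base at desk scale.  It always contains six exemplar records
— the canonical worked materials (`nmm-0006` Ma-huang, `nmm-0016`
Jing-pian-jiang-huang, Ephedra sinica Stem-herbaceous / Root, Taraxacum
unspecified Herb, and the honey-aquafried processed material) — so the
worked examples run against any fixture, plus seeded random records
(synthetic Latin binomials, lexicon-drawn parts/processing, pinyin-like
generic names, random CJK display names) from integer id 100 upward.
`n_records` is the total record count (minimum six: the exemplars are
never dropped).  Every record contributes glossary entries in both
languages in the standardized `Systematic Name (NMM-ID, Generic Name)`
format and coreference edges from its Chinese name, its Generic Name,
and the spaced title-case variant of the Generic Name (`Ma Huang`).

What the fixtures do **not** emulate: real curation scale (thousands of
records), hierarchical parent–child NMM relations,
ingredient/target/disease link tables, genuine Chinese systematic-name
generation (Chinese names are stored as data), and noisy or conflicting
coreference curation.  Tests passing on fixtures therefore demonstrate
algorithmic correctness of the pipelines, not robustness to curation
errors in a production knowledge base.

## Coreference graph search

Relation edges compile into a directed graph; acyclicity is verified at
build time (the error carries one offending cycle).  Primary Terms are
the sinks (out-degree 0).  Resolution returns *all* sinks reachable
from a term: the data model implies a unique Primary Term per surface,
but returning the full set degrades gracefully and surfaces curation
errors instead of hiding them; a sink resolves to itself and an unknown
term to the empty set.  Resolution is property-tested against an
independent brute-force reachable-sink DFS on random DAGs.

Entity extraction is exact longest-match, leftmost-first dictionary
matching over the graph's surface forms: at each position the longest
matching surface wins and its span is consumed, so matches are
non-overlapping and sorted.  No fuzzy matching happens here by design —
approximate matching belongs to full-text search, where a wrong match
costs a ranking position rather than a wrong standardized term.

## MLMD

The grammar recognizes `[[x | y]]` (annotated term), `[[x]]` (entity
reference when `x` matches `nmm-XXXX` case-insensitively, else glossary
term), and `{{zh :: en}}` (bilingual pair); everything else is plain
text, and an unclosed opener fails soft to literal text (strict mode
raises).  The `{{… :: …}}` pair syntax is this toolkit's own dialect
choice, isolated behind one grammar rule so it can be swapped.  Interior
whitespace is trimmed in the parsed fields, but each node retains its
raw source slice, so `serialize(parse(s)) == s` holds for *arbitrary*
input — verified on 1,000 seeded generated documents plus
hypothesis-generated arbitrary text.

Rendering: four modes (`zh-en`, `en-zh`, `zh`, `en`; dual modes emit
the primary language first, joined by a newline) × two formats.
`plain` strips annotations to display text; `markup` emits minimal
deterministic HTML-like tags (`<term id="nmm-0006">…</term>`,
`<gloss>…</gloss>`, `<pair>…</pair>`) — exactly one highlight element
per term occurrence — for downstream styling and tooltips.

## Search

**Tokenizer.**  Latin/numeric runs lowercase; CJK runs emit overlapping
character bigrams (a single CJK character emits itself).  Bigrams are a
standard segmentation-free baseline for Chinese retrieval; the
tokenizer is a plain `text -> [token]` callable, so a dictionary-based
segmenter can be plugged in without touching the index.

**Full-text ranking.**  The index is the classic inverted index; the
ranking function is TF-IDF with cosine normalization:
`score(d,q) = cos(w(d), w(q))` with `w_t = tf_t · idf_t` and
`idf_t = ln((1+N)/(1+df_t)) + 1` (the smoothed form keeps idf positive
so single-document corpora still rank).  Ties break by ascending
document id.  The production ranking function of document stores is
unpublished; this definition is pinned by an exhaustive-scoring oracle
test on corpora up to 200 documents.

**Vector search.**  Cosine similarity, exact (no approximate-NN
index), ties by document id.  The default embedder is a seeded hashed
bag-of-tokens projection: each token is BLAKE2-hashed (keyed by the
seed) to a coordinate and sign, counts accumulated, vector
L2-normalized.  Dimension defaults to 1536 to match the interface of
common sentence-embedding services; the embedder is a contract
(`text -> fixed-dim vector`) and the hashed default is a deterministic
stand-in, not a semantic model — nearest neighbours reflect token
overlap, not meaning.

**Component search.**  AND semantics across constraints; a species
constraint matches if the queried binomial is a *member* of the
record's origin set (so `Ephedra sinica` finds the three-species
Ma-huang record too); results sort by NMM id.  Adding a constraint can
only shrink the result set (property-tested).

## Translation

The pipeline's contract: detect (CGS extraction over the query) →
standardize (glossary lookup, `Systematic Name (NMM-ID, Generic Name)`
format; the English format is mirrored for the zh direction using the
stored Chinese names, as no canonical zh-side example exists) → format
the annotation dictionary (`[[primary | standardized]]` for
knowledge-base terms, `[[target]]` for user-glossary terms; entries
ordered by first occurrence; on overlapping spans the knowledge-base
term wins, since standardization is the system's purpose) → backend →
validate (every dictionary source occurring in the input must be
annotated exactly once per occurrence, else an integrity error names
the missing annotations).  A surface resolving to multiple primary
terms is annotated with the full set and flagged with a warning rather
than silently picking one.

The stub backend substitutes dictionary sources with their annotations
and maps residual text through a small fixed connective lexicon
(longest match first; unknown segments pass through).  It makes the
pipeline a deterministic pure function for testing and offline use; it
is a toy translator by construction, and translation *quality* is
entirely a property of the plugged-in backend.  Few-shot prompt
templates are configuration strings the stub ignores.

## Chat

Retrieval defaults to CGS (entities extracted from the question and
resolved to records), with full-text and vector retrieval available as
alternatives ranking record abstracts.  The serialized context is an
allowlist of structured fields (`nmm_id`, names, type,
`species_origins`, plus the matched surface); which fields a production
system would inject is unstated, so the allowlist is configuration.
The prompt bundle carries two fixed system prompts as configuration
strings: a fallback instruction requiring answers without retrieved
support to open with an exact disclaimer sentence, and a multi-turn
consistency instruction (continuity, no contradictions, consistent
knowledge).  Responses are parsed as MLMD; `[[nmm-id]]` citations are
extracted and any citation outside the retrieval context records an
integrity warning on the response (a warning, not an error: a real
backend may legitimately draw on prior turns).  With the stub backend —
which templates answers from the context fields and appends the
citation sentence — the whole chain is deterministic, and citation
soundness is property-tested over random fixture queries.

Headline accuracy percentages of LLM question answering are properties
of a particular backend, not of this toolkit, and are out of scope; the
deterministic stubs verify the *plumbing* (retrieval, prompt assembly,
citation discipline), not model quality.

## Numerical and scale choices

* Fixture size 12 records and seed-derived sub-seeds everywhere; all
  randomness flows from a single integer seed, kept below 2³¹.
* Property-suite sizes: 10,000 sampled integers (plus boundary values)
  for the ID round-trip; 500 random DAGs of ≤ 50 nodes (edge
  probability 0.12) for graph resolution; 1,000 generated documents for
  the MLMD round-trip; 200-document corpora with 25 queries for the
  full-text and vector oracles.  These sizes exercise the combinatorial
  space thoroughly while keeping the whole suite in seconds.
* Score comparisons against oracles use absolute tolerance 1e-12
  (full-text) — both sides compute the same real-valued formula by
  different routes — and exact ranking equality for top-k lists.
* Degenerate inputs: empty query/corpus yield empty hit lists; a zero
  query vector is an error (cosine undefined); empty processing lists
  render as the empty string; the empty component query matches all
  records.

## Known limitations

* Chinese Systematic Names are stored data, never generated; automated
  transliteration and subspecies/variety/hybrid Latin markers are out
  of scope.
* The default lexicons cover the canonical examples plus a small
  realistic vocabulary; production use requires domain lexicons (JSON).
* The hashed embedder is not semantic; the stub translator and chat
  backends are templates.  All three exist to make contracts testable.
* Multi-genus name formatting and >2-step processing conjunctions
  follow this toolkit's own rules where no canonical example
  constrains them.
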