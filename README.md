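# nmmkit

A toolkit for the standardized description, curation, retrieval, and
translation of **Natural Medicinal Materials (NMMs)** — herbs, roots,
rhizomes and other medicinal substances whose traditional names are
notoriously ambiguous.  A single conventional name ("Ma Huang",
"Ephedrae Herba") may cover several species, medicinal parts and
processing states; pharmacologists, regulators and translators need a
naming scheme that pins each material down exactly, and software that
keeps every downstream step (search, question answering, translation)
consistent with that scheme.

## What it implements

**Systematic nomenclature.**  Each NMM is identified by a *Systematic
Name* composed of four ordered components:

> I. species origin · II. medicinal part · III. special description ·
> IV. processing method

Alternative species of one genus are joined with the Latin conjunction
*vel* ("or"); an unresolved origin carries the reserved epithet
*unspecified*:

```
Ephedra equisetina vel intermedia vel sinica Stem-herbaceous
Curcuma wenyujin Rhizome Freshly-sliced Cleaned
Taraxacum unspecified Herb
```

Alongside the Systematic Name each material has a *Generic Name*
(hyphenated romanized traditional name, `Ma-huang`) and an *NMM ID* —
a 4-digit base-36 code with prefix `NMM-` (`NMM-0006` ↔ integer 6,
`NMM-ZZZZ` ↔ 36⁴−1).  The material's type follows from its components:
*processed* iff component IV is non-empty, *agricultural* iff a
medicinal part is given without processing, *raw* otherwise.

**Knowledge base.**  Five JSON collections (`snnmm`, `text`,
`knowledge`, `glossary`, `relation`) hold identity records, bilingual
abstracts, nested knowledge sections, standardized translations and
coreference edges, with referential-integrity validation, a
submit/review contribution workflow, and a deterministic synthetic
fixture generator for offline work.

**Coreference graph search (CGS).**  Relation edges compile into a
directed acyclic *Coreference Primary Term Graph* whose sinks are
Primary Terms (canonical keys, typically NMM IDs).  Any surface term —
`麻黄`, `Ma Huang`, `Ephedrae Herba` — resolves to the sinks reachable
from it, and free text is mined for NMM entities by longest-match
dictionary extraction over the graph's surface forms.

**MLMD markup.**  A lightweight multilingual dialect:
`[[nmm-0006]]` (entity reference), `[[nmm-0006 | display text]]`
(annotated term), `[[Natural Medicinal Material]]` (glossary term) and
`{{中文 :: English}}` (bilingual pair), rendered in four display modes
(`zh-en`, `en-zh`, `zh`, `en`) as plain text or highlight markup, with
exact parse/serialize round-tripping.

**Search.**  TF-IDF/cosine full-text search over an inverted index
(CJK runs tokenize as character bigrams), cosine-similarity vector
search over a pluggable embedder (a deterministic hashed bag-of-tokens
projection by default, 1536-dimensional), and AND-semantics search over
name components.

**Translation and chat.**  Terminology-constrained translation detects
NMM terms via CGS, builds an annotation dictionary mapping each term to
`[[primary-term | Systematic Name (NMM-ID, Generic Name)]]` (user
glossaries contribute `[[target]]` entries; standardized terms win on
overlapping spans), invokes a pluggable backend, and *validates* that
every dictionary term was annotated — a backend cannot silently drop a
standardized term.  Retrieval-augmented chat extracts entities from the
question, serializes the matching records into the prompt together with
fixed fallback/consistency system prompts, and checks that every
`[[nmm-id]]` citation in the answer was actually retrieved.  Both
pipelines ship deterministic stub backends so the whole chain is a pure
function; real model backends plug in through the same contracts.

## Worked example

Generate a fixture knowledge base and run the pipeline end to end:

```sh
nmm kb fixture --seed 1 --n 12 --out kbdemo

nmm name construct --species "Ephedra sinica" --species "Ephedra intermedia" \
    --species "Ephedra equisetina" --part stem-herbaceous
```

```json
{
 "nmm_type": "agricultural",
 "systematic_name": "Ephedra equisetina vel intermedia vel sinica Stem-herbaceous",
 "components": {"species": [["Ephedra", "equisetina"], ["Ephedra", "intermedia"],
                ["Ephedra", "sinica"]], "part": {"main": "stem",
                "qualifier": "herbaceous"}, "special": [], "processing": []}
}
```

The three binomials are canonically sorted and joined with *vel*; the
name has a part but no processing, so the material is *agricultural*.

```sh
echo 麻黄是一种天然药材。 > src.txt
printf '{"天然药材": "Natural Medicinal Material"}' > g.json
nmm translate src.txt --direction zh-en --glossary g.json --kb kbdemo
```

```json
{
 "dictionary": "麻黄 -> [[nmm-0006 | Ephedra equisetina vel intermedia vel sinica Stem-herbaceous (NMM-0006, Ma-huang)]]\n天然药材 -> [[Natural Medicinal Material]]",
 "mlmd": "[[nmm-0006 | Ephedra equisetina vel intermedia vel sinica Stem-herbaceous (NMM-0006, Ma-huang)]] is a kind of [[Natural Medicinal Material]].",
 "plain": "Ephedra equisetina vel intermedia vel sinica Stem-herbaceous (NMM-0006, Ma-huang) is a kind of Natural Medicinal Material.",
 "term_spans": [[0, 81, "kb_standard"], [95, 121, "user_custom"]]
}
```

`麻黄` was detected, resolved to primary term `nmm-0006`, and rendered
with its standardized translation rather than a free paraphrase; the
user-glossary term is annotated separately, and the span list drives
highlighting with per-term provenance.

```sh
nmm chat "What is the species origin of Ma Huang?" --kb kbdemo
```

```json
{
 "answer": "The species origin of Ma Huang is Ephedra equisetina, Ephedra intermedia, or Ephedra sinica. This response is based on the relevant knowledge of the following Natural Medicinal Material: [[nmm-0006]].",
 "cited_ids": ["nmm-0006"],
 "fallback_used": false
}
```

The multi-species character of the material is preserved — exactly the
ambiguity the nomenclature exists to surface — and the citation is
verified against the retrieval context.

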