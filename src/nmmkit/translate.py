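"""Terminology-constrained translation (coreference primary-term pipeline).

Translation of NMM text must not paraphrase the material names: a term
like 麻黄 has a unique standardized rendering built from its Systematic
Name.  The pipeline therefore:

1. detects NMM terms in the source text with coreference graph search
   and resolves each to its primary term;
2. looks up the standardized translation of each primary term
   ("Systematic Name (NMM-ID, Generic Name)" format) and formats an
   *annotation dictionary* mapping source terms to MLMD annotations —
   ``[[primary-term | standardized translation]]`` for knowledge-base
   terms and ``[[target term]]`` for user-glossary terms (on overlapping
   spans the knowledge-base entry wins);
3. hands text, direction, dictionary and a prompt template to a
   translation backend, which must return MLMD-annotated target text;
4. validates the output: every dictionary source occurring in the input
   must be annotated exactly once per occurrence — a backend that drops
   an annotation raises :class:`~nmmkit.errors.IntegrityError`.

The default backend is a deterministic stub that substitutes dictionary
entries and maps residual text through a small fixed lexicon; it gives
the pipeline a pure, reproducible end-to-end path.  Real neural
backends plug in through the same four-argument contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Mapping, Optional

from .cgs import CptgGraph, build_cptg, extract_entities
from .errors import IntegrityError, NmmValidationError
from .knowledgebase import KnowledgeBase, NmmRecord
from .mlmd import MlmdDocument, parse_mlmd, render_mlmd

__all__ = [
    "TranslationRequest",
    "AnnotationEntry",
    "AnnotationDictionary",
    "TranslationResult",
    "format_standard_translation",
    "prepare_annotation_dictionary",
    "StubTranslationBackend",
    "translate_text",
    "PROMPT_TEMPLATE",
]

Direction = Literal["zh-en", "en-zh"]

#: Few-shot prompt template handed to backends (configuration data; the
#: deterministic stub ignores it).
PROMPT_TEMPLATE = (
    "Translate the following text ({direction}). Terms listed in the "
    "dictionary below MUST be rendered exactly as their annotated form, "
    "keeping the [[...]] markup:\n{dictionary}\n---\n{text}"
)


@dataclass(frozen=True)
class TranslationRequest:
    text: str
    direction: Direction = "zh-en"
    user_glossary: tuple[tuple[str, str], ...] = ()
    mode: str = "accurate"

    def __post_init__(self):
        if not self.text:
            raise NmmValidationError("translation request text must be non-empty")
        keys = [k for k, _ in self.user_glossary]
        if len(keys) != len(set(keys)):
            raise NmmValidationError("duplicate user-glossary key")
        if self.direction not in ("zh-en", "en-zh"):
            raise NmmValidationError(f"unknown direction {self.direction!r}")

    @property
    def target_lang(self) -> str:
        return self.direction.split("-")[1]


@dataclass(frozen=True)
class AnnotationEntry:
    source: str
    annotation: str
    provenance: Literal["kb_standard", "user_custom"]
    first_offset: int
    occurrences: int


@dataclass
class AnnotationDictionary:
    entries: list[AnnotationEntry] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def formatted(self) -> str:
        """Human/prompt-readable "source -> annotation" lines."""
        return "\n".join(f"{e.source} -> {e.annotation}" for e in self.entries)

    def as_mapping(self) -> dict[str, str]:
        return {e.source: e.annotation for e in self.entries}


def format_standard_translation(record: NmmRecord, target_lang: str) -> str:
    """Standardized rendering: ``<Systematic Name> (<NMM-ID>, <Generic Name>)``."""
    sys_name = record.systematic_name.get(target_lang)
    generic = record.generic_name.get(target_lang)
    if not sys_name or not generic:
        raise NmmValidationError(
            f"record {record.key} has no {target_lang!r} names"
        )
    return f"{sys_name} ({record.nmm_id.display}, {generic})"


def _kb_matches(kb: KnowledgeBase, cptg: CptgGraph, text: str):
    """Extraction matches whose primaries all resolve to KB records."""
    out = []
    for m in extract_entities(cptg, text):
        primaries = [p for p in m.primary_terms if p.lower() in kb.records]
        if primaries:
            out.append((m, primaries))
    return out


def prepare_annotation_dictionary(
    request: TranslationRequest,
    kb: KnowledgeBase,
    cptg: CptgGraph | None = None,
) -> AnnotationDictionary:
    """Assemble the per-request annotation dictionary.

    Knowledge-base terms are found by entity extraction and annotated
    ``[[primary | standardized translation]]``; user-glossary keys
    occurring in the text outside those spans are annotated
    ``[[target]]``.  Entries are ordered by first occurrence in the
    source text.  A surface resolving to several primary terms is
    annotated with the full set and flagged in ``warnings``.
    """
    if cptg is None:
        cptg = build_cptg(kb.relations)
    result = AnnotationDictionary()
    covered: list[tuple[int, int]] = []
    by_source: dict[str, AnnotationEntry] = {}
    for match, primaries in _kb_matches(kb, cptg, request.text):
        covered.append((match.start, match.end))
        if match.surface in by_source:
            e = by_source[match.surface]
            by_source[match.surface] = AnnotationEntry(
                source=e.source, annotation=e.annotation,
                provenance=e.provenance, first_offset=e.first_offset,
                occurrences=e.occurrences + 1,
            )
            continue
        if len(primaries) > 1:
            result.warnings.append(
                f"surface {match.surface!r} resolves to multiple primary "
                f"terms: {', '.join(primaries)}"
            )
        parts = []
        for p in primaries:
            record = kb.records[p.lower()]
            std = kb.standard_translation(p.lower(), request.target_lang)
            if std is None:
                std = format_standard_translation(record, request.target_lang)
            parts.append(f"[[{p.lower()} | {std}]]")
        by_source[match.surface] = AnnotationEntry(
            source=match.surface,
            annotation=" / ".join(parts),
            provenance="kb_standard",
            first_offset=match.start,
            occurrences=1,
        )
    for key, target in request.user_glossary:
        # count occurrences not overlapping knowledge-base spans (D11)
        occ = 0
        first = None
        start = 0
        while True:
            idx = request.text.find(key, start)
            if idx == -1:
                break
            span = (idx, idx + len(key))
            if not any(a < span[1] and span[0] < b for a, b in covered):
                occ += 1
                if first is None:
                    first = idx
            start = idx + len(key)
        if occ:
            by_source[key] = AnnotationEntry(
                source=key,
                annotation=f"[[{target}]]",
                provenance="user_custom",
                first_offset=first if first is not None else 0,
                occurrences=occ,
            )
    result.entries = sorted(by_source.values(), key=lambda e: e.first_offset)
    return result


# ---------------------------------------------------------------------------
# Deterministic stub backend
# ---------------------------------------------------------------------------

# Minimal zh -> en lexicon for residual (non-dictionary) text.  This is a
# toy vocabulary: it keeps the stub pipeline a pure function of its
# inputs and covers connective phrases common in NMM sentences.
_ZH_EN = [
    ("是一种", "is a kind of"),
    ("是", "is"),
    ("一种", "a kind of"),
    ("可以", "can"),
    ("用于", "be used for"),
    ("和", "and"),
    ("的", ""),
    ("。", "."),
    ("，", ","),
]
_EN_ZH = [
    ("is a kind of", "是一种"),
    ("is", "是"),
    ("a kind of", "一种"),
    ("and", "和"),
    (".", "。"),
    (",", "，"),
]
_PUNCT = {".", ",", "。", "，"}


class StubTranslationBackend:
    """Pure-function stand-in for a neural translation backend.

    Substitutes every dictionary source term with its annotation and
    maps residual text with a fixed toy lexicon (longest match first);
    unknown residual segments pass through unchanged.  Deterministic:
    identical inputs always give identical output.
    """

    name = "stub"

    def __call__(
        self,
        text: str,
        direction: Direction,
        dictionary: AnnotationDictionary,
        prompt_template: str = PROMPT_TEMPLATE,
    ) -> str:
        lexicon = _ZH_EN if direction == "zh-en" else _EN_ZH
        table = [(e.source, e.annotation) for e in dictionary.entries]
        table += lexicon
        table.sort(key=lambda kv: -len(kv[0]))
        segments: list[str] = []
        i = 0
        pending = []
        while i < len(text):
            hit = None
            for src, tgt in table:
                if src and text.startswith(src, i):
                    hit = (src, tgt)
                    break
            if hit is None:
                ch = text[i]
                if not ch.isspace():
                    pending.append(ch)
                elif pending:
                    segments.append("".join(pending))
                    pending.clear()
                i += 1
                continue
            if pending:
                segments.append("".join(pending))
                pending.clear()
            if hit[1]:
                segments.append(hit[1])
            i += len(hit[0])
        if pending:
            segments.append("".join(pending))
        if direction == "zh-en":
            out = ""
            for seg in segments:
                if not out or seg in _PUNCT:
                    out += seg
                else:
                    out += " " + seg
            return out
        return "".join(segments)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class TranslationResult:
    mlmd_text: str
    doc: MlmdDocument
    term_spans: list[tuple[int, int, str]]  # (start, end, provenance) in plain text
    dictionary: AnnotationDictionary
    warnings: list[str] = field(default_factory=list)

    @property
    def plain(self) -> str:
        return render_mlmd(self.doc, mode="en", fmt="plain")

    def rendered(self, mode: str = "en", fmt: str = "plain") -> str:
        return render_mlmd(self.doc, mode=mode, fmt=fmt)


Backend = Callable[[str, Direction, AnnotationDictionary, str], str]


def translate_text(
    request: TranslationRequest,
    kb: KnowledgeBase,
    backend: Backend | None = None,
    cptg: CptgGraph | None = None,
) -> TranslationResult:
    """Run the full pipeline and validate the backend's output.

    Raises :class:`IntegrityError` naming the missing annotations if the
    backend fails to annotate every occurrence of a dictionary source
    term.
    """
    backend = backend or StubTranslationBackend()
    dictionary = prepare_annotation_dictionary(request, kb, cptg=cptg)
    mlmd_text = backend(request.text, request.direction, dictionary,
                        PROMPT_TEMPLATE)
    doc = parse_mlmd(mlmd_text)
    missing = []
    for entry in dictionary.entries:
        found = mlmd_text.count(entry.annotation)
        if found != entry.occurrences:
            missing.append(
                f"{entry.source!r}: expected {entry.occurrences} "
                f"annotation(s), found {found}"
            )
    if missing:
        raise IntegrityError(
            "backend output missing annotations: " + "; ".join(missing)
        )
    # character spans of highlighted terms in the plain rendering
    spans: list[tuple[int, int, str]] = []
    offset = 0
    for node in doc.nodes:
        rendered = render_mlmd(MlmdDocument(nodes=[node]),
                               mode="en", fmt="plain")
        if node.kind == "annotated_term":
            spans.append((offset, offset + len(rendered), "kb_standard"))
        elif node.kind == "glossary_term":
            spans.append((offset, offset + len(rendered), "user_custom"))
        offset += len(rendered)
    return TranslationResult(
        mlmd_text=mlmd_text,
        doc=doc,
        term_spans=spans,
        dictionary=dictionary,
        warnings=list(dictionary.warnings),
    )
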