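"""Retrieval-augmented chat over the NMM knowledge base.

A user query is first mined for NMM entities (coreference graph search
by default; vector or full-text retrieval as alternatives).  The
matching records' structured fields form the retrieval context, which
is bundled with two fixed system prompts — a fallback instruction for
queries the search cannot support, and a multi-turn consistency
instruction — plus the serialized conversation history, and handed to a
chat backend.  The backend's answer is MLMD text whose ``[[nmm-id]]``
citations are parsed out and checked against the retrieval context;
citing an id that was never retrieved records an integrity warning on
the response.

The default backend is a deterministic stub that templates an answer
from the context fields, so the whole chain is a pure function of
(session, query, knowledge base).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Optional

from .cgs import CptgGraph, build_cptg, extract_entities
from .errors import NmmValidationError
from .knowledgebase import KnowledgeBase, NmmRecord
from .mlmd import parse_mlmd
from .search import (
    HashedEmbedder,
    build_index,
    fulltext_search,
    vector_search,
)

__all__ = [
    "ChatSession",
    "RetrievalContext",
    "ChatResponse",
    "FALLBACK_SENTENCE",
    "FALLBACK_SYSTEM_PROMPT",
    "CONSISTENCY_SYSTEM_PROMPT",
    "CONTEXT_FIELDS",
    "retrieve_context",
    "build_prompt",
    "StubChatBackend",
    "answer_query",
]

#: Exact sentence a backend must open with when answering without
#: retrieved knowledge.
FALLBACK_SENTENCE = (
    "I could not find relevant knowledge from the search to directly "
    "answer your question, but I will do my best to answer it based on "
    "my internal knowledge."
)

FALLBACK_SYSTEM_PROMPT = (
    "To ensure scientific accuracy and rigor in responses, if the "
    "knowledge search does not retrieve relevant knowledge that directly "
    "supports answering the user's latest question, begin your response "
    "with the following statement: " + FALLBACK_SENTENCE
)

CONSISTENCY_SYSTEM_PROMPT = (
    "In multi-turn conversations, when responding to a new question from "
    "the user, you should:\n"
    "1. Maintain Continuity: Ensure that responses are logically "
    "connected and the conversation flows smoothly.\n"
    "2. Avoid Contradictions: Do not contradict previous responses.\n"
    "3. Ensure Consistency: Provide consistent and accurate knowledge "
    "across all interactions."
)

#: Record fields serialized into the context window (allowlist).
CONTEXT_FIELDS = ("nmm_id", "systematic_name", "generic_name", "nmm_type",
                  "species_origins")

Strategy = Literal["cgs", "vector", "fulltext"]


@dataclass
class ChatSession:
    """Alternating (user, assistant) turns plus per-turn retrieval log."""

    turns: list[tuple[str, str]] = field(default_factory=list)
    retrieval_log: list[list[str]] = field(default_factory=list)

    def append_exchange(self, query: str, answer: str,
                        retrieved: list[str]) -> None:
        if self.turns and self.turns[-1][0] == "user":
            raise NmmValidationError("session already awaiting an answer")
        self.turns.append(("user", query))
        self.turns.append(("assistant", answer))
        self.retrieval_log.append(retrieved)


@dataclass
class ContextRecord:
    nmm_id: str
    fields: dict
    matched_surface: Optional[str] = None


@dataclass
class RetrievalContext:
    records: list[ContextRecord] = field(default_factory=list)
    strategy: Strategy = "cgs"

    @property
    def record_ids(self) -> list[str]:
        return [r.nmm_id for r in self.records]

    def serialized(self) -> str:
        lines = []
        for rec in self.records:
            lines.append(f"nmm_id: {rec.nmm_id}")
            for key, value in rec.fields.items():
                if key == "nmm_id":
                    continue
                if key == "species_origins":
                    value = ", or, ".join(value)
                lines.append(f"{key}: {value}")
            if rec.matched_surface:
                lines.append(f"matched_surface: {rec.matched_surface}")
            lines.append("")
        return "\n".join(lines).strip()


@dataclass
class ChatResponse:
    mlmd_text: str
    cited_ids: list[str]
    context: RetrievalContext
    fallback_used: bool
    warnings: list[str] = field(default_factory=list)


def _context_record(record: NmmRecord,
                    surface: str | None = None) -> ContextRecord:
    fields = {}
    for name in CONTEXT_FIELDS:
        if name == "nmm_id":
            fields[name] = record.key
        elif name == "species_origins":
            fields[name] = list(record.species_origins)
        elif name == "nmm_type":
            fields[name] = record.nmm_type.value
        else:
            value = getattr(record, name)
            fields[name] = value.get("en", "") if isinstance(value, dict) else value
    return ContextRecord(nmm_id=record.key, fields=fields,
                         matched_surface=surface)


def retrieve_context(
    query: str,
    kb: KnowledgeBase,
    strategy: Strategy = "cgs",
    cptg: CptgGraph | None = None,
    k: int = 3,
) -> RetrievalContext:
    """Fetch the records relevant to a query.

    ``cgs`` (default) extracts NMM entities from the query and resolves
    them through the coreference graph — precise, term-driven retrieval.
    ``fulltext``/``vector`` rank record abstracts against the whole
    query and keep the top ``k``.
    """
    context = RetrievalContext(strategy=strategy)
    if strategy == "cgs":
        if cptg is None:
            cptg = build_cptg(kb.relations)
        seen = set()
        for match in extract_entities(cptg, query):
            for primary in match.primary_terms:
                key = primary.lower()
                if key in kb.records and key not in seen:
                    seen.add(key)
                    context.records.append(
                        _context_record(kb.records[key], match.surface)
                    )
        return context
    corpus = {
        key: " ".join(
            [rec.systematic_name.get("en", ""),
             rec.generic_name.get("en", ""),
             rec.abstract.get("en", ""), rec.abstract.get("zh", "")]
        )
        for key, rec in kb.records.items()
    }
    if strategy == "fulltext":
        hits = fulltext_search(build_index(corpus), query, k=k)
    elif strategy == "vector":
        embed = HashedEmbedder()
        store = {key: embed(text) for key, text in corpus.items()}
        hits = vector_search(store, embed(query), k=k)
    else:
        raise NmmValidationError(f"unknown retrieval strategy {strategy!r}")
    for hit in hits:
        context.records.append(_context_record(kb.records[hit.doc_id]))
    return context


def build_prompt(context: RetrievalContext,
                 session: ChatSession, query: str = "") -> dict:
    """Assemble the prompt bundle handed to a chat backend."""
    return {
        "system_prompts": [FALLBACK_SYSTEM_PROMPT, CONSISTENCY_SYSTEM_PROMPT],
        "context": context.serialized(),
        "history": [
            {"role": role, "text": text} for role, text in session.turns
        ],
        "query": query,
    }


class StubChatBackend:
    """Deterministic template-based backend.

    With retrieved context it answers from the structured fields —
    species-origin questions get the "The species origin of X is A, B,
    or C." template — and appends the citation sentence naming the
    record ids in ``[[...]]`` notation.  Without context it opens with
    the exact fallback sentence.
    """

    name = "stub"

    def __call__(self, prompt: dict) -> str:
        context_ids = []
        records = []
        for block in prompt["context"].split("\n\n"):
            fields = {}
            for line in block.splitlines():
                key, _, value = line.partition(": ")
                if key:
                    fields[key] = value
            if fields.get("nmm_id"):
                context_ids.append(fields["nmm_id"])
                records.append(fields)
        query = prompt.get("query", "")
        if not records:
            return (
                FALLBACK_SENTENCE
                + " Unfortunately, no matching material was found in the "
                  "knowledge base for this question."
            )
        sentences = []
        for fields in records:
            subject = fields.get("matched_surface") or fields.get(
                "generic_name", fields["nmm_id"]
            )
            if "species origin" in query.lower():
                origins = fields.get("species_origins", "").split(", or, ")
                if len(origins) > 1:
                    listed = ", ".join(origins[:-1]) + ", or " + origins[-1]
                else:
                    listed = origins[0] if origins else ""
                sentences.append(
                    f"The species origin of {subject} is {listed}."
                )
            else:
                sentences.append(
                    f"{fields.get('systematic_name', fields['nmm_id'])} "
                    f"({fields['nmm_id'].upper()}, "
                    f"{fields.get('generic_name', '')}) is a"
                    f"{'n' if fields.get('nmm_type', '')[:1] == 'a' else ''} "
                    f"{fields.get('nmm_type', '')} natural medicinal material."
                )
        cite_list = ", ".join(f"[[{cid}]]" for cid in context_ids)
        noun = (
            "Natural Medicinal Material"
            if len(context_ids) == 1
            else "Natural Medicinal Materials"
        )
        sentences.append(
            "This response is based on the relevant knowledge of the "
            f"following {noun}: {cite_list}."
        )
        return " ".join(sentences)


ChatBackend = Callable[[dict], str]


def answer_query(
    query: str,
    session: ChatSession,
    kb: KnowledgeBase,
    backend: ChatBackend | None = None,
    strategy: Strategy = "cgs",
    cptg: CptgGraph | None = None,
) -> ChatResponse:
    """One retrieval-augmented exchange; appends the turn to the session."""
    backend = backend or StubChatBackend()
    context = retrieve_context(query, kb, strategy=strategy, cptg=cptg)
    prompt = build_prompt(context, session, query=query)
    answer = backend(prompt)
    doc = parse_mlmd(answer)
    cited = []
    for cid in doc.cited_ids():
        if cid not in cited:
            cited.append(cid)
    warnings = [
        f"cited id {cid!r} not in retrieval context"
        for cid in cited
        if cid not in context.record_ids
    ]
    response = ChatResponse(
        mlmd_text=answer,
        cited_ids=cited,
        context=context,
        fallback_used=answer.startswith(FALLBACK_SENTENCE),
        warnings=warnings,
    )
    session.append_exchange(query, answer, context.record_ids)
    return response
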