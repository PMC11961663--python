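"""Multilingual Markdown (MLMD) dialect: parse, render, serialize.

MLMD is a lightweight markup for multilingual knowledge text.  The
grammar recognized here:

``[[xxx | yyy]]``
    *annotated term*: ``xxx`` is a primary-term key, ``yyy`` its display
    text (typically a standardized translation).
``[[xxx]]``
    *entity reference* when ``xxx`` matches the NMM-ID pattern
    (``nmm-XXXX``, case-insensitive), otherwise a *glossary term* whose
    display text is ``xxx`` itself.
``{{zh-text :: en-text}}``
    *bilingual pair* carrying the same content in both languages.

Everything else is plain text.  Unclosed brackets fail soft to literal
text unless ``strict=True``.  Each non-text node retains the exact raw
source between its delimiters, so ``serialize(parse(s)) == s`` holds for
every input, including non-canonical interior whitespace.

Rendering supports the four display modes ``zh-en``, ``en-zh``, ``zh``
and ``en`` (bilingual pairs emit only the selected language(s), primary
language first) and two formats: ``plain`` strips markup to display
text; ``markup`` wraps annotated/glossary terms in minimal HTML-like
``<term>``/``<gloss>`` tags carrying the id, for highlighting and
tooltips.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Literal, Optional

from .errors import NmmParseError, NmmValidationError

__all__ = ["MlmdNode", "MlmdDocument", "parse_mlmd", "serialize_mlmd",
           "render_mlmd", "MODES", "FORMATS"]

MODES = ("zh-en", "en-zh", "zh", "en")
FORMATS = ("plain", "markup")

_ID_PATTERN = re.compile(r"^nmm-[0-9a-z]{4}$", re.IGNORECASE)

NodeKind = Literal[
    "text", "entity_ref", "annotated_term", "glossary_term", "bilingual_pair"
]


@dataclass(frozen=True)
class MlmdNode:
    """One parsed node; ``raw`` preserves the source between delimiters."""

    kind: NodeKind
    text: str = ""            # plain text nodes
    id: Optional[str] = None  # entity_ref / annotated_term
    display: str = ""         # annotated_term / glossary_term display text
    zh: str = ""              # bilingual_pair
    en: str = ""              # bilingual_pair
    raw: str = ""             # exact interior source, for round-tripping


@dataclass
class MlmdDocument:
    nodes: list[MlmdNode] = field(default_factory=list)

    def cited_ids(self) -> list[str]:
        """Lowercased ids of entity references and annotated terms, in order."""
        out = []
        for n in self.nodes:
            if n.kind in ("entity_ref", "annotated_term") and n.id:
                out.append(n.id.lower())
        return out


def _bracket_node(raw: str) -> MlmdNode:
    if "|" in raw:
        key, _, display = raw.partition("|")
        return MlmdNode(
            kind="annotated_term",
            id=key.strip(),
            display=display.strip(),
            raw=raw,
        )
    inner = raw.strip()
    if _ID_PATTERN.match(inner):
        return MlmdNode(kind="entity_ref", id=inner, raw=raw)
    return MlmdNode(kind="glossary_term", display=inner, raw=raw)


def _pair_node(raw: str) -> MlmdNode:
    zh, sep, en = raw.partition("::")
    if not sep:
        zh, en = raw, ""
    return MlmdNode(kind="bilingual_pair", zh=zh.strip(), en=en.strip(), raw=raw)


def parse_mlmd(text: str, strict: bool = False) -> MlmdDocument:
    """Parse MLMD source into a node sequence.

    Fail-soft: an opener without its matching closer is kept as literal
    text; with ``strict=True`` it raises :class:`NmmParseError` with the
    offset of the unclosed opener.
    """
    nodes: list[MlmdNode] = []
    buf: list[str] = []
    i = 0
    n = len(text)

    def flush():
        if buf:
            nodes.append(MlmdNode(kind="text", text="".join(buf)))
            buf.clear()

    while i < n:
        two = text[i:i + 2]
        if two in ("[[", "{{"):
            closer = "]]" if two == "[[" else "}}"
            end = text.find(closer, i + 2)
            if end == -1:
                if strict:
                    raise NmmParseError(
                        f"unclosed {two!r} at offset {i}", position=i
                    )
                buf.append(text[i:])
                break
            raw = text[i + 2:end]
            flush()
            nodes.append(_bracket_node(raw) if two == "[[" else _pair_node(raw))
            i = end + 2
        else:
            buf.append(text[i])
            i += 1
    flush()
    return MlmdDocument(nodes=nodes)


def serialize_mlmd(doc: MlmdDocument) -> str:
    """Exact inverse of :func:`parse_mlmd`."""
    out: list[str] = []
    for node in doc.nodes:
        if node.kind == "text":
            out.append(node.text)
        elif node.kind == "bilingual_pair":
            raw = node.raw if node.raw else f"{node.zh} :: {node.en}"
            out.append("{{" + raw + "}}")
        else:
            if node.raw:
                raw = node.raw
            elif node.kind == "annotated_term":
                raw = f"{node.id} | {node.display}"
            elif node.kind == "entity_ref":
                raw = node.id or ""
            else:
                raw = node.display
            out.append("[[" + raw + "]]")
    return "".join(out)


def _render_node(node: MlmdNode, mode: str, fmt: str) -> str:
    if node.kind == "text":
        return node.text
    if node.kind == "bilingual_pair":
        if mode == "zh":
            return node.zh
        if mode == "en":
            return node.en
        first, second = (
            (node.zh, node.en) if mode == "zh-en" else (node.en, node.zh)
        )
        if fmt == "markup":
            return (
                f'<pair><primary>{first}</primary>'
                f'<secondary>{second}</secondary></pair>'
            )
        return f"{first}\n{second}" if second else first
    if node.kind == "entity_ref":
        ident = (node.id or "").lower()
        if fmt == "markup":
            return f'<term id="{ident}">{node.id}</term>'
        return node.id or ""
    if node.kind == "annotated_term":
        if fmt == "markup":
            return f'<term id="{(node.id or "").lower()}">{node.display}</term>'
        return node.display
    if node.kind == "glossary_term":
        if fmt == "markup":
            return f"<gloss>{node.display}</gloss>"
        return node.display
    raise NmmValidationError(f"unknown node kind {node.kind!r}")


def render_mlmd(doc: MlmdDocument, mode: str = "en", fmt: str = "plain") -> str:
    """Render a document in one of the four display modes.

    ``plain`` strips all markup to display text; ``markup`` emits
    minimal HTML-like tags (one highlight element per annotated or
    glossary term) for downstream styling.
    """
    if mode not in MODES:
        raise NmmValidationError(f"unknown display mode {mode!r}; use {MODES}")
    if fmt not in FORMATS:
        raise NmmValidationError(f"unknown format {fmt!r}; use {FORMATS}")
    return "".join(_render_node(node, mode, fmt) for node in doc.nodes)
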