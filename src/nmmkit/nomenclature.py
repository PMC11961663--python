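"""Systematic nomenclature for Natural Medicinal Materials (NMMs).

An NMM is identified by a *Systematic Name* built from four ordered
components:

I.   species origin — the Latin names of every pertinent source species;
II.  medicinal part — the organ or tissue used medicinally;
III. special description — initial preparation at the production site or
     other distinguishing characteristics;
IV.  processing method — the processing applied to produce the material
     for medicinal use.

Alternative species of the same genus are joined with the Latin
conjunction "vel" ("or"), e.g. ``Ephedra equisetina vel intermedia vel
sinica Stem-herbaceous``; a genus whose exact species is historically
unclear carries the reserved epithet ``unspecified`` ("Taraxacum
unspecified Herb").  Alongside the Systematic Name each NMM carries a
*Generic Name* (hyphenated romanized traditional name, e.g. "Ma-huang")
and a 4-digit base-36 *NMM ID* with prefix "NMM-" ("NMM-0006").

This module defines the component types, the deterministic renderers,
the Systematic-Name parser (the renderer's inverse over a component
lexicon), NMM-type inference and the base-36 ID codec.
"""

from __future__ import annotations

import enum
import json
import re
from pathlib import Path
from typing import Optional, Sequence

from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import NmmParseError, NmmValidationError

__all__ = [
    "GENUS_RE",
    "EPITHET_RE",
    "UNSPECIFIED",
    "SpeciesOrigin",
    "MedicinalPart",
    "SpecialDescription",
    "ProcessingMethod",
    "ProcessingMethodList",
    "NameComponents",
    "SystematicName",
    "NmmId",
    "GenericName",
    "NmmType",
    "Lexicon",
    "DEFAULT_LEXICON",
    "format_species_origin",
    "format_medicinal_part",
    "format_special_description",
    "format_processing_methods",
    "construct_systematic_name",
    "parse_systematic_name",
    "format_generic_name",
    "encode_nmm_id",
    "decode_nmm_id",
    "infer_nmm_type",
]

GENUS_RE = re.compile(r"^[A-Z][a-z]+$")
EPITHET_RE = re.compile(r"^[a-z-]+$")
LOWER_TOKEN_RE = re.compile(r"^[a-z]+$")

#: Reserved epithet marking a historically unresolved species origin.
UNSPECIFIED = "unspecified"

#: Reserved conjunction joining alternative species origins.
VEL = "vel"


# ---------------------------------------------------------------------------
# Component types (slots I-IV)
# ---------------------------------------------------------------------------

class SpeciesOrigin(BaseModel):
    """Component I: ordered set of (genus, epithet) source species.

    Entries are stored canonically: genera in alphabetical order, and
    epithets of the same genus sorted case-insensitively.  The reserved
    epithet ``unspecified`` may only appear as the sole entry for its
    genus.
    """

    entries: tuple[tuple[str, str], ...]

    @field_validator("entries", mode="before")
    @classmethod
    def _coerce(cls, v):
        return tuple(tuple(e) for e in v)

    @model_validator(mode="after")
    def _validate(self) -> "SpeciesOrigin":
        if not self.entries:
            raise NmmValidationError("species origin requires at least one entry")
        seen = set()
        for genus, epithet in self.entries:
            if not GENUS_RE.match(genus):
                raise NmmValidationError(f"malformed genus token: {genus!r}")
            if epithet != UNSPECIFIED and not EPITHET_RE.match(epithet):
                raise NmmValidationError(f"malformed epithet token: {epithet!r}")
            if (genus, epithet) in seen:
                raise NmmValidationError(f"duplicate species entry: {genus} {epithet}")
            seen.add((genus, epithet))
        by_genus: dict[str, list[str]] = {}
        for genus, epithet in self.entries:
            by_genus.setdefault(genus, []).append(epithet)
        for genus, eps in by_genus.items():
            if UNSPECIFIED in eps and len(eps) > 1:
                raise NmmValidationError(
                    f"'unspecified' must be the sole entry for genus {genus}"
                )
        canonical = tuple(
            (g, e)
            for g in sorted(by_genus)
            for e in sorted(by_genus[g], key=str.lower)
        )
        if canonical != self.entries:
            object.__setattr__(self, "entries", canonical)
        return self

    @classmethod
    def from_binomials(cls, binomials: Sequence[str]) -> "SpeciesOrigin":
        """Build from strings like ``"Ephedra sinica"``."""
        entries = []
        for b in binomials:
            parts = b.split()
            if len(parts) != 2:
                raise NmmValidationError(f"not a binomial: {b!r}")
            entries.append((parts[0], parts[1]))
        return cls(entries=entries)

    @property
    def binomials(self) -> tuple[str, ...]:
        return tuple(f"{g} {e}" for g, e in self.entries)


class MedicinalPart(BaseModel):
    """Component II: medicinal part, e.g. (stem, herbaceous) -> "Stem-herbaceous"."""

    main: str
    qualifier: Optional[str] = None

    @model_validator(mode="after")
    def _validate(self) -> "MedicinalPart":
        if not self.main or not LOWER_TOKEN_RE.match(self.main):
            raise NmmValidationError(f"malformed medicinal-part token: {self.main!r}")
        if self.qualifier is not None and not LOWER_TOKEN_RE.match(self.qualifier):
            raise NmmValidationError(
                f"malformed part qualifier token: {self.qualifier!r}"
            )
        return self


class SpecialDescription(BaseModel):
    """Component III: ordered multi-word descriptors, e.g. [["freshly", "sliced"]]."""

    terms: tuple[tuple[str, ...], ...] = ()

    @field_validator("terms", mode="before")
    @classmethod
    def _coerce(cls, v):
        return tuple(tuple(t) for t in v)

    @model_validator(mode="after")
    def _validate(self) -> "SpecialDescription":
        for term in self.terms:
            if not term:
                raise NmmValidationError("empty special-description term")
            for w in term:
                if not LOWER_TOKEN_RE.match(w):
                    raise NmmValidationError(
                        f"malformed special-description word: {w!r}"
                    )
        return self


class ProcessingMethod(BaseModel):
    """One processing step: a verb plus an optional adjunct material."""

    verb: str
    adjunct: Optional[str] = None

    @model_validator(mode="after")
    def _validate(self) -> "ProcessingMethod":
        if not self.verb or not LOWER_TOKEN_RE.match(self.verb):
            raise NmmValidationError(f"malformed processing verb: {self.verb!r}")
        if self.adjunct is not None and not LOWER_TOKEN_RE.match(self.adjunct):
            raise NmmValidationError(f"malformed processing adjunct: {self.adjunct!r}")
        return self


class ProcessingMethodList(BaseModel):
    """Component IV: processing steps kept in process order."""

    methods: tuple[ProcessingMethod, ...] = ()


class NameComponents(BaseModel):
    """The four slots of a Systematic Name; species origin is mandatory."""

    species: SpeciesOrigin
    part: Optional[MedicinalPart] = None
    special: SpecialDescription = Field(default_factory=SpecialDescription)
    processing: ProcessingMethodList = Field(default_factory=ProcessingMethodList)


class NmmType(str, enum.Enum):
    """Raw material, initially prepared (agricultural), or processed for medicinal use."""

    raw = "raw"
    agricultural = "agricultural"
    processed = "processed"


class SystematicName(BaseModel):
    """Canonical rendered name string paired with its components."""

    text: str
    components: NameComponents


class GenericName(BaseModel):
    """Hyphenated romanized traditional name, e.g. "Jing-pian-jiang-huang"."""

    syllables: tuple[str, ...]
    rendered: str


class NmmId(BaseModel):
    """4-character base-36 identifier; canonical display "NMM-XXXX"."""

    value: int
    code: str

    @property
    def display(self) -> str:
        return f"NMM-{self.code}"

    @property
    def key(self) -> str:
        """Lowercase storage/lookup key, e.g. "nmm-0006"."""
        return f"nmm-{self.code.lower()}"


# ---------------------------------------------------------------------------
# Lexicons (component vocabularies, D6: data not code)
# ---------------------------------------------------------------------------

class Lexicon(BaseModel):
    """Vocabularies for the three non-species components.

    Construction and parsing consult these sets so that typos surface as
    errors naming the offending component instead of silently producing
    a plausible-looking name.  ``vel`` and ``unspecified`` are reserved
    words and may not appear in any vocabulary.
    """

    part_mains: frozenset[str]
    part_qualifiers: frozenset[str]
    special_terms: frozenset[tuple[str, ...]]
    processing_verbs: frozenset[str]
    processing_adjuncts: frozenset[str]

    @field_validator("special_terms", mode="before")
    @classmethod
    def _coerce(cls, v):
        return frozenset(tuple(t) for t in v)

    @model_validator(mode="after")
    def _no_reserved(self) -> "Lexicon":
        reserved = {VEL, UNSPECIFIED}
        pools = (
            self.part_mains, self.part_qualifiers,
            self.processing_verbs, self.processing_adjuncts,
        )
        for pool in pools:
            if reserved & set(pool):
                raise NmmValidationError("reserved token in lexicon")
        # a single-word descriptor doubling as a processing verb would make
        # rendered names ambiguous between components III and IV
        singles = {t[0] for t in self.special_terms if len(t) == 1}
        clash = singles & self.processing_verbs
        if clash:
            raise NmmValidationError(
                f"ambiguous lexicon: {sorted(clash)} appear both as "
                "special descriptors and processing verbs"
            )
        return self

    @classmethod
    def from_json(cls, path: str | Path) -> "Lexicon":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(**data)

    def to_json(self) -> str:
        data = {
            "part_mains": sorted(self.part_mains),
            "part_qualifiers": sorted(self.part_qualifiers),
            "special_terms": sorted(list(t) for t in self.special_terms),
            "processing_verbs": sorted(self.processing_verbs),
            "processing_adjuncts": sorted(self.processing_adjuncts),
        }
        return json.dumps(data, ensure_ascii=False, indent=1, sort_keys=True)


DEFAULT_LEXICON = Lexicon(
    part_mains=frozenset({
        "stem", "root", "rhizome", "herb", "leaf", "flower", "fruit",
        "seed", "bark", "tuber", "bulb", "branch", "wood", "resin",
        "pericarp", "spike",
    }),
    part_qualifiers=frozenset({
        "herbaceous", "woody", "tender", "aerial", "fibrous", "lateral",
    }),
    special_terms=frozenset({
        ("freshly", "sliced"), ("dried",), ("fresh",), ("wild",),
        ("sun", "dried"), ("peeled",), ("cored",),
    }),
    processing_verbs=frozenset({
        "cleaned", "segmented", "aquafried", "stirfried", "calcined",
        "steamed", "roasted", "carbonized", "sliced", "crushed",
    }),
    processing_adjuncts=frozenset({
        "honey", "salt", "vinegar", "wine", "bran", "ginger",
    }),
)


# ---------------------------------------------------------------------------
# Renderers (components -> text)
# ---------------------------------------------------------------------------

def format_species_origin(species: SpeciesOrigin) -> str:
    """Render component I.

    Same-genus entries render as the genus once followed by its epithets
    joined by " vel "; distinct genera render as full binomials joined by
    " vel ".
    """
    by_genus: dict[str, list[str]] = {}
    for genus, epithet in species.entries:
        by_genus.setdefault(genus, []).append(epithet)
    groups = [f"{genus} {' vel '.join(eps)}" for genus, eps in by_genus.items()]
    return " vel ".join(groups)


def format_medicinal_part(part: MedicinalPart) -> str:
    """Render component II: "Root", "Stem-herbaceous"."""
    text = part.main.capitalize()
    if part.qualifier:
        text += f"-{part.qualifier}"
    return text


def format_special_description(special: SpecialDescription) -> str:
    """Render component III: each descriptor hyphen-joined with the first
    word capitalized ("Freshly-sliced"); descriptors joined by spaces."""
    rendered = []
    for term in special.terms:
        rendered.append("-".join([term[0].capitalize(), *term[1:]]))
    return " ".join(rendered)


def format_processing_methods(processing: ProcessingMethodList) -> str:
    """Render component IV: "Cleaned", "Segmented and Aquafried-honey"."""
    rendered = []
    for m in processing.methods:
        text = m.verb.capitalize()
        if m.adjunct:
            text += f"-{m.adjunct}"
        rendered.append(text)
    return " and ".join(rendered)


def _check_lexicon(components: NameComponents, lexicon: Lexicon) -> None:
    if components.part is not None:
        if components.part.main not in lexicon.part_mains:
            raise NmmValidationError(
                f"medicinal part: unknown token {components.part.main!r}"
            )
        q = components.part.qualifier
        if q is not None and q not in lexicon.part_qualifiers:
            raise NmmValidationError(f"medicinal part: unknown qualifier {q!r}")
    for term in components.special.terms:
        if term not in lexicon.special_terms:
            raise NmmValidationError(
                f"special description: unknown term {'-'.join(term)!r}"
            )
    for m in components.processing.methods:
        if m.verb not in lexicon.processing_verbs:
            raise NmmValidationError(f"processing method: unknown verb {m.verb!r}")
        if m.adjunct is not None and m.adjunct not in lexicon.processing_adjuncts:
            raise NmmValidationError(
                f"processing method: unknown adjunct {m.adjunct!r}"
            )


def construct_systematic_name(
    components: NameComponents,
    lexicon: Lexicon | None = None,
) -> SystematicName:
    """Assemble the canonical Systematic Name from its four components.

    Non-empty component renderings are joined, in slot order I-IV, by
    single spaces.  When a lexicon is supplied, every part / special /
    processing token must belong to it; unknown tokens raise a validation
    error naming the offending component (species tokens are validated
    structurally only — Latin binomials are open-ended).
    """
    if lexicon is not None:
        _check_lexicon(components, lexicon)
    pieces = [format_species_origin(components.species)]
    if components.part is not None:
        pieces.append(format_medicinal_part(components.part))
    special = format_special_description(components.special)
    if special:
        pieces.append(special)
    processing = format_processing_methods(components.processing)
    if processing:
        pieces.append(processing)
    return SystematicName(text=" ".join(pieces), components=components)


# ---------------------------------------------------------------------------
# Parser (text -> components), inverse of construction over a lexicon
# ---------------------------------------------------------------------------

def parse_systematic_name(
    text: str,
    lexicon: Lexicon | None = None,
) -> NameComponents:
    """Parse a rendered Systematic Name back into components.

    Grammar (token = whitespace-separated word)::

        name     := species part? special* processing?
        species  := Genus epithet ("vel" (epithet | Genus epithet))*
        part     := Capitalized main token [-qualifier], main in lexicon
        special  := Capitalized-hyphenated descriptor in lexicon
        processing := method ("and" method)*

    Species tokens are consumed until the first token whose hyphen-split
    head is in the part lexicon (or, with no remaining tokens, the name
    is species-only).  Raises :class:`NmmParseError` with the 0-based
    token position on unknown tokens.
    """
    lexicon = lexicon or DEFAULT_LEXICON
    tokens = text.split()
    if not tokens:
        raise NmmParseError("empty name", position=0)

    def is_part_token(tok: str) -> bool:
        head, _, qual = tok.partition("-")
        return (
            head[:1].isupper()
            and head.lower() in lexicon.part_mains
            and (not qual or qual in lexicon.part_qualifiers)
        )

    # --- component I: species ---------------------------------------
    i = 0
    entries: list[tuple[str, str]] = []
    genus: str | None = None
    expecting_epithet = False
    while i < len(tokens):
        tok = tokens[i]
        if not expecting_epithet and is_part_token(tok) and entries:
            break
        if tok == VEL:
            if not entries:
                raise NmmParseError("'vel' before any species entry", position=i)
            expecting_epithet = True
            i += 1
            continue
        if GENUS_RE.match(tok) and (genus is None or expecting_epithet or False):
            # A capitalized token opens a (new) genus; its epithet follows.
            genus = tok
            i += 1
            if i >= len(tokens):
                raise NmmParseError(f"genus {tok!r} lacks an epithet", position=i)
            ep = tokens[i]
            if ep != UNSPECIFIED and not EPITHET_RE.match(ep):
                raise NmmParseError(f"malformed epithet {ep!r}", position=i)
            entries.append((genus, ep))
            expecting_epithet = False
            i += 1
            continue
        if expecting_epithet:
            if tok != UNSPECIFIED and not EPITHET_RE.match(tok):
                raise NmmParseError(f"malformed epithet {tok!r}", position=i)
            if genus is None:
                raise NmmParseError("epithet without genus", position=i)
            entries.append((genus, tok))
            expecting_epithet = False
            i += 1
            continue
        break
    if not entries:
        raise NmmParseError(f"no species origin found in {text!r}", position=0)

    # --- component II: medicinal part -------------------------------
    part: MedicinalPart | None = None
    if i < len(tokens) and is_part_token(tokens[i]):
        head, _, qual = tokens[i].partition("-")
        part = MedicinalPart(main=head.lower(), qualifier=qual or None)
        i += 1

    # --- components III & IV -----------------------------------------
    special_terms: list[tuple[str, ...]] = []
    methods: list[ProcessingMethod] = []
    while i < len(tokens):
        tok = tokens[i]
        if tok == "and":
            if not methods:
                raise NmmParseError("'and' outside processing list", position=i)
            i += 1
            if i >= len(tokens):
                raise NmmParseError("dangling 'and'", position=i)
            tok = tokens[i]
        words = tuple(w.lower() for w in tok.split("-"))
        if not methods and words in lexicon.special_terms:
            special_terms.append(words)
        elif words[0] in lexicon.processing_verbs and len(words) <= 2 and (
            len(words) == 1 or words[1] in lexicon.processing_adjuncts
        ):
            methods.append(
                ProcessingMethod(
                    verb=words[0],
                    adjunct=words[1] if len(words) == 2 else None,
                )
            )
        else:
            raise NmmParseError(f"unknown token {tok!r}", position=i)
        i += 1

    if (special_terms or methods) and part is None:
        raise NmmParseError(
            "special description / processing present but no medicinal part found",
            position=0,
        )

    return NameComponents(
        species=SpeciesOrigin(entries=entries),
        part=part,
        special=SpecialDescription(terms=special_terms),
        processing=ProcessingMethodList(methods=methods),
    )


# ---------------------------------------------------------------------------
# Generic Name
# ---------------------------------------------------------------------------

def format_generic_name(syllables: Sequence[str]) -> GenericName:
    """Hyphen-join romanized syllables, first capitalized: "Ma-huang"."""
    sylls = tuple(s.lower() for s in syllables)
    if not sylls or any(not LOWER_TOKEN_RE.match(s) for s in sylls):
        raise NmmValidationError(f"malformed generic-name syllables: {syllables!r}")
    rendered = "-".join([sylls[0].capitalize(), *sylls[1:]])
    return GenericName(syllables=sylls, rendered=rendered)


# ---------------------------------------------------------------------------
# NMM ID codec (base 36, alphabet 0-9 A-Z)
# ---------------------------------------------------------------------------

_ALPHABET = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"
_ID_RE = re.compile(r"^(?:nmm-)?([0-9a-z]{4})$", re.IGNORECASE)
MAX_ID = 36 ** 4  # 1 679 616 codes


def encode_nmm_id(n: int) -> NmmId:
    """Encode an integer as a zero-padded 4-character base-36 NMM ID."""
    if not 0 <= n < MAX_ID:
        raise NmmValidationError(f"NMM ID integer out of range [0, 36^4): {n}")
    digits = []
    v = n
    for _ in range(4):
        v, r = divmod(v, 36)
        digits.append(_ALPHABET[r])
    return NmmId(value=n, code="".join(reversed(digits)))


def decode_nmm_id(text: str) -> int:
    """Decode "NMM-0006" / "nmm-0006" / "0006" to its integer value."""
    m = _ID_RE.match(text.strip())
    if not m:
        raise NmmParseError(f"not a valid NMM ID: {text!r}")
    code = m.group(1).upper()
    n = 0
    for ch in code:
        n = n * 36 + _ALPHABET.index(ch)
    return n


def nmm_id_from_text(text: str) -> NmmId:
    """Parse an ID string into its canonical :class:`NmmId`."""
    return encode_nmm_id(decode_nmm_id(text))


# ---------------------------------------------------------------------------
# NMM type inference
# ---------------------------------------------------------------------------

def infer_nmm_type(components: NameComponents) -> NmmType:
    """Processed iff any processing method; agricultural iff a medicinal
    part (or special description) without processing; raw otherwise."""
    if components.processing.methods:
        return NmmType.processed
    if components.part is not None:
        return NmmType.agricultural
    return NmmType.raw
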