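"""Five-collection NMM knowledge base: load, validate, persist, revise.

The knowledge base is stored as one UTF-8 JSON array file per collection
inside a directory::

    snnmm.json      identity records (IDs, names, components, type)
    text.json       per-language abstracts (MLMD text)
    knowledge.json  section trees and contributor lists
    glossary.json   standardized translations keyed by (primary term, language)
    relation.json   coreference edges feeding the primary-term graph

Records are keyed by lowercase NMM-ID ("nmm-0006"); lookups are
case-insensitive.  A contribution workflow (submit -> review ->
accept/reject) is modeled as a pure state machine with an append-only
revision history.

:func:`generate_fixture_kb` produces a deterministic synthetic knowledge
base for offline testing.  It always contains the worked exemplar
records (Ma-huang = nmm-0006, Jing-pian-jiang-huang = nmm-0016, Ephedra
sinica Root, Taraxacum unspecified Herb, ...) so the toolkit's worked
examples run against any fixture, plus seeded random records whose names
are built through :func:`~nmmkit.nomenclature.construct_systematic_name`.
"""

from __future__ import annotations

import datetime
import json
import random
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, Field

from .errors import KbLoadError, NotFoundError, NmmValidationError, StateError
from .nomenclature import (
    DEFAULT_LEXICON,
    Lexicon,
    MedicinalPart,
    NameComponents,
    NmmId,
    NmmType,
    ProcessingMethod,
    ProcessingMethodList,
    SpecialDescription,
    SpeciesOrigin,
    construct_systematic_name,
    decode_nmm_id,
    encode_nmm_id,
    format_generic_name,
    infer_nmm_type,
)

__all__ = [
    "KnowledgeSection",
    "NmmRecord",
    "GlossaryEntry",
    "RelationEdge",
    "Revision",
    "KnowledgeBase",
    "COLLECTION_FILES",
    "load_kb",
    "save_kb",
    "generate_fixture_kb",
]

COLLECTION_FILES = (
    "snnmm.json", "text.json", "knowledge.json", "glossary.json", "relation.json",
)


class KnowledgeSection(BaseModel):
    """One titled knowledge section; children give the nested tree."""

    title: dict[str, str]
    body: str = ""
    children: list["KnowledgeSection"] = Field(default_factory=list)

    def model_post_init(self, __context) -> None:
        if not any(v for v in self.title.values()):
            raise NmmValidationError("section title must be non-empty")


class NmmRecord(BaseModel):
    """One knowledge-base entry for a Natural Medicinal Material."""

    nmm_id: NmmId
    systematic_name: dict[str, str]
    generic_name: dict[str, str]
    nmm_type: NmmType
    components: NameComponents
    abstract: dict[str, str] = Field(default_factory=dict)
    sections: list[KnowledgeSection] = Field(default_factory=list)
    contributors: list[str] = Field(default_factory=list)

    @property
    def key(self) -> str:
        return self.nmm_id.key

    @property
    def species_origins(self) -> tuple[str, ...]:
        return self.components.species.binomials


class GlossaryEntry(BaseModel):
    """Standardized translation of a primary term in one language."""

    primary_term: str
    language: str
    standardized_translation: str


class RelationEdge(BaseModel):
    """Directed coreference link: surface term -> term nearer the primary."""

    source_term: str
    source_language: str = "en"
    target_term: str
    relation: str = "coreference"

    def model_post_init(self, __context) -> None:
        if self.source_term == self.target_term:
            raise NmmValidationError(
                f"self-loop relation on term {self.source_term!r}"
            )


class Revision(BaseModel):
    """A proposed edit to one section of one record."""

    record_id: str
    section_path: tuple[int, ...]
    proposed_body: str
    contributor: str
    submitted_at: str = ""
    status: str = "pending"  # pending | accepted | rejected
    reviewer: Optional[str] = None
    reason: Optional[str] = None
    prior_body: Optional[str] = None


def _resolve_section(record: NmmRecord, path: tuple[int, ...]) -> KnowledgeSection:
    nodes = record.sections
    section = None
    for idx in path:
        if not 0 <= idx < len(nodes):
            raise NotFoundError(
                f"record {record.key}: no section at path {list(path)}"
            )
        section = nodes[idx]
        nodes = section.children
    if section is None:
        raise NotFoundError("empty section path")
    return section


class KnowledgeBase:
    """In-memory knowledge base with id and surface-term indexes."""

    def __init__(
        self,
        records: list[NmmRecord],
        glossary: list[GlossaryEntry],
        relations: list[RelationEdge],
    ):
        self.records: dict[str, NmmRecord] = {}
        for rec in records:
            if rec.key in self.records:
                raise KbLoadError(f"duplicate NMM id: {rec.key}")
            self.records[rec.key] = rec
        self.glossary: dict[tuple[str, str], GlossaryEntry] = {}
        for entry in glossary:
            gk = (entry.primary_term, entry.language)
            if gk in self.glossary:
                raise KbLoadError(
                    f"duplicate glossary entry: {entry.primary_term!r}/{entry.language}"
                )
            self.glossary[gk] = entry
        self.relations: list[RelationEdge] = list(relations)
        self.revisions: list[Revision] = []
        self._validate_integrity()

    # -- validation ----------------------------------------------------
    def _validate_integrity(self) -> None:
        for rec in self.records.values():
            expected = construct_systematic_name(rec.components).text
            got = rec.systematic_name.get("en")
            if got != expected:
                raise KbLoadError(
                    f"record {rec.key}: stored English systematic name {got!r} "
                    f"!= constructed {expected!r}"
                )
        glossary_primaries = {pt for pt, _lang in self.glossary}
        edge_sources = {e.source_term for e in self.relations}
        for edge in self.relations:
            t = edge.target_term
            if (
                t.lower() not in self.records
                and t not in glossary_primaries
                and t not in edge_sources
            ):
                raise KbLoadError(
                    f"relation {edge.source_term!r} -> {t!r}: dangling target"
                )

    # -- lookup --------------------------------------------------------
    def get_record(self, id_text: str) -> NmmRecord:
        """Case-insensitive lookup by NMM-ID text ("NMM-0006", "nmm-0006", "0006")."""
        key = encode_nmm_id(decode_nmm_id(id_text)).key
        if key not in self.records:
            raise NotFoundError(f"no record with id {key!r}")
        return self.records[key]

    def standard_translation(self, primary_term: str, language: str) -> str | None:
        entry = self.glossary.get((primary_term, language))
        return entry.standardized_translation if entry else None

    # -- contribution workflow -----------------------------------------
    def submit_revision(self, revision: Revision) -> int:
        """Store a pending revision; returns its index in the history."""
        record = self.get_record(revision.record_id)
        _resolve_section(record, revision.section_path)
        rev = revision.model_copy(update={"status": "pending"})
        if not rev.submitted_at:
            rev.submitted_at = datetime.datetime(
                2000, 1, 1, tzinfo=datetime.timezone.utc
            ).isoformat()
        self.revisions.append(rev)
        return len(self.revisions) - 1

    def review_revision(
        self,
        revision_id: int,
        verdict: str,
        reviewer: str,
        reason: str | None = None,
    ) -> Revision:
        """Accept (apply body, credit contributor) or reject (record reason)."""
        if not 0 <= revision_id < len(self.revisions):
            raise NotFoundError(f"no revision {revision_id}")
        rev = self.revisions[revision_id]
        if rev.status != "pending":
            raise StateError(
                f"revision {revision_id} already reviewed ({rev.status})"
            )
        if verdict == "accept":
            record = self.get_record(rev.record_id)
            section = _resolve_section(record, rev.section_path)
            rev.prior_body = section.body
            section.body = rev.proposed_body
            if rev.contributor not in record.contributors:
                record.contributors.append(rev.contributor)
            rev.status = "accepted"
            rev.reviewer = reviewer
        elif verdict == "reject":
            if not reason:
                raise NmmValidationError("rejection requires a reason")
            rev.status = "rejected"
            rev.reviewer = reviewer
            rev.reason = reason
        else:
            raise NmmValidationError(f"unknown verdict {verdict!r}")
        return rev

    # -- export / import -----------------------------------------------
    def export_record(self, id_text: str) -> dict:
        """Self-contained JSON-serializable document for one record."""
        rec = self.get_record(id_text)
        return _record_to_doc(rec)

    @staticmethod
    def import_record(doc: dict) -> NmmRecord:
        return _record_from_doc(doc)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _components_to_doc(c: NameComponents) -> dict:
    return {
        "species": [list(e) for e in c.species.entries],
        "part": (
            {"main": c.part.main, "qualifier": c.part.qualifier}
            if c.part else None
        ),
        "special": [list(t) for t in c.special.terms],
        "processing": [
            {"verb": m.verb, "adjunct": m.adjunct} for m in c.processing.methods
        ],
    }


def _components_from_doc(doc: dict) -> NameComponents:
    return NameComponents(
        species=SpeciesOrigin(entries=[tuple(e) for e in doc["species"]]),
        part=MedicinalPart(**doc["part"]) if doc.get("part") else None,
        special=SpecialDescription(terms=[tuple(t) for t in doc.get("special", [])]),
        processing=ProcessingMethodList(
            methods=[ProcessingMethod(**m) for m in doc.get("processing", [])]
        ),
    )


def _section_to_doc(s: KnowledgeSection) -> dict:
    return {
        "title": s.title,
        "body": s.body,
        "children": [_section_to_doc(c) for c in s.children],
    }


def _section_from_doc(doc: dict) -> KnowledgeSection:
    return KnowledgeSection(
        title=doc["title"],
        body=doc.get("body", ""),
        children=[_section_from_doc(c) for c in doc.get("children", [])],
    )


def _record_to_doc(rec: NmmRecord) -> dict:
    return {
        "nmm_id": rec.key,
        "systematic_name": rec.systematic_name,
        "generic_name": rec.generic_name,
        "nmm_type": rec.nmm_type.value,
        "components": _components_to_doc(rec.components),
        "abstract": rec.abstract,
        "sections": [_section_to_doc(s) for s in rec.sections],
        "contributors": rec.contributors,
    }


def _record_from_doc(doc: dict) -> NmmRecord:
    return NmmRecord(
        nmm_id=encode_nmm_id(decode_nmm_id(doc["nmm_id"])),
        systematic_name=doc["systematic_name"],
        generic_name=doc["generic_name"],
        nmm_type=NmmType(doc["nmm_type"]),
        components=_components_from_doc(doc["components"]),
        abstract=doc.get("abstract", {}),
        sections=[_section_from_doc(s) for s in doc.get("sections", [])],
        contributors=list(doc.get("contributors", [])),
    )


def _dump(obj) -> str:
    return json.dumps(obj, ensure_ascii=False, indent=1, sort_keys=True) + "\n"


def save_kb(kb: KnowledgeBase, path: str | Path) -> Path:
    """Write the five collection files (UTF-8, sorted keys, deterministic)."""
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    records = [kb.records[k] for k in sorted(kb.records)]
    snnmm = [
        {
            "nmm_id": r.key,
            "systematic_name": r.systematic_name,
            "generic_name": r.generic_name,
            "nmm_type": r.nmm_type.value,
            "components": _components_to_doc(r.components),
        }
        for r in records
    ]
    text = [{"nmm_id": r.key, "abstract": r.abstract} for r in records]
    knowledge = [
        {
            "nmm_id": r.key,
            "sections": [_section_to_doc(s) for s in r.sections],
            "contributors": r.contributors,
        }
        for r in records
    ]
    glossary = [
        kb.glossary[k].model_dump() for k in sorted(kb.glossary)
    ]
    relation = [
        e.model_dump()
        for e in sorted(
            kb.relations, key=lambda e: (e.source_term, e.target_term)
        )
    ]
    for name, payload in [
        ("snnmm.json", snnmm),
        ("text.json", text),
        ("knowledge.json", knowledge),
        ("glossary.json", glossary),
        ("relation.json", relation),
    ]:
        (out / name).write_text(_dump(payload), encoding="utf-8")
    return out


def load_kb(path: str | Path) -> KnowledgeBase:
    """Load and validate a collection directory.

    Raises :class:`KbLoadError` naming the offender on a missing
    collection file, duplicate id, name/component mismatch, or dangling
    relation target.
    """
    base = Path(path)
    raw: dict[str, list] = {}
    for name in COLLECTION_FILES:
        f = base / name
        if not f.is_file():
            raise KbLoadError(f"missing collection file: {name}")
        raw[name] = json.loads(f.read_text(encoding="utf-8"))

    text_by_id = {d["nmm_id"]: d for d in raw["text.json"]}
    knowledge_by_id = {d["nmm_id"]: d for d in raw["knowledge.json"]}
    records = []
    for doc in raw["snnmm.json"]:
        rid = doc["nmm_id"]
        merged = dict(doc)
        merged["abstract"] = text_by_id.get(rid, {}).get("abstract", {})
        kdoc = knowledge_by_id.get(rid, {})
        merged["sections"] = kdoc.get("sections", [])
        merged["contributors"] = kdoc.get("contributors", [])
        records.append(_record_from_doc(merged))
    glossary = [GlossaryEntry(**d) for d in raw["glossary.json"]]
    relations = [RelationEdge(**d) for d in raw["relation.json"]]
    return KnowledgeBase(records, glossary, relations)


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------

def _make_record(
    n: int,
    binomials: list[str],
    part: tuple[str, str | None] | None,
    special: list[tuple[str, ...]],
    processing: list[tuple[str, str | None]],
    generic_syllables: list[str],
    zh_name: str,
) -> NmmRecord:
    components = NameComponents(
        species=SpeciesOrigin.from_binomials(binomials),
        part=MedicinalPart(main=part[0], qualifier=part[1]) if part else None,
        special=SpecialDescription(terms=special),
        processing=ProcessingMethodList(
            methods=[ProcessingMethod(verb=v, adjunct=a) for v, a in processing]
        ),
    )
    nmm_id = encode_nmm_id(n)
    sys_name = construct_systematic_name(components)
    generic = format_generic_name(generic_syllables)
    record = NmmRecord(
        nmm_id=nmm_id,
        systematic_name={"en": sys_name.text, "zh": zh_name},
        generic_name={"en": generic.rendered, "zh": zh_name},
        nmm_type=infer_nmm_type(components),
        components=components,
        abstract={
            "en": f"[[{nmm_id.key}]] ({generic.rendered}) is a natural "
                  f"medicinal material derived from "
                  f"{', '.join(components.species.binomials)}.",
            "zh": f"[[{nmm_id.key}]]（{zh_name}）是一种天然药材。",
        },
        sections=[
            KnowledgeSection(
                title={"en": "Abstract", "zh": "摘要"},
                body=f"{{{{{zh_name}是一种天然药材。 :: "
                     f"[[{nmm_id.key}]] is a natural medicinal material.}}}}",
                children=[
                    KnowledgeSection(
                        title={"en": "Species origin", "zh": "物种基源"},
                        body=", ".join(components.species.binomials),
                    )
                ],
            )
        ],
    )
    return record


#: Worked exemplar records present in every fixture.
_EXEMPLARS = [
    # (int id, binomials, part, special, processing, generic syllables, zh name)
    (2, ["Ephedra sinica"], ("stem", "herbaceous"), [], [],
     ["cao", "ma", "huang"], "草麻黄"),
    (3, ["Ephedra sinica"], ("root", None), [], [],
     ["ma", "huang", "gen"], "麻黄根"),
    (4, ["Taraxacum unspecified"], ("herb", None), [], [],
     ["pu", "gong", "ying"], "蒲公英"),
    (5, ["Ephedra sinica"], ("stem", "herbaceous"), [],
     [("segmented", None), ("aquafried", "honey")],
     ["mi", "cao", "ma", "huang"], "蜜草麻黄"),
    (6, ["Ephedra equisetina", "Ephedra intermedia", "Ephedra sinica"],
     ("stem", "herbaceous"), [], [], ["ma", "huang"], "麻黄"),
    (42, ["Curcuma wenyujin"], ("rhizome", None), [("freshly", "sliced")],
     [("cleaned", None)], ["jing", "pian", "jiang", "huang"], "净片姜黄"),
]

_GENUS_SYLLABLES = [
    "an", "bel", "cor", "dra", "eph", "flor", "gal", "hum", "ix", "jun",
    "kal", "lum", "mor", "nex", "os", "pra", "qui", "ros", "sal", "tor",
]
_EPITHET_SYLLABLES = [
    "al", "bi", "cens", "dor", "en", "fol", "gra", "his", "ica", "lon",
    "ma", "nis", "ola", "pur", "ra", "sis", "ta", "ul", "vi", "za",
]
_PINYIN = [
    "bai", "cao", "chen", "dan", "fang", "gan", "hua", "jin", "ku", "lian",
    "mu", "ning", "pi", "qing", "ren", "shan", "tian", "wu", "xia", "ye",
    "zhi", "zi",
]
_ZH_CHARS = "草木花根茎叶果实山石白黄青紫甘苦参芝莲菊桂杞"


def _random_latin(rng: random.Random, syllables: list[str], n: int) -> str:
    return "".join(rng.choice(syllables) for _ in range(n))


def generate_fixture_kb(
    seed: int,
    n_records: int,
    out_dir: str | Path,
    lexicon: Lexicon = DEFAULT_LEXICON,
) -> Path:
    """Write a deterministic synthetic knowledge base to ``out_dir``.

    The fixture always contains the six worked exemplar records; when
    ``n_records`` exceeds six, seeded random records are added whose
    Systematic Names are constructed from the lexicon vocabularies.
    Identical ``(seed, n_records)`` produce byte-identical files.
    """
    if n_records < 1:
        raise NmmValidationError("n_records must be >= 1")
    rng = random.Random(seed)
    records = [_make_record(*spec) for spec in _EXEMPLARS]
    used_ids = {2, 3, 4, 5, 6, 42}
    used_zh = {r.systematic_name["zh"] for r in records}
    next_id = 100
    while len(records) < n_records:
        while next_id in used_ids:
            next_id += 1
        genus = _random_latin(rng, _GENUS_SYLLABLES, 2).capitalize()
        n_species = rng.choice([1, 1, 1, 2, 3])
        epithets = set()
        while len(epithets) < n_species:
            epithets.add(_random_latin(rng, _EPITHET_SYLLABLES, 2))
        binomials = [f"{genus} {e}" for e in sorted(epithets)]
        part = (
            rng.choice(sorted(lexicon.part_mains)),
            rng.choice([None, None, *sorted(lexicon.part_qualifiers)]),
        )
        special = (
            [rng.choice(sorted(lexicon.special_terms))]
            if rng.random() < 0.3 else []
        )
        n_proc = rng.choice([0, 0, 1, 1, 2])
        processing = [
            (
                rng.choice(sorted(lexicon.processing_verbs)),
                rng.choice([None, None, *sorted(lexicon.processing_adjuncts)]),
            )
            for _ in range(n_proc)
        ]
        syllables = [rng.choice(_PINYIN) for _ in range(rng.randint(2, 4))]
        zh_name = "".join(rng.choice(_ZH_CHARS) for _ in range(rng.randint(2, 4)))
        if zh_name in used_zh:
            continue
        used_zh.add(zh_name)
        records.append(
            _make_record(
                next_id, binomials, part, special, processing, syllables, zh_name
            )
        )
        used_ids.add(next_id)

    glossary: list[GlossaryEntry] = []
    relations: list[RelationEdge] = []
    for rec in records:
        std_en = (
            f"{rec.systematic_name['en']} "
            f"({rec.nmm_id.display}, {rec.generic_name['en']})"
        )
        std_zh = (
            f"{rec.systematic_name['zh']}"
            f"（{rec.nmm_id.display}，{rec.generic_name['zh']}）"
        )
        glossary.append(
            GlossaryEntry(
                primary_term=rec.key, language="en",
                standardized_translation=std_en,
            )
        )
        glossary.append(
            GlossaryEntry(
                primary_term=rec.key, language="zh",
                standardized_translation=std_zh,
            )
        )
        relations.append(
            RelationEdge(
                source_term=rec.systematic_name["zh"], source_language="zh",
                target_term=rec.key,
            )
        )
        relations.append(
            RelationEdge(
                source_term=rec.generic_name["en"], source_language="en",
                target_term=rec.key,
            )
        )
        spaced = " ".join(
            s.capitalize() for s in rec.generic_name["en"].split("-")
        )
        if spaced != rec.generic_name["en"]:
            relations.append(
                RelationEdge(
                    source_term=spaced, source_language="en",
                    target_term=rec.key,
                )
            )
    # Conventional-name alias chain for the Ma-huang exemplar: the Latin
    # pharmacopoeia name resolves through the Chinese surface term.
    relations.append(
        RelationEdge(
            source_term="Ephedrae Herba", source_language="en",
            target_term="麻黄",
        )
    )
    kb = KnowledgeBase(records, glossary, relations)
    return save_kb(kb, out_dir)
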