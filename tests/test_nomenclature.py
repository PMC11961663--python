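"""Systematic-name construction/parsing and NMM-ID codec."""

import pytest
from hypothesis import given, settings, strategies as st

from nmmkit.errors import NmmError, NmmParseError, NmmValidationError
from nmmkit.nomenclature import (
    DEFAULT_LEXICON,
    MAX_ID,
    MedicinalPart,
    NameComponents,
    NmmType,
    ProcessingMethod,
    ProcessingMethodList,
    SpecialDescription,
    SpeciesOrigin,
    construct_systematic_name,
    decode_nmm_id,
    encode_nmm_id,
    format_generic_name,
    format_medicinal_part,
    format_processing_methods,
    format_species_origin,
    infer_nmm_type,
    parse_systematic_name,
)


def components(binomials, part=None, special=(), processing=()):
    return NameComponents(
        species=SpeciesOrigin.from_binomials(binomials),
        part=MedicinalPart(main=part[0], qualifier=part[1]) if part else None,
        special=SpecialDescription(terms=list(special)),
        processing=ProcessingMethodList(
            methods=[ProcessingMethod(verb=v, adjunct=a) for v, a in processing]
        ),
    )


# ---------------------------------------------------------------------------
# Species origin (component I)
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "binomials,expected",
    [
        (["Ephedra equisetina", "Ephedra intermedia", "Ephedra sinica"],
         "Ephedra equisetina vel intermedia vel sinica"),
        (["Ephedra sinica"], "Ephedra sinica"),
        (["Taraxacum unspecified"], "Taraxacum unspecified"),
        # unsorted input is canonicalized by the sorting invariant
        (["Ephedra sinica", "Ephedra intermedia", "Ephedra equisetina"],
         "Ephedra equisetina vel intermedia vel sinica"),
        # distinct genera: full binomials joined by "vel", genera sorted
        (["Taraxacum unspecified", "Ephedra sinica"],
         "Ephedra sinica vel Taraxacum unspecified"),
    ],
)
def test_species_origin_rendering(binomials, expected):
    assert format_species_origin(SpeciesOrigin.from_binomials(binomials)) == expected


def test_species_origin_invariants():
    with pytest.raises(NmmError):
        SpeciesOrigin(entries=[])
    with pytest.raises(NmmError):
        SpeciesOrigin(entries=[("ephedra", "sinica")])  # genus not capitalized
    with pytest.raises(NmmError):
        SpeciesOrigin(entries=[("Ephedra", "Sinica")])  # epithet not lowercase
    with pytest.raises(NmmError):
        # "unspecified" must be the sole entry for its genus
        SpeciesOrigin(entries=[("Taraxacum", "unspecified"),
                               ("Taraxacum", "mongolicum")])


# ---------------------------------------------------------------------------
# Parts, special description, processing (components II-IV)
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "part,expected",
    [(("stem", "herbaceous"), "Stem-herbaceous"),
     (("root", None), "Root"),
     (("herb", None), "Herb")],
)
def test_medicinal_part_rendering(part, expected):
    assert format_medicinal_part(
        MedicinalPart(main=part[0], qualifier=part[1])
    ) == expected


def test_medicinal_part_requires_main():
    with pytest.raises(NmmError):
        MedicinalPart(main="")


@pytest.mark.parametrize(
    "methods,expected",
    [([("cleaned", None)], "Cleaned"),
     ([("segmented", None), ("aquafried", "honey")],
      "Segmented and Aquafried-honey"),
     ([], "")],
)
def test_processing_rendering(methods, expected):
    plist = ProcessingMethodList(
        methods=[ProcessingMethod(verb=v, adjunct=a) for v, a in methods]
    )
    assert format_processing_methods(plist) == expected


# ---------------------------------------------------------------------------
# Full systematic-name construction
# ---------------------------------------------------------------------------

WORKED_NAMES = [
    (components(["Curcuma wenyujin"], ("rhizome", None),
                [("freshly", "sliced")], [("cleaned", None)]),
     "Curcuma wenyujin Rhizome Freshly-sliced Cleaned"),
    (components(["Ephedra sinica"], ("stem", "herbaceous"), [],
                [("segmented", None), ("aquafried", "honey")]),
     "Ephedra sinica Stem-herbaceous Segmented and Aquafried-honey"),
    (components(["Ephedra equisetina", "Ephedra intermedia", "Ephedra sinica"],
                ("stem", "herbaceous")),
     "Ephedra equisetina vel intermedia vel sinica Stem-herbaceous"),
    (components(["Taraxacum unspecified"], ("herb", None)),
     "Taraxacum unspecified Herb"),
    (components(["Ephedra sinica"], ("root", None)),
     "Ephedra sinica Root"),
]


@pytest.mark.parametrize("comps,expected", WORKED_NAMES)
def test_construct_worked_names(comps, expected):
    assert construct_systematic_name(comps, lexicon=DEFAULT_LEXICON).text == expected


def test_construct_rejects_unknown_lexicon_tokens():
    comps = components(["Ephedra sinica"], ("frond", None))
    with pytest.raises(NmmValidationError, match="medicinal part"):
        construct_systematic_name(comps, lexicon=DEFAULT_LEXICON)
    # without a lexicon, structurally valid free tokens are allowed
    assert construct_systematic_name(comps).text == "Ephedra sinica Frond"


@pytest.mark.parametrize("comps,expected", WORKED_NAMES)
def test_parse_inverts_construction(comps, expected):
    parsed = parse_systematic_name(expected)
    assert construct_systematic_name(parsed).text == expected
    assert parsed == comps


def test_parse_errors():
    with pytest.raises(NmmParseError):
        parse_systematic_name("Wibble wobble Xyzzy")
    with pytest.raises(NmmParseError):
        parse_systematic_name("")
    err = None
    try:
        parse_systematic_name("Ephedra sinica Root Xyzzy")
    except NmmParseError as exc:
        err = exc
    assert err is not None and err.position == 3


# ---------------------------------------------------------------------------
# Generic names
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "syllables,expected",
    [(["ma", "huang"], "Ma-huang"),
     (["jing", "pian", "jiang", "huang"], "Jing-pian-jiang-huang"),
     (["ren"], "Ren")],
)
def test_generic_name(syllables, expected):
    assert format_generic_name(syllables).rendered == expected


def test_generic_name_rejects_empty():
    with pytest.raises(NmmValidationError):
        format_generic_name([])


# ---------------------------------------------------------------------------
# NMM-ID codec
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "n,display", [(6, "NMM-0006"), (0, "NMM-0000"), (1679615, "NMM-ZZZZ")]
)
def test_encode_nmm_id(n, display):
    assert encode_nmm_id(n).display == display


@pytest.mark.parametrize(
    "text,n", [("NMM-0006", 6), ("nmm-0016", 42), ("0A0A", 10 * 36 ** 2 + 10)]
)
def test_decode_nmm_id(text, n):
    assert decode_nmm_id(text) == n


@pytest.mark.parametrize("bad", ["NMM-00G!", "NMM-00065", "NMM-006", "xyz"])
def test_decode_rejects_malformed(bad):
    with pytest.raises(NmmParseError):
        decode_nmm_id(bad)


def test_encode_range_errors():
    for n in (-1, MAX_ID):
        with pytest.raises(NmmValidationError):
            encode_nmm_id(n)


@settings(deadline=None, max_examples=300)
@given(st.integers(min_value=0, max_value=MAX_ID - 1))
def test_id_roundtrip_property(n):
    assert decode_nmm_id(encode_nmm_id(n).display) == n
    assert decode_nmm_id(encode_nmm_id(n).key) == n  # lowercase accepted


# ---------------------------------------------------------------------------
# Type inference
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "comps,expected",
    [
        (WORKED_NAMES[0][0], NmmType.processed),
        (WORKED_NAMES[2][0], NmmType.agricultural),
        (components(["Ephedra sinica"]), NmmType.raw),
    ],
)
def test_infer_nmm_type(comps, expected):
    assert infer_nmm_type(comps) == expected


# ---------------------------------------------------------------------------
# Property tests over random component sets
# ---------------------------------------------------------------------------

_genus = st.from_regex(r"[A-Z][a-z]{2,8}", fullmatch=True)
_epithet = st.from_regex(r"[a-z]{2,10}", fullmatch=True).filter(
    lambda e: e not in ("vel", "and")
)
_parts = sorted(DEFAULT_LEXICON.part_mains)
_quals = sorted(DEFAULT_LEXICON.part_qualifiers)
_specials = sorted(DEFAULT_LEXICON.special_terms)
_verbs = sorted(DEFAULT_LEXICON.processing_verbs)
_adjs = sorted(DEFAULT_LEXICON.processing_adjuncts)


@st.composite
def component_sets(draw):
    genus = draw(_genus)
    epithets = draw(st.sets(_epithet, min_size=1, max_size=4))
    species = SpeciesOrigin(entries=[(genus, e) for e in epithets])
    part = draw(st.one_of(
        st.none(),
        st.builds(
            MedicinalPart,
            main=st.sampled_from(_parts),
            qualifier=st.one_of(st.none(), st.sampled_from(_quals)),
        ),
    ))
    special = SpecialDescription(
        terms=draw(st.lists(st.sampled_from(_specials), max_size=2, unique=True))
    )
    processing = ProcessingMethodList(methods=draw(st.lists(
        st.builds(
            ProcessingMethod,
            verb=st.sampled_from(_verbs),
            adjunct=st.one_of(st.none(), st.sampled_from(_adjs)),
        ),
        max_size=3,
    )))
    if part is None:
        special = SpecialDescription()
        processing = ProcessingMethodList()
    return NameComponents(
        species=species, part=part, special=special, processing=processing
    )


@settings(deadline=None, max_examples=200)
@given(component_sets())
def test_random_names_are_canonical(comps):
    """Rendered names have no doubled spaces, keep component order, and
    honour the per-genus 'vel' count; construct∘parse is idempotent."""
    name = construct_systematic_name(comps, lexicon=DEFAULT_LEXICON)
    assert "  " not in name.text
    assert name.text == name.text.strip()
    n_vel_expected = sum(
        len([e for g2, e in comps.species.entries if g2 == g]) - 1
        for g in {g for g, _ in comps.species.entries}
    ) + (len({g for g, _ in comps.species.entries}) - 1)
    species_text = format_species_origin(comps.species)
    assert species_text.split().count("vel") == n_vel_expected
    assert name.text.startswith(species_text)

    # genus tokens may collide with lexicon vocab in rare draws; the
    # parser contract only covers names whose species tokens are free
    genus_heads = {g.lower() for g, _ in comps.species.entries}
    if genus_heads & set(_parts):
        return
    reparsed = parse_systematic_name(name.text)
    assert construct_systematic_name(reparsed).text == name.text
    assert reparsed == comps
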