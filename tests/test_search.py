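"""Full-text, vector, and name-component search against brute-force oracles."""

import math
import random
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nmmkit.errors import NmmValidationError
from nmmkit.search import (
    ComponentQuery,
    HashedEmbedder,
    build_index,
    fulltext_search,
    search_by_name_components,
    tokenize,
    vector_search,
)


# ---------------------------------------------------------------------------
# Tokenizer
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "text,expected",
    [
        ("Ephedra sinica", ["ephedra", "sinica"]),
        ("麻黄碱", ["麻黄", "黄碱"]),
        ("", []),
        ("草", ["草"]),
        ("NMM-0006 麻黄", ["nmm", "0006", "麻黄"]),
    ],
)
def test_tokenize(text, expected):
    assert tokenize(text) == expected


# ---------------------------------------------------------------------------
# Inverted index
# ---------------------------------------------------------------------------

def test_shared_token_posting():
    idx = build_index({"a": "ephedra root", "b": "ephedra stem"})
    assert set(idx.postings["ephedra"]) == {"a", "b"}
    assert idx.doc_count == 2


def test_empty_corpus():
    idx = build_index({})
    assert idx.postings == {} and idx.doc_count == 0


def test_duplicate_doc_id_rejected():
    with pytest.raises(NmmValidationError):
        build_index([("a", "x"), ("a", "y")])


@settings(deadline=None, max_examples=50)
@given(st.dictionaries(
    st.from_regex(r"d[0-9]{1,3}", fullmatch=True),
    st.lists(st.sampled_from("麻黄 根 ephedra root stem 草".split()),
             max_size=8).map(" ".join),
    max_size=10,
))
def test_postings_reconstruct_token_multisets(corpus):
    """Recount oracle: postings recover the exact token multiset per doc."""
    idx = build_index(corpus)
    for doc_id, text in corpus.items():
        recovered = Counter()
        for token, plist in idx.postings.items():
            if doc_id in plist:
                recovered[token] = plist[doc_id]
        assert recovered == Counter(tokenize(text))
        assert idx.doc_lengths[doc_id] == sum(recovered.values())


# ---------------------------------------------------------------------------
# Full-text search vs exhaustive oracle
# ---------------------------------------------------------------------------

def brute_force_fulltext(corpus, query, k):
    """Independent oracle: score every document directly with numpy."""
    docs = {d: Counter(tokenize(t)) for d, t in corpus.items()}
    q = Counter(tokenize(query))
    n = len(corpus)
    df = Counter()
    for tf in docs.values():
        df.update(tf.keys())

    def idf(t):
        return math.log((1 + n) / (1 + df[t])) + 1.0 if df[t] else 0.0

    vocab = sorted(set().union(*[set(tf) for tf in docs.values()] or [set()]))
    scores = {}
    qv = np.array([q.get(t, 0) * idf(t) for t in vocab], dtype=float)
    if np.linalg.norm(qv) == 0:
        return []
    for d, tf in docs.items():
        dv = np.array([tf.get(t, 0) * idf(t) for t in vocab], dtype=float)
        if np.linalg.norm(dv) == 0:
            continue
        s = float(qv @ dv / (np.linalg.norm(qv) * np.linalg.norm(dv)))
        if s > 0:
            scores[d] = s
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    return ranked


def test_exact_document_ranks_first():
    corpus = {"a": "ephedra stem herbaceous", "b": "curcuma rhizome",
              "c": "taraxacum herb"}
    hits = fulltext_search(build_index(corpus), "curcuma rhizome", k=3)
    assert hits[0].doc_id == "b" and hits[0].rank == 1


def test_unindexed_query_is_empty():
    idx = build_index({"a": "ephedra"})
    assert fulltext_search(idx, "zzzz qqqq", k=5) == []


@settings(deadline=None, max_examples=40)
@given(st.integers(min_value=0, max_value=10_000))
def test_fulltext_matches_brute_force(seed):
    rng = random.Random(seed)
    words = "麻黄 根 茎 ephedra curcuma root stem herb 草 黄".split()
    corpus = {
        f"d{i:03d}": " ".join(rng.choices(words, k=rng.randint(1, 10)))
        for i in range(rng.randint(2, 30))
    }
    query = " ".join(rng.choices(words, k=rng.randint(1, 4)))
    k = rng.randint(1, 5)
    hits = fulltext_search(build_index(corpus), query, k=k)
    oracle = brute_force_fulltext(corpus, query, k)
    assert [h.doc_id for h in hits] == [d for d, _ in oracle]
    for h, (_, s) in zip(hits, oracle):
        assert h.score == pytest.approx(s, abs=1e-12)


# ---------------------------------------------------------------------------
# Vector search
# ---------------------------------------------------------------------------

def test_identical_vector_is_rank_one():
    rng = np.random.default_rng(0)
    store = {f"d{i}": rng.normal(size=8) for i in range(5)}
    hits = vector_search(store, store["d3"], k=3)
    assert hits[0].doc_id == "d3"
    assert hits[0].score == pytest.approx(1.0)


def test_orthogonal_vectors_score_zero():
    store = {"a": np.array([1.0, 0.0])}
    hits = vector_search(store, np.array([0.0, 1.0]), k=1)
    assert hits[0].score == pytest.approx(0.0)


def test_zero_query_rejected():
    with pytest.raises(NmmValidationError):
        vector_search({"a": np.ones(3)}, np.zeros(3), k=1)


def test_dim_mismatch_rejected():
    with pytest.raises(NmmValidationError):
        vector_search({"a": np.ones(3)}, np.ones(4), k=1)


@settings(deadline=None, max_examples=40)
@given(st.integers(min_value=0, max_value=10_000))
def test_vector_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    n, dim = int(rng.integers(2, 40)), int(rng.integers(2, 16))
    store = {f"d{i:03d}": rng.normal(size=dim) for i in range(n)}
    q = rng.normal(size=dim)
    k = int(rng.integers(1, 6))
    hits = vector_search(store, q, k=k)
    sims = {
        d: float(v @ q / (np.linalg.norm(v) * np.linalg.norm(q)))
        for d, v in store.items()
    }
    expected = sorted(sims.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    assert [h.doc_id for h in hits] == [d for d, _ in expected]
    assert all(-1.0 - 1e-12 <= h.score <= 1.0 + 1e-12 for h in hits)
    assert [h.rank for h in hits] == list(range(1, len(hits) + 1))


def test_hashed_embedder_is_deterministic():
    e1 = HashedEmbedder(dim=64, seed=5)
    e2 = HashedEmbedder(dim=64, seed=5)
    assert np.array_equal(e1("麻黄 ephedra"), e2("麻黄 ephedra"))
    assert np.linalg.norm(e1("麻黄 ephedra")) == pytest.approx(1.0)
    e3 = HashedEmbedder(dim=64, seed=6)
    assert not np.array_equal(e1("麻黄 ephedra"), e3("麻黄 ephedra"))


# ---------------------------------------------------------------------------
# Name-component search
# ---------------------------------------------------------------------------

def test_species_constraint_matches_membership(kb):
    hits = search_by_name_components(
        kb, ComponentQuery(species="Ephedra sinica")
    )
    names = {h.systematic_name["en"] for h in hits}
    assert {
        "Ephedra sinica Stem-herbaceous",
        "Ephedra equisetina vel intermedia vel sinica Stem-herbaceous",
        "Ephedra sinica Root",
    } <= names
    assert "Taraxacum unspecified Herb" not in names


def test_added_part_constraint_narrows(kb):
    hits = search_by_name_components(
        kb,
        ComponentQuery(species="Ephedra sinica", part_main="stem",
                       part_qualifier="herbaceous"),
    )
    names = {h.systematic_name["en"] for h in hits}
    assert "Ephedra sinica Stem-herbaceous" in names
    assert (
        "Ephedra equisetina vel intermedia vel sinica Stem-herbaceous" in names
    )
    assert "Ephedra sinica Root" not in names


def test_empty_query_returns_all_sorted(kb):
    hits = search_by_name_components(kb, ComponentQuery())
    assert len(hits) == len(kb.records)
    values = [h.nmm_id.value for h in hits]
    assert values == sorted(values)


_constraints = st.fixed_dictionaries({}, optional={
    "species": st.sampled_from(["Ephedra sinica", "Curcuma wenyujin",
                                "Taraxacum unspecified", "Nope nope"]),
    "part_main": st.sampled_from(["stem", "root", "rhizome", "herb"]),
    "part_qualifier": st.sampled_from(["herbaceous"]),
    "processing_verb": st.sampled_from(["cleaned", "segmented", "aquafried"]),
    "processing_adjunct": st.sampled_from(["honey", "salt"]),
    "special": st.sampled_from([("freshly", "sliced"), ("dried",)]),
})


@settings(deadline=None, max_examples=100)
@given(_constraints, st.sampled_from([
    "species", "part_main", "processing_verb", "special"
]))
def test_component_query_monotonicity(kb, constraints, dropped):
    """Adding a constraint never enlarges the result set."""
    base = dict(constraints)
    base.pop(dropped, None)
    wider = {r.key for r in search_by_name_components(kb, ComponentQuery(**base))}
    narrower = {
        r.key for r in search_by_name_components(kb, ComponentQuery(**constraints))
    }
    assert narrower <= wider
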