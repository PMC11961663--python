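"""Three-strategy search layer.

* **Full-text search** — tokenized inverted index with TF-IDF weighting
  and cosine normalization.  The default tokenizer lowercases Latin
  alphanumeric runs and emits overlapping character bigrams for CJK runs
  (a lone CJK character emits itself); any callable ``text -> [token]``
  can be plugged in instead.
* **Vector search** — cosine similarity over a store of fixed-dimension
  embeddings.  The default embedder is a deterministic seeded
  hashed bag-of-tokens projection (L2-normalized, 1536 dimensions by
  default); real embedding backends satisfy the same contract.
* **Name-component search** — AND-semantics filtering of NMM records on
  species origin, medicinal part, special description and processing
  method.
"""

from __future__ import annotations

import hashlib
import math
import re
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .errors import NmmValidationError
from .knowledgebase import KnowledgeBase, NmmRecord

__all__ = [
    "tokenize",
    "InvertedIndex",
    "build_index",
    "fulltext_search",
    "SearchHit",
    "HashedEmbedder",
    "vector_search",
    "ComponentQuery",
    "search_by_name_components",
]

# CJK unified ideographs (base + extension A) and compatibility block.
_CJK = r"㐀-䶿一-鿿豈-﫿"
_TOKEN_RE = re.compile(rf"[a-zA-Z0-9]+|[{_CJK}]+")


def tokenize(text: str) -> list[str]:
    """Default tokenizer: Latin/numeric runs lowercased; CJK runs as
    overlapping character bigrams (single character emits itself)."""
    tokens: list[str] = []
    for m in _TOKEN_RE.finditer(text):
        run = m.group(0)
        if run[0].isascii():
            tokens.append(run.lower())
        elif len(run) == 1:
            tokens.append(run)
        else:
            tokens.extend(run[i:i + 2] for i in range(len(run) - 1))
    return tokens


Tokenizer = Callable[[str], list[str]]


@dataclass(frozen=True)
class SearchHit:
    doc_id: str
    score: float
    rank: int


@dataclass
class InvertedIndex:
    """Token -> {doc id: term frequency} postings over a fixed corpus."""

    postings: dict[str, dict[str, int]]
    doc_count: int
    doc_lengths: dict[str, int]
    tokenizer: Tokenizer


def build_index(
    corpus: Mapping[str, str] | Sequence[tuple[str, str]],
    tokenizer: Tokenizer = tokenize,
) -> InvertedIndex:
    """Tokenize a corpus and build the inverted index (deterministic).

    ``corpus`` maps doc id -> text (a sequence of pairs is also
    accepted); duplicate ids are rejected.
    """
    pairs = list(corpus.items()) if isinstance(corpus, Mapping) else list(corpus)
    ids = [doc_id for doc_id, _ in pairs]
    if len(set(ids)) != len(ids):
        raise NmmValidationError("duplicate document id in corpus")
    postings: dict[str, dict[str, int]] = {}
    doc_lengths: dict[str, int] = {}
    for doc_id, text in pairs:
        tokens = tokenizer(text)
        doc_lengths[doc_id] = len(tokens)
        for token, tf in Counter(tokens).items():
            postings.setdefault(token, {})[doc_id] = tf
    return InvertedIndex(
        postings=postings,
        doc_count=len(ids),
        doc_lengths=doc_lengths,
        tokenizer=tokenizer,
    )


def _idf(index: InvertedIndex, token: str) -> float:
    df = len(index.postings.get(token, {}))
    if df == 0:
        return 0.0
    return math.log((1 + index.doc_count) / (1 + df)) + 1.0


def _rank(scored: dict[str, float], k: int) -> list[SearchHit]:
    ordered = sorted(scored.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    return [
        SearchHit(doc_id=d, score=s, rank=r + 1)
        for r, (d, s) in enumerate(ordered)
    ]


def fulltext_search(
    index: InvertedIndex, query: str, k: int = 10
) -> list[SearchHit]:
    """TF-IDF / cosine ranking of the corpus against a free-text query.

    Score(d, q) = cos( w(d), w(q) ) with w_t = tf_t * idf_t and
    idf_t = ln((1+N)/(1+df_t)) + 1.  Ties break by ascending doc id.
    """
    if k < 1:
        raise NmmValidationError("k must be >= 1")
    q_tf = Counter(index.tokenizer(query))
    q_weights = {
        t: tf * _idf(index, t)
        for t, tf in q_tf.items()
        if t in index.postings
    }
    if not q_weights:
        return []
    q_norm = math.sqrt(sum(w * w for w in q_weights.values()))
    # accumulate dot products over candidate docs via postings
    dots: dict[str, float] = {}
    for token, q_w in q_weights.items():
        idf = _idf(index, token)
        for doc_id, tf in index.postings[token].items():
            dots[doc_id] = dots.get(doc_id, 0.0) + q_w * tf * idf
    # per-document norms over the full token vector
    doc_norm_sq: dict[str, float] = {d: 0.0 for d in dots}
    for token, plist in index.postings.items():
        idf = _idf(index, token)
        for doc_id, tf in plist.items():
            if doc_id in doc_norm_sq:
                doc_norm_sq[doc_id] += (tf * idf) ** 2
    scored = {
        d: dots[d] / (q_norm * math.sqrt(doc_norm_sq[d]))
        for d in dots
        if doc_norm_sq[d] > 0
    }
    return _rank(scored, k)


# ---------------------------------------------------------------------------
# Vector search
# ---------------------------------------------------------------------------

class HashedEmbedder:
    """Deterministic hashed bag-of-tokens embedding.

    Each token is hashed (BLAKE2, keyed by the seed) to a coordinate and
    a sign; token counts are accumulated and the vector L2-normalized.
    Identical text, seed and dimension always give identical vectors, so
    the embedder stands in for a real sentence-embedding backend in
    offline pipelines while honouring the same ``text -> vector``
    contract.
    """

    def __init__(self, dim: int = 1536, seed: int = 0,
                 tokenizer: Tokenizer = tokenize):
        if dim < 1:
            raise NmmValidationError("embedding dimension must be >= 1")
        self.dim = dim
        self.seed = seed
        self.tokenizer = tokenizer

    def __call__(self, text: str) -> np.ndarray:
        vec = np.zeros(self.dim, dtype=np.float64)
        for token in self.tokenizer(text):
            h = hashlib.blake2b(
                token.encode("utf-8"),
                digest_size=8,
                key=str(self.seed).encode(),
            ).digest()
            value = int.from_bytes(h, "big")
            idx = value % self.dim
            sign = 1.0 if (value >> 63) & 1 == 0 else -1.0
            vec[idx] += sign
        norm = np.linalg.norm(vec)
        if norm > 0:
            vec /= norm
        return vec


def vector_search(
    store: Mapping[str, np.ndarray],
    query_vec: np.ndarray,
    k: int = 10,
) -> list[SearchHit]:
    """Top-k documents by cosine similarity to the query vector."""
    if k < 1:
        raise NmmValidationError("k must be >= 1")
    q = np.asarray(query_vec, dtype=np.float64)
    q_norm = np.linalg.norm(q)
    if q_norm == 0:
        raise NmmValidationError("zero query vector: cosine similarity undefined")
    scored: dict[str, float] = {}
    for doc_id, vec in store.items():
        v = np.asarray(vec, dtype=np.float64)
        if v.shape != q.shape:
            raise NmmValidationError(
                f"dimension mismatch: store {v.shape[0]} vs query {q.shape[0]}"
            )
        v_norm = np.linalg.norm(v)
        if v_norm == 0:
            continue
        scored[doc_id] = float(np.dot(q, v) / (q_norm * v_norm))
    return _rank(scored, k)


# ---------------------------------------------------------------------------
# Name-component search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComponentQuery:
    """Optional constraints ANDed over Systematic-Name components.

    ``species`` is a binomial ("Ephedra sinica") that must be a member
    of the record's species-origin set.  ``part_main``/``part_qualifier``
    constrain the medicinal part; ``special`` is a descriptor word tuple;
    ``processing_verb``/``processing_adjunct`` constrain any one
    processing step.  The empty query matches every record.
    """

    species: Optional[str] = None
    part_main: Optional[str] = None
    part_qualifier: Optional[str] = None
    special: Optional[tuple[str, ...]] = None
    processing_verb: Optional[str] = None
    processing_adjunct: Optional[str] = None


def _matches(record: NmmRecord, query: ComponentQuery) -> bool:
    c = record.components
    if query.species is not None:
        if query.species not in c.species.binomials:
            return False
    if query.part_main is not None:
        if c.part is None or c.part.main != query.part_main:
            return False
    if query.part_qualifier is not None:
        if c.part is None or c.part.qualifier != query.part_qualifier:
            return False
    if query.special is not None:
        if tuple(query.special) not in c.special.terms:
            return False
    if query.processing_verb is not None:
        steps = [
            m for m in c.processing.methods if m.verb == query.processing_verb
        ]
        if not steps:
            return False
        if query.processing_adjunct is not None and not any(
            m.adjunct == query.processing_adjunct for m in steps
        ):
            return False
    elif query.processing_adjunct is not None:
        if not any(
            m.adjunct == query.processing_adjunct for m in c.processing.methods
        ):
            return False
    return True


def search_by_name_components(
    kb: KnowledgeBase, query: ComponentQuery
) -> list[NmmRecord]:
    """Records satisfying every constraint, sorted by NMM id."""
    hits = [r for r in kb.records.values() if _matches(r, query)]
    return sorted(hits, key=lambda r: r.nmm_id.value)
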