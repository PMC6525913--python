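"""Word embeddings for synonym proposal.

Vectors are learned by factorising a positive pointwise-mutual-information
(PPMI) co-occurrence matrix with truncated SVD.  This count-based
formulation captures the same distributional signal as sampled
predict-style embeddings (tokens used in interchangeable contexts get
nearly parallel vectors) while being exactly reproducible: the
co-occurrence counts are deterministic and the factorisation is seeded.

The training stream for each record is the concatenation of its title,
abstract, and index terms, tokenized by the same normalizer the matcher
uses, so embedding vocabulary and matching vocabulary agree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import TruncatedSVD

from .normalize import normalize_text


@dataclass(frozen=True)
class EmbeddingConfig:
    """Hyperparameters for co-occurrence embedding training.

    vector_size:
        Dimensionality of the factorised vectors (capped at vocab size - 1).
    window:
        Symmetric co-occurrence window in tokens.
    min_count:
        Minimum corpus frequency for a token to receive a vector.
    seed:
        Seed for the randomized SVD solver.
    """

    vector_size: int = 100
    window: int = 5
    min_count: int = 5
    seed: int = 0


class EmbeddingModel:
    """Token vectors with cosine nearest-neighbour queries.

    Also records, per token, the set of documents it occurs in, which the
    synonym proposer uses to check that a candidate for a multi-word term
    actually co-occurs with the term's remaining tokens somewhere.
    """

    def __init__(self, tokens: list[str], vectors: np.ndarray,
                 doc_sets: dict[str, set[int]], config: EmbeddingConfig):
        norms = np.linalg.norm(vectors, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        self._tokens = tokens
        self._index = {t: i for i, t in enumerate(tokens)}
        self._unit = vectors / norms
        self._doc_sets = doc_sets
        self.config = config

    def __contains__(self, token: str) -> bool:
        return token in self._index

    @property
    def vocabulary(self) -> list[str]:
        return list(self._tokens)

    def vector(self, token: str) -> np.ndarray:
        """Unit vector for ``token``; KeyError if below min_count/unseen."""
        if token not in self._index:
            raise KeyError(
                f"token {token!r} not in embedding vocabulary (needs >= "
                f"{self.config.min_count} corpus occurrences)")
        return self._unit[self._index[token]]

    def most_similar(self, token: str, k: int) -> list[tuple[str, float]]:
        """Top-``k`` neighbours by cosine similarity, excluding the token.

        Ties break lexicographically; ``k=0`` returns an empty list.
        """
        if k <= 0:
            return []
        query = self.vector(token)
        sims = self._unit @ query
        order = sorted(
            (i for i in range(len(self._tokens)) if self._tokens[i] != token),
            key=lambda i: (-round(float(sims[i]), 12), self._tokens[i]))
        return [(self._tokens[i], float(sims[i])) for i in order[:k]]

    def cooccurs_in_document(self, a: str, b: str) -> bool:
        """True if tokens ``a`` and ``b`` share at least one document."""
        return bool(self._doc_sets.get(a, set()) & self._doc_sets.get(b, set()))


def _record_stream(record) -> list[str]:
    tokens = [t.text for t in normalize_text(record.title)]
    tokens += [t.text for t in normalize_text(record.abstract)]
    for term in sorted(record.index_terms):
        tokens += [t.text for t in normalize_text(term)]
    return tokens


def train_embedding(corpora: Iterable, config: EmbeddingConfig | None = None,
                    ) -> EmbeddingModel:
    """Train a PPMI-SVD embedding over concept corpora.

    Raises ``ValueError`` if fewer than two tokens reach ``min_count``
    occurrences (no meaningful neighbour structure exists below that).
    Deterministic for a fixed config: counting is exact and the SVD uses
    the configured seed.
    """
    config = config or EmbeddingConfig()
    counts: dict[str, int] = {}
    doc_sets: dict[str, set[int]] = {}
    streams: list[list[str]] = []
    doc_id = 0
    for corpus in corpora:
        for rec in corpus.records:
            stream = _record_stream(rec)
            streams.append(stream)
            for tok in set(stream):
                doc_sets.setdefault(tok, set()).add(doc_id)
            for tok in stream:
                counts[tok] = counts.get(tok, 0) + 1
            doc_id += 1

    vocab = sorted(t for t, c in counts.items() if c >= config.min_count)
    if len(vocab) < 2:
        raise ValueError(
            f"corpus too small: need >= {config.min_count} occurrences for "
            f"at least 2 tokens, found {len(vocab)}")
    index = {t: i for i, t in enumerate(vocab)}

    rows: list[int] = []
    cols: list[int] = []
    for stream in streams:
        ids = [index.get(t, -1) for t in stream]
        n = len(ids)
        for i, ti in enumerate(ids):
            if ti < 0:
                continue
            for j in range(i + 1, min(i + 1 + config.window, n)):
                tj = ids[j]
                if tj < 0:
                    continue
                rows.extend((ti, tj))
                cols.extend((tj, ti))
    data = np.ones(len(rows), dtype=np.float64)
    cooc = sp.coo_matrix((data, (rows, cols)),
                         shape=(len(vocab), len(vocab))).tocsr()

    row_sums = np.asarray(cooc.sum(axis=1)).ravel()
    # context-distribution smoothing (alpha=0.75) damps the inflated PMI
    # of rare contexts and the ubiquity of function words
    ctx = row_sums ** 0.75
    ctx_total = ctx.sum()
    total = cooc.sum()
    coo = cooc.tocoo()
    # PPMI: max(0, log(p(i,j) / (p(i) p_smoothed(j))))
    pmi = np.log((coo.data / total)
                 / ((row_sums[coo.row] / total) * (ctx[coo.col] / ctx_total)))
    keep = pmi > 0
    ppmi = sp.csr_matrix((pmi[keep], (coo.row[keep], coo.col[keep])),
                         shape=cooc.shape)

    n_comp = max(1, min(config.vector_size, len(vocab) - 1))
    svd = TruncatedSVD(n_components=n_comp, random_state=config.seed)
    reduced = svd.fit_transform(ppmi)  # U * Sigma
    # scale back to U * sqrt(Sigma): balances word/context spaces
    sigma = svd.singular_values_.copy()
    sigma[sigma == 0] = 1.0
    vectors = reduced / np.sqrt(sigma)

    doc_sets = {t: s for t, s in doc_sets.items() if t in index}
    return EmbeddingModel(vocab, vectors, doc_sets, config)
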