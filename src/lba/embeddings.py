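"""Turn open-ended responses into fixed-length feature vectors.

Two extraction regimes are supported behind one embedder contract:

* contextualized — the whole token sequence passes through the embedder at
  once, so each token's vector can depend on its neighbours; the selected
  layer's token vectors are then mean-pooled into one response vector.
* decontextualized — every word is embedded as its own one-word document
  (the embedder never sees any context), and the word vectors are pooled.
  This regime is order-invariant by construction.

By default the second-to-last layer is used (layer index ``-2``), following
evidence that the penultimate layer of deep transformers is the most
reliable representation for document- and person-level prediction: for a
24-layer model this is layer 23.

Real transformer backends plug in by implementing :class:`EmbedderContract`.
The deterministic :class:`HashEmbedder` used throughout the test-suite
draws each token's vector from a hash of the token string, optionally
adding a previous-token interaction term so that context sensitivity can
be switched on and off at will.
"""

from __future__ import annotations

import re
import zlib
from abc import ABC, abstractmethod
from dataclasses import dataclass

import numpy as np

from .datatypes import EmbeddingMatrix, ResponseSet
from .errors import AlignmentError, InvalidInputError, InvalidParameterError

__all__ = [
    "tokenize",
    "normalize_token",
    "EmbedderContract",
    "HashEmbedder",
    "embed_contextualized",
    "embed_decontextualized",
    "aggregate_tokens",
    "combine_feature_sets",
]

BOUNDARY_TOKENS = ("[CLS]", "[SEP]")

_PUNCT_RE = re.compile(r"[^\w\s'-]", flags=re.UNICODE)


def normalize_token(token: str) -> str:
    """Lowercase and strip punctuation from a single token."""
    return _PUNCT_RE.sub("", token.lower()).strip("'-_")


def tokenize(text: str) -> list[str]:
    """Whitespace tokenization after lowercasing and punctuation stripping.

    The word-response format is a comma/space separated word list, so this
    rule recovers the words a respondent typed; the same rule feeds the
    diversity index so information is measured on the words the models saw.
    """
    toks = [normalize_token(t) for t in str(text).split()]
    return [t for t in toks if t]


# ---------------------------------------------------------------------------
# Embedder contract and toy backends


class EmbedderContract(ABC):
    """Minimal surface a pluggable embedding backend must provide.

    ``embed_tokens`` maps a token sequence (without boundary markers) to an
    array of shape ``(n_layers, n_tokens + 2, dim)`` — boundary markers are
    added at the start and end — plus a boolean marker mask over that token
    axis. Output must be deterministic for a fixed input.
    """

    name: str
    n_layers: int
    dim: int

    @abstractmethod
    def embed_tokens(self, tokens: list[str]) -> tuple[np.ndarray, np.ndarray]:
        """Return (vectors (n_layers, T, dim), is_marker (T,))."""

    def resolve_layer(self, layer: int) -> int:
        """Validate and normalize a (possibly negative) layer index."""
        if not -self.n_layers <= layer < self.n_layers:
            raise InvalidParameterError(
                f"layer {layer} out of range for {self.n_layers}-layer embedder {self.name!r}"
            )
        return layer % self.n_layers


def _token_entropy(*parts) -> list[int]:
    return [zlib.crc32(str(p).encode("utf-8")) for p in parts]


class HashEmbedder(EmbedderContract):
    """Deterministic toy embedder: token vectors drawn from a hash seed.

    Each (token, layer) pair gets a fixed standard-normal vector. With
    ``context_strength > 0`` a second term keyed on (previous token, token)
    is added, making the vector of a token depend on its left neighbour —
    a minimal stand-in for contextual sensitivity. The first real token has
    the start marker as its left neighbour, exactly as a transformer would
    see it, so single-token responses embed identically with and without
    context.
    """

    def __init__(
        self,
        dim: int = 32,
        n_layers: int = 4,
        context_strength: float = 0.0,
        seed: int = 0,
        name: str | None = None,
    ) -> None:
        if dim < 1 or n_layers < 1:
            raise InvalidParameterError("dim and n_layers must be >= 1")
        self.dim = int(dim)
        self.n_layers = int(n_layers)
        self.context_strength = float(context_strength)
        self.seed = int(seed)
        kind = "context" if context_strength else "static"
        self.name = name or f"hash-{kind}-d{dim}"
        self._cache: dict[tuple, np.ndarray] = {}

    def _cached(self, key: tuple) -> np.ndarray:
        vec = self._cache.get(key)
        if vec is None:
            rng = np.random.default_rng(_token_entropy(*key, self.seed))
            vec = self._cache[key] = rng.standard_normal(self.dim)
        return vec

    def _token_vec(self, token: str, layer: int) -> np.ndarray:
        return self._cached(("tok", layer, token))

    def _context_vec(self, prev: str, token: str, layer: int) -> np.ndarray:
        return self._cached(("ctx", layer, prev, token))

    def embed_tokens(self, tokens: list[str]) -> tuple[np.ndarray, np.ndarray]:
        if len(tokens) == 0:
            raise InvalidInputError("cannot embed an empty token sequence")
        seq = [BOUNDARY_TOKENS[0], *tokens, BOUNDARY_TOKENS[1]]
        out = np.empty((self.n_layers, len(seq), self.dim))
        for layer in range(self.n_layers):
            for t, tok in enumerate(seq):
                vec = self._token_vec(tok, layer)
                if self.context_strength and t > 0:
                    vec = vec + self.context_strength * self._context_vec(
                        seq[t - 1], tok, layer
                    )
                out[layer, t] = vec
        is_marker = np.zeros(len(seq), dtype=bool)
        is_marker[[0, -1]] = True
        return out, is_marker


# ---------------------------------------------------------------------------
# Pooling and extraction


def aggregate_tokens(token_vectors) -> np.ndarray:
    """Pool per-token vectors into one response vector: the arithmetic mean."""
    vecs = [np.asarray(v, dtype=float) for v in token_vectors]
    if len(vecs) == 0:
        raise InvalidInputError("cannot pool an empty list of token vectors")
    dims = {v.shape for v in vecs}
    if len(dims) != 1:
        raise InvalidInputError(f"token vectors have mixed shapes: {sorted(dims)}")
    return np.mean(vecs, axis=0)


def _single_block(responses: ResponseSet) -> ResponseSet:
    groups = responses.frame[["construct", "format"]].drop_duplicates()
    if len(groups) > 1:
        raise InvalidInputError(
            "response set mixes (construct, format) blocks; use .select() first"
        )
    return responses


def _pool_response(
    vectors: np.ndarray, is_marker: np.ndarray, include_markers: bool
) -> np.ndarray:
    keep = np.ones(len(is_marker), dtype=bool) if include_markers else ~is_marker
    return aggregate_tokens(list(vectors[keep]))


def embed_contextualized(
    responses: ResponseSet,
    embedder: EmbedderContract,
    layer: int = -2,
    include_markers: bool = False,
) -> EmbeddingMatrix:
    """One pooled vector per response, tokens embedded in full context.

    Each response's whole token sequence passes through the embedder once;
    the selected layer's real-word token vectors (boundary markers excluded
    unless ``include_markers``) are mean-pooled to one row.
    """
    block = _single_block(responses)
    layer_ix = embedder.resolve_layer(layer)
    rows, ids = [], []
    for pid, _, _, text in block.iter_records():
        tokens = tokenize(text)
        if not tokens:
            raise InvalidInputError(f"participant {pid!r}: empty response, nothing to embed")
        vectors, is_marker = embedder.embed_tokens(tokens)
        rows.append(_pool_response(vectors[layer_ix], is_marker, include_markers))
        ids.append(pid)
    return EmbeddingMatrix(
        values=np.vstack(rows),
        row_ids=tuple(ids),
        mode="contextual",
        layer=layer_ix,
        source=embedder.name,
    )


def embed_decontextualized(
    responses: ResponseSet,
    embedder: EmbedderContract,
    layer: int = -2,
    include_markers: bool = False,
) -> EmbeddingMatrix:
    """One pooled vector per response, each word embedded in isolation.

    Every word is passed to the embedder as its own one-word document
    (the "1 word/document" regime), so no vector can depend on word order;
    word vectors are then mean-pooled per response.
    """
    block = _single_block(responses)
    layer_ix = embedder.resolve_layer(layer)
    rows, ids = [], []
    for pid, _, _, text in block.iter_records():
        tokens = tokenize(text)
        if not tokens:
            raise InvalidInputError(f"participant {pid!r}: empty response, nothing to embed")
        word_vecs = []
        for tok in tokens:
            vectors, is_marker = embedder.embed_tokens([tok])
            word_vecs.append(_pool_response(vectors[layer_ix], is_marker, include_markers))
        rows.append(aggregate_tokens(word_vecs))
        ids.append(pid)
    return EmbeddingMatrix(
        values=np.vstack(rows),
        row_ids=tuple(ids),
        mode="decontextual",
        layer=layer_ix,
        source=embedder.name,
    )


def combine_feature_sets(matrices) -> EmbeddingMatrix:
    """Column-wise concatenation of feature sets over identical participants.

    This is how the combined ("All") models are built: response-specific
    pooled vectors are kept side by side rather than averaged, so the model
    can exploit information specific to each question and format.
    """
    matrices = list(matrices)
    if not matrices:
        raise InvalidInputError("no feature sets to combine")
    if len(matrices) == 1:
        return matrices[0]
    ref = matrices[0]
    for m in matrices[1:]:
        if m.row_ids != ref.row_ids:
            bad = [a for a, b in zip(m.row_ids, ref.row_ids) if a != b][:5]
            extra = set(m.row_ids) ^ set(ref.row_ids)
            detail = bad or sorted(extra)[:5]
            raise AlignmentError(f"feature sets disagree on participants, e.g. {detail}")
    modes = {m.mode for m in matrices}
    layers = {m.layer for m in matrices}
    return EmbeddingMatrix(
        values=np.hstack([m.values for m in matrices]),
        row_ids=ref.row_ids,
        mode=modes.pop() if len(modes) == 1 else "mixed",
        layer=layers.pop() if len(layers) == 1 else None,
        source="+".join(m.source for m in matrices),
    )
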