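"""Text preprocessing and sentence embeddings behind a pluggable embedder contract.

The pipeline's default embedder is a deterministic, dependency-free reference
embedder: each token is mapped to a signed feature-hashed count vector of its
character 3-grams, and a text embedding is the L2-normalized mean of its token
vectors (mean pooling).  The contract — fixed dimension, finite values, mean
pooling, zero vector for empty input — is shared by the optional
sentence-transformer plugin ("minilm", all-MiniLM-L6-v2, d=384), which is only
used when explicitly configured and installed; every test runs against the
reference embedder.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .errors import ConfigurationError

#: Token cap applied during preprocessing ("padding" length of the contract).
TOKEN_CAP = 128

#: Default dimension of the reference embedder.
REFERENCE_DIM = 256

_TOKEN_PUNCT_RE = re.compile(r"[^\w\s]|_", re.UNICODE)


def load_stopwords(path: str | Path | None = None) -> frozenset[str]:
    """Load a stop-word list (one word per line, ``#`` comments); packaged default."""
    if path is None:
        source = resources.files("phqscreen.data").joinpath("stopwords.txt")
        text = source.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    words = set()
    for line in text.splitlines():
        line = line.strip().lower()
        if line and not line.startswith("#"):
            words.add(line)
    return frozenset(words)


@dataclass(frozen=True)
class TokenSequence:
    """Lowercased content tokens, capped at ``truncated_to`` tokens."""

    tokens: tuple[str, ...]
    truncated_to: int | None = TOKEN_CAP

    def __len__(self) -> int:
        return len(self.tokens)


def preprocess(
    text: str,
    stopwords: frozenset[str] | set[str] | None = None,
    cap: int | None = TOKEN_CAP,
) -> TokenSequence:
    """Lowercase, strip punctuation, split on whitespace, drop stop words, truncate.

    ``cap=None`` disables truncation (used by the context-relevance metric,
    which needs the full content-token set).
    """
    if stopwords is None:
        stopwords = _default_stopwords()
    tokens = _TOKEN_PUNCT_RE.sub(" ", text.lower()).split()
    tokens = [t for t in tokens if t not in stopwords]
    if cap is not None:
        tokens = tokens[:cap]
    return TokenSequence(tuple(tokens), truncated_to=cap)


_STOPWORDS_CACHE: frozenset[str] | None = None


def _default_stopwords() -> frozenset[str]:
    global _STOPWORDS_CACHE
    if _STOPWORDS_CACHE is None:
        _STOPWORDS_CACHE = load_stopwords()
    return _STOPWORDS_CACHE


def _stable_hash(data: bytes, salt: bytes) -> int:
    return int.from_bytes(
        hashlib.blake2b(data, digest_size=8, key=salt).digest(), "little"
    )


def reference_token_vector(token: str, dim: int = REFERENCE_DIM) -> np.ndarray:
    """Deterministic signed character-3-gram hash vector for one token.

    The token is framed as ``^token$``; each 3-gram is hashed to a bucket in
    ``[0, dim)`` with a sign from a second hash; the count vector is then
    L2-normalized.  Identical across runs and platforms.
    """
    if dim < 16:
        raise ConfigurationError(f"embedding dim must be >= 16, got {dim}")
    framed = f"^{token}$"
    vec = np.zeros(dim, dtype=np.float64)
    for i in range(len(framed) - 2):
        gram = framed[i : i + 3].encode("utf-8")
        bucket = _stable_hash(gram, b"bucket") % dim
        sign = 1.0 if _stable_hash(gram, b"sign") % 2 == 0 else -1.0
        vec[bucket] += sign
    norm = np.linalg.norm(vec)
    if norm > 0:
        vec /= norm
    return vec


class ReferenceEmbedder:
    """Deterministic feature-hashing embedder satisfying the embedder contract."""

    name = "reference"
    deterministic = True

    def __init__(self, dim: int = REFERENCE_DIM):
        if dim < 16:
            raise ConfigurationError(f"embedding dim must be >= 16, got {dim}")
        self.dim = dim
        self._cache: dict[str, np.ndarray] = {}

    def token_vector(self, token: str) -> np.ndarray:
        vec = self._cache.get(token)
        if vec is None:
            vec = reference_token_vector(token, self.dim)
            self._cache[token] = vec
        return vec

    def embed_tokens(self, tokens: tuple[str, ...]) -> np.ndarray:
        if not tokens:
            return np.zeros(self.dim, dtype=np.float64)
        mat = np.stack([self.token_vector(t) for t in tokens])
        pooled = mat.mean(axis=0)
        norm = np.linalg.norm(pooled)
        if norm > 0:
            pooled = pooled / norm
        return pooled


class MiniLMEmbedder:
    """Optional sentence-transformer plugin (all-MiniLM-L6-v2, d=384)."""

    name = "minilm"
    deterministic = True
    dim = 384

    def __init__(self) -> None:
        try:
            from sentence_transformers import SentenceTransformer
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ConfigurationError(
                "embedder 'minilm' requires the sentence-transformers package; "
                "install the [minilm] extra or use the 'reference' embedder"
            ) from exc
        self._model = SentenceTransformer("sentence-transformers/all-MiniLM-L6-v2")

    def embed_tokens(self, tokens: tuple[str, ...]) -> np.ndarray:  # pragma: no cover
        if not tokens:
            return np.zeros(self.dim, dtype=np.float64)
        vec = self._model.encode(" ".join(tokens), normalize_embeddings=True)
        return np.asarray(vec, dtype=np.float64)


def get_embedder(name: str = "reference", dim: int | None = None):
    """Look up an embedder by config name (``reference`` | ``minilm``)."""
    if name == "reference":
        return ReferenceEmbedder(dim or REFERENCE_DIM)
    if name == "minilm":
        if dim not in (None, 384):
            raise ConfigurationError("minilm embedder has fixed dim 384")
        return MiniLMEmbedder()
    raise ConfigurationError(f"unknown embedder {name!r}")


def embed(seq: TokenSequence, embedder) -> np.ndarray:
    """Mean-pooled, L2-normalized embedding of a token sequence.

    The empty sequence maps to the zero vector; cosine against it is defined
    as 0 downstream.
    """
    vec = embedder.embed_tokens(seq.tokens)
    if vec.shape != (embedder.dim,):
        raise ConfigurationError(
            f"embedder {embedder.name!r} returned shape {vec.shape}, expected ({embedder.dim},)"
        )
    if not np.all(np.isfinite(vec)):
        raise ConfigurationError(f"embedder {embedder.name!r} produced non-finite values")
    return vec


def embed_text(text: str, embedder, stopwords=None) -> np.ndarray:
    """Convenience: preprocess then embed."""
    return embed(preprocess(text, stopwords), embedder)
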