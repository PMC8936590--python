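"""Per-token input features: word vector, case one-hot, terminology index.

The per-token vector is the concatenation [v_w, v_c, v_t] where v_w is a
word embedding (default 25 dimensions), v_c a 7-dimensional one-hot case
feature and v_t a single raw integer indexing the token's gazetteer BIO
label (0 when unmatched).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .bootstrap import DictionarySet, MatchedTerm, match_terms
from .schema import ELEMENT_TAG_INDEX, SchemaError, Token

CASE_CLASSES = (
    "numeric",
    "allLower",
    "allUpper",
    "initialUpper",
    "mainly_numeric",
    "contains_digit",
    "other",
)
CASE_DIM = len(CASE_CLASSES)  # listed as six in prose but seven values exist


@dataclass(frozen=True)
class FeatureConfig:
    embed_dim: int = 25
    oov_policy: str = "seeded-random"  # or "zero"

    @property
    def total_dim(self) -> int:
        return self.embed_dim + CASE_DIM + 1


def case_class(text: str) -> str:
    """Classify a token's letter case; first matching predicate wins."""
    if not text:
        raise SchemaError("empty token has no case feature")
    digits = sum(c.isdigit() for c in text)
    if digits == len(text):
        return "numeric"
    if text.islower():
        return "allLower"
    if text.isupper():
        return "allUpper"
    if text[0].isupper() and (len(text) == 1 or text[1:].islower()):
        return "initialUpper"
    if digits > len(text) / 2:
        return "mainly_numeric"
    if digits > 0:
        return "contains_digit"
    return "other"


def case_feature(text: str) -> np.ndarray:
    vec = np.zeros(CASE_DIM)
    vec[CASE_CLASSES.index(case_class(text))] = 1.0
    return vec


def dict_feature(
    tokens: Sequence[Token], matches: Sequence[MatchedTerm]
) -> np.ndarray:
    """Per-token index of the gazetteer BIO label; 0 (= "O") when unmatched."""
    labels = ["O"] * len(tokens)
    for m in matches:
        labels[m.span.start - 1] = f"B-{m.span.label}"
        for i in range(m.span.start, m.span.end):
            labels[i] = f"I-{m.span.label}"
    return np.array([ELEMENT_TAG_INDEX[l] for l in labels], dtype=float)


class EmbeddingTable:
    """Word-vector lookup, either loaded from a text file or seed-derived.

    Lookup is lowercased; case information is carried by the case feature.
    The seeded table derives a stable vector per word from a CRC of the
    word and the table seed, so no stored file is needed.
    """

    def __init__(self, dim: int, vectors: dict[str, np.ndarray] | None = None,
                 seed: int | None = None):
        self.dim = dim
        self.vectors = vectors or {}
        self.seed = seed

    @classmethod
    def load_text(cls, path) -> "EmbeddingTable":
        """Read a word2vec/GloVe-style text table: "word f1 ... fD" lines."""
        vectors: dict[str, np.ndarray] = {}
        dim = None
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                parts = line.rstrip().split()
                if len(parts) == 2 and dim is None and not _is_float(parts[1]):
                    continue  # word2vec header line
                if len(parts) < 2:
                    continue
                word, values = parts[0], np.array([float(x) for x in parts[1:]])
                if dim is None:
                    dim = values.size
                elif values.size != dim:
                    raise SchemaError(
                        f"embedding dimension mismatch for {word!r}: "
                        f"{values.size} != {dim}"
                    )
                vectors[word.lower()] = values
        if dim is None:
            raise SchemaError(f"no vectors found in {path}")
        return cls(dim, vectors)

    @classmethod
    def seeded(cls, dim: int, seed: int) -> "EmbeddingTable":
        return cls(dim, {}, seed=seed)

    def _seeded_vector(self, word: str) -> np.ndarray:
        key = zlib.crc32(word.encode("utf-8")) ^ (self.seed or 0)
        rng = np.random.default_rng(key & 0xFFFFFFFF)
        return rng.normal(scale=0.3, size=self.dim)

    def lookup(self, word: str, oov_policy: str = "seeded-random") -> np.ndarray:
        word = word.lower()
        if word in self.vectors:
            return self.vectors[word]
        if self.seed is not None:
            return self._seeded_vector(word)
        if oov_policy == "zero":
            return np.zeros(self.dim)
        if oov_policy == "seeded-random":
            key = zlib.crc32(word.encode("utf-8"))
            return np.random.default_rng(key).normal(scale=0.3, size=self.dim)
        raise SchemaError(f"unknown OOV policy {oov_policy!r}")


def _is_float(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def featurize_sentence(
    tokens: Sequence[Token],
    embeddings: EmbeddingTable,
    dicts: DictionarySet,
    config: FeatureConfig = FeatureConfig(),
) -> np.ndarray:
    """Build the (n, embed_dim + 8) feature matrix for one sentence."""
    if embeddings.dim != config.embed_dim:
        raise SchemaError(
            f"embedding table dimension {embeddings.dim} does not match "
            f"configured {config.embed_dim}"
        )
    matches = match_terms(tokens, dicts)
    v_t = dict_feature(tokens, matches)
    out = np.empty((len(tokens), config.total_dim))
    for i, tok in enumerate(tokens):
        out[i, : config.embed_dim] = embeddings.lookup(tok.text, config.oov_policy)
        out[i, config.embed_dim : config.embed_dim + CASE_DIM] = case_feature(tok.text)
        out[i, -1] = v_t[i]
    return out
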