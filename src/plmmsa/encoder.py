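"""Sequence encoders and embedding pooling.

Every downstream stage of the pipeline consumes :class:`ResidueEmbedding`
matrices — one row of dimension ``D`` per residue — produced by *some*
encoder.  In production that encoder is a protein language model; here the
encoder contract is any callable ``encode(sequence, sequence_id) ->
ResidueEmbedding`` with a ``spec`` attribute, and the bundled
:class:`ToyEncoder` (seeded k-mer feature hashing) satisfies it
deterministically with no trained weights.

Pooling turns a residue matrix into one fixed-length vector per sequence,
which is what the vector index stores and searches.  For encoders with a
bounded input window, :func:`chunked_pool` splits the sequence into
consecutive chunks, encodes each, and combines chunk means weighted by chunk
length, so the result equals the mean over all encoded residues.
"""

from __future__ import annotations

from dataclasses import dataclass
from hashlib import blake2b
from typing import Callable, Optional

import numpy as np

from .errors import InvalidAlphabetError, InvalidInputError

AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: Accepted residue alphabet: the 20 canonical amino acids plus the unknown
#: residue 'X', which is hashed like any other letter.
ALPHABET = frozenset(AA20 + "X")


@dataclass(frozen=True)
class EncoderSpec:
    """Static description of an encoder.

    Parameters
    ----------
    name:
        Identifier used for routing and index naming.
    dim:
        Embedding dimension ``D``.
    max_len:
        Longest sequence the encoder can embed in one pass (``None`` =
        unbounded).  Longer sequences are handled by chunked pooling.
    db_max_len:
        Longest sequence admitted into this encoder's database at build
        time (``None`` = unbounded).
    """

    name: str
    dim: int
    max_len: Optional[int] = None
    db_max_len: Optional[int] = None

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise InvalidInputError(f"dim must be >= 1, got {self.dim}")
        if self.max_len is not None and self.max_len < 1:
            raise InvalidInputError(f"max_len must be >= 1, got {self.max_len}")
        if self.db_max_len is not None and self.db_max_len < 1:
            raise InvalidInputError(f"db_max_len must be >= 1, got {self.db_max_len}")


@dataclass
class ResidueEmbedding:
    """Per-residue embedding matrix ``[L, D]`` for one sequence."""

    sequence_id: str
    residues: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if len(self.residues) < 1:
            raise InvalidInputError("residues must be non-empty")
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.residues):
            raise InvalidInputError(
                f"matrix shape {self.matrix.shape} does not match "
                f"sequence length {len(self.residues)}"
            )
        if self.matrix.shape[1] < 1:
            raise InvalidInputError("embedding dimension must be >= 1")
        if not np.all(np.isfinite(self.matrix)):
            raise InvalidInputError("embedding matrix contains non-finite entries")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]


@dataclass
class PooledVector:
    """Average-pooled whole-sequence embedding ``[D]``."""

    sequence_id: str
    vector: np.ndarray

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=np.float64)
        if self.vector.ndim != 1 or self.vector.size < 1:
            raise InvalidInputError("pooled vector must be 1-D and non-empty")
        if not np.all(np.isfinite(self.vector)):
            raise InvalidInputError("pooled vector contains non-finite entries")

    @property
    def dim(self) -> int:
        return self.vector.size


def _validate_sequence(sequence: str) -> None:
    if not sequence:
        raise InvalidInputError("sequence must be non-empty")
    bad = set(sequence) - ALPHABET
    if bad:
        raise InvalidAlphabetError(
            f"illegal residue character(s) {sorted(bad)!r}; "
            f"accepted alphabet is the 20 amino acids plus 'X'"
        )


def _kmer_feature(kmer: str, dim: int, seed: int) -> tuple[int, int, float, float]:
    """Hash a k-mer into two (bucket, sign) features.

    Two features per k-mer keep the chance of a row cancelling to zero
    negligible.  blake2b keyed by the seed makes the mapping stable across
    processes and runs.
    """
    digest = blake2b(
        kmer.encode("ascii"),
        key=int(seed).to_bytes(8, "little", signed=False),
        digest_size=16,
    ).digest()
    v1 = int.from_bytes(digest[:8], "little")
    v2 = int.from_bytes(digest[8:], "little")
    b1, b2 = v1 % dim, v2 % dim
    s1 = 1.0 if (v1 >> 62) & 1 else -1.0
    s2 = 1.0 if (v2 >> 62) & 1 else -1.0
    return b1, b2, s1, s2


def encode_toy(
    sequence: str,
    dim: int = 64,
    k: int = 3,
    seed: int = 0,
    sequence_id: str = "query",
) -> ResidueEmbedding:
    """Deterministic k-mer feature-hashing encoder.

    Row ``i`` is the L2-normalised sum of seeded hash features of every
    k-mer window covering position ``i``.  Identical sequences give
    bit-identical matrices; point mutations perturb only the rows whose
    covering windows changed, so homologs stay close in embedding space.

    For sequences shorter than ``k`` the whole sequence is used as the
    single covering window.
    """
    _validate_sequence(sequence)
    if k < 1:
        raise InvalidInputError(f"k must be >= 1, got {k}")
    L = len(sequence)
    keff = min(k, L)
    n_windows = L - keff + 1
    # one hashed feature pair per window, computed once
    feats = np.zeros((n_windows, dim), dtype=np.float64)
    cache: dict[str, tuple[int, int, float, float]] = {}
    for w in range(n_windows):
        kmer = sequence[w : w + keff]
        f = cache.get(kmer)
        if f is None:
            f = _kmer_feature(kmer, dim, seed)
            cache[kmer] = f
        b1, b2, s1, s2 = f
        feats[w, b1] += s1
        feats[w, b2] += s2
    matrix = np.zeros((L, dim), dtype=np.float64)
    for i in range(L):
        lo = max(0, i - keff + 1)
        hi = min(i, n_windows - 1)
        row = feats[lo : hi + 1].sum(axis=0)
        nrm = np.linalg.norm(row)
        if nrm < 1e-12:  # all features cancelled; deterministic fallback
            b1, _, _, _ = _kmer_feature(sequence[lo : lo + keff], dim, seed)
            row = np.zeros(dim)
            row[b1] = 1.0
            nrm = 1.0
        matrix[i] = row / nrm
    return ResidueEmbedding(sequence_id=sequence_id, residues=sequence, matrix=matrix)


class ToyEncoder:
    """Callable wrapper for :func:`encode_toy` satisfying the encoder contract."""

    def __init__(
        self,
        name: str = "toy",
        dim: int = 64,
        k: int = 3,
        seed: int = 0,
        max_len: Optional[int] = None,
        db_max_len: Optional[int] = None,
    ) -> None:
        self.spec = EncoderSpec(name=name, dim=dim, max_len=max_len, db_max_len=db_max_len)
        self.k = k
        self.seed = seed

    def encode(self, sequence: str, sequence_id: str = "query") -> ResidueEmbedding:
        if self.spec.max_len is not None and len(sequence) > self.spec.max_len:
            raise InvalidInputError(
                f"sequence length {len(sequence)} exceeds encoder window "
                f"{self.spec.max_len}; use chunked_pool"
            )
        return encode_toy(
            sequence, dim=self.spec.dim, k=self.k, seed=self.seed, sequence_id=sequence_id
        )

    __call__ = encode


def average_pool(emb: ResidueEmbedding) -> PooledVector:
    """Column-wise mean of the residue matrix."""
    return PooledVector(sequence_id=emb.sequence_id, vector=emb.matrix.mean(axis=0))


def chunked_pool(
    sequence: str,
    encoder: Callable[..., ResidueEmbedding],
    sequence_id: str = "query",
    max_len: Optional[int] = None,
) -> PooledVector:
    """Pool a sequence through a length-limited encoder.

    The sequence is split into consecutive non-overlapping chunks of at most
    ``max_len`` residues (taken from the encoder spec when not given); each
    chunk is encoded and average-pooled, and the chunk pools are combined
    weighted by chunk length.  By construction the result equals the mean
    over all encoded residue rows.
    """
    _validate_sequence(sequence)
    if max_len is None:
        spec = getattr(encoder, "spec", None)
        max_len = spec.max_len if spec is not None else None
    L = len(sequence)
    if max_len is None or L <= max_len:
        return average_pool(encoder(sequence, sequence_id=sequence_id))
    total = None
    for start in range(0, L, max_len):
        chunk = sequence[start : start + max_len]
        pooled = average_pool(encoder(chunk, sequence_id=sequence_id))
        contrib = pooled.vector * len(chunk)
        total = contrib if total is None else total + contrib
    return PooledVector(sequence_id=sequence_id, vector=total / L)
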