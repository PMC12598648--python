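"""Inverted-file nearest-neighbour index with 8-bit scalar quantization.

Pooled sequence embeddings are L2-normalised, clustered into ``nlist``
coarse centroids (k-means), and each vector is stored in its nearest
centroid's list as one byte per dimension (SQ8: per-dimension min/max
scaling over the build set).  A search probes the ``nprobe`` centroids
nearest to the query by cosine and ranks the dequantized candidates by
cosine to the query, ties broken by ascending id.

:func:`brute_force_search` is the exact reference: with ``nprobe = nlist``
the IVF search returns exactly the brute-force ranking over the dequantized
vectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import h5py
import numpy as np
from sklearn.cluster import KMeans

from .encoder import PooledVector
from .errors import InvalidInputError


def nlist_heuristic(n: int, c: float = 5.0) -> int:
    """Number of coarse centroids for a database of ``n`` vectors.

    ``round(c * sqrt(n))`` rounded to two significant figures — the scaling
    that yields ~40,000 centroids for a 63-million-entry database at c = 5.
    """
    if n < 1:
        raise InvalidInputError(f"database size must be >= 1, got {n}")
    if not c > 0:
        raise InvalidInputError(f"scaling factor must be positive, got {c}")
    v = c * math.sqrt(n)
    if v < 10:
        return max(1, round(v))
    mag = 10 ** (math.floor(math.log10(v)) - 1)
    return int(round(v / mag) * mag)


def sq8_quantize(v: np.ndarray, per_dim_min: np.ndarray, per_dim_max: np.ndarray) -> np.ndarray:
    """Quantize a vector to one byte per dimension over the given ranges.

    ``code_d = round(255 * (v_d - min_d) / (max_d - min_d))`` clamped to
    [0, 255]; a degenerate dimension (max = min) always encodes to 0.
    """
    v = np.asarray(v, dtype=np.float64)
    lo = np.asarray(per_dim_min, dtype=np.float64)
    hi = np.asarray(per_dim_max, dtype=np.float64)
    if np.any(hi < lo):
        raise InvalidInputError("per_dim_max must be >= per_dim_min elementwise")
    rng = hi - lo
    safe = np.where(rng > 0, rng, 1.0)
    codes = np.rint(255.0 * (v - lo) / safe)
    codes = np.where(rng > 0, np.clip(codes, 0, 255), 0.0)
    return codes.astype(np.uint8)


def sq8_dequantize(
    codes: np.ndarray, per_dim_min: np.ndarray, per_dim_max: np.ndarray
) -> np.ndarray:
    """Inverse of :func:`sq8_quantize`; exact on lattice points."""
    lo = np.asarray(per_dim_min, dtype=np.float64)
    hi = np.asarray(per_dim_max, dtype=np.float64)
    return lo + np.asarray(codes, dtype=np.float64) * (hi - lo) / 255.0


@dataclass(frozen=True)
class SearchParams:
    """``top_k`` results; ``nprobe`` clusters examined (default nlist/16)."""

    top_k: int = 1000
    nprobe: Optional[int] = None

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise InvalidInputError(f"top_k must be >= 1, got {self.top_k}")
        if self.nprobe is not None and self.nprobe < 1:
            raise InvalidInputError(f"nprobe must be >= 1, got {self.nprobe}")


def _cosine_scores(mat: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Cosine of every row of ``mat`` against ``q`` (shared code path so the
    IVF search and the brute-force reference agree bitwise)."""
    qn = np.linalg.norm(q)
    norms = np.linalg.norm(mat, axis=1)
    norms = np.where(norms > 0, norms, 1.0)
    return (mat @ q) / (norms * (qn if qn > 0 else 1.0))


def _rank(ids: Sequence[str], scores: np.ndarray, top_k: int) -> List[Tuple[str, float]]:
    order = sorted(range(len(ids)), key=lambda i: (-scores[i], ids[i]))
    return [(ids[i], float(scores[i])) for i in order[:top_k]]


@dataclass
class IvfSq8Index:
    """IVF index over SQ8-quantized, L2-normalised pooled vectors."""

    centroids: np.ndarray  # [K, D]
    per_dim_min: np.ndarray  # [D]
    per_dim_max: np.ndarray  # [D]
    list_ids: List[List[str]] = field(default_factory=list)  # per-centroid ids
    list_codes: List[np.ndarray] = field(default_factory=list)  # per-centroid uint8 [n, D]

    @property
    def nlist(self) -> int:
        return self.centroids.shape[0]

    @property
    def dim(self) -> int:
        return self.centroids.shape[1]

    @property
    def size(self) -> int:
        return sum(len(ids) for ids in self.list_ids)

    @classmethod
    def build(
        cls, vectors: Sequence[PooledVector], nlist: int, seed: int = 0
    ) -> "IvfSq8Index":
        """Cluster the build set and store every vector quantized in exactly
        one inverted list.  Deterministic for a fixed seed."""
        if nlist < 1:
            raise InvalidInputError(f"nlist must be >= 1, got {nlist}")
        if len(vectors) < nlist:
            raise InvalidInputError(
                f"need at least nlist={nlist} vectors, got {len(vectors)}"
            )
        ids = [v.sequence_id for v in vectors]
        if len(set(ids)) != len(ids):
            raise InvalidInputError("duplicate sequence ids in build set")
        X = np.stack([v.vector for v in vectors]).astype(np.float64)
        norms = np.linalg.norm(X, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise InvalidInputError("zero vector in build set")
        X = X / norms
        km = KMeans(
            n_clusters=nlist, init="k-means++", n_init=1, max_iter=25, random_state=seed
        ).fit(X)
        lo = X.min(axis=0)
        hi = X.max(axis=0)
        index = cls(
            centroids=km.cluster_centers_.astype(np.float64),
            per_dim_min=lo,
            per_dim_max=hi,
            list_ids=[[] for _ in range(nlist)],
            list_codes=[[] for _ in range(nlist)],
        )
        # deterministic list order: ascending id within each list
        order = sorted(range(len(ids)), key=lambda i: ids[i])
        buckets: List[List[int]] = [[] for _ in range(nlist)]
        for i in order:
            buckets[km.labels_[i]].append(i)
        for c in range(nlist):
            index.list_ids[c] = [ids[i] for i in buckets[c]]
            codes = [sq8_quantize(X[i], lo, hi) for i in buckets[c]]
            index.list_codes[c] = (
                np.stack(codes) if codes else np.empty((0, X.shape[1]), dtype=np.uint8)
            )
        return index

    def dequantized_vectors(self) -> List[PooledVector]:
        """Every stored vector after the quantization round trip."""
        out = []
        for ids, codes in zip(self.list_ids, self.list_codes):
            for i, sid in enumerate(ids):
                out.append(
                    PooledVector(
                        sequence_id=sid,
                        vector=sq8_dequantize(codes[i], self.per_dim_min, self.per_dim_max),
                    )
                )
        return out

    def search(
        self, query: PooledVector, params: SearchParams = SearchParams()
    ) -> List[Tuple[str, float]]:
        """Probe the nearest clusters and rank dequantized candidates by
        cosine to the query; ties broken by ascending id."""
        q = np.asarray(query.vector, dtype=np.float64)
        if q.size != self.dim:
            raise InvalidInputError(
                f"query dimension {q.size} does not match index dimension {self.dim}"
            )
        nprobe = params.nprobe if params.nprobe is not None else max(1, self.nlist // 16)
        nprobe = min(nprobe, self.nlist)
        cscore = _cosine_scores(self.centroids, q)
        probe = sorted(range(self.nlist), key=lambda c: (-cscore[c], c))[:nprobe]
        cand_ids: List[str] = []
        cand_codes: List[np.ndarray] = []
        for c in probe:
            cand_ids.extend(self.list_ids[c])
            if len(self.list_ids[c]):
                cand_codes.append(self.list_codes[c])
        if not cand_ids:
            return []
        mat = sq8_dequantize(np.concatenate(cand_codes), self.per_dim_min, self.per_dim_max)
        scores = _cosine_scores(mat, q)
        return _rank(cand_ids, scores, params.top_k)

    def save(self, path: str) -> None:
        """Persist centroids, quantizer ranges and inverted lists to HDF5."""
        with h5py.File(path, "w") as f:
            f.create_dataset("centroids", data=self.centroids)
            f.create_dataset("per_dim_min", data=self.per_dim_min)
            f.create_dataset("per_dim_max", data=self.per_dim_max)
            g = f.create_group("lists")
            for c in range(self.nlist):
                gc = g.create_group(str(c))
                gc.create_dataset(
                    "ids", data=np.array(self.list_ids[c], dtype=h5py.string_dtype())
                )
                gc.create_dataset("codes", data=self.list_codes[c], dtype=np.uint8)

    @classmethod
    def load(cls, path: str) -> "IvfSq8Index":
        with h5py.File(path, "r") as f:
            centroids = f["centroids"][...]
            lo = f["per_dim_min"][...]
            hi = f["per_dim_max"][...]
            nlist = centroids.shape[0]
            list_ids: List[List[str]] = []
            list_codes: List[np.ndarray] = []
            for c in range(nlist):
                gc = f["lists"][str(c)]
                list_ids.append([s.decode() for s in gc["ids"][...]])
                list_codes.append(gc["codes"][...].astype(np.uint8))
        return cls(centroids, lo, hi, list_ids, list_codes)


def brute_force_search(
    vectors: Sequence[PooledVector], query: PooledVector, top_k: int = 1000
) -> List[Tuple[str, float]]:
    """Exact cosine ranking over all vectors; the IVF oracle."""
    if not vectors:
        return []
    q = np.asarray(query.vector, dtype=np.float64)
    mat = np.stack([v.vector for v in vectors]).astype(np.float64)
    if mat.shape[1] != q.size:
        raise InvalidInputError("query dimension does not match database vectors")
    scores = _cosine_scores(mat, q)
    return _rank([v.sequence_id for v in vectors], scores, top_k)
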