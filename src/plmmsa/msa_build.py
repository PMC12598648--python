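"""Retrieval, alignment, filtering and A3M assembly for one query.

The single-query pipeline: pool the query embedding, search the routed
vector indexes (short queries use only the short-sequence encoder's
database), union and deduplicate the candidates, align every candidate to
the query on embedding similarity, filter by the self-alignment score, and
emit a query-anchored A3M where uppercase letters sit in query columns,
'-' marks deletions and lowercase letters are insertions.

Also provides the effective-sequence-number (Neff) diagnostic: rows are
down-weighted by the number of rows within 80 % identity over match
columns, so redundant hits do not inflate the apparent depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Mapping, Optional, Tuple

import numpy as np

from .embedding_align import (
    AlignmentResult,
    FilterParams,
    dp_align,
    filter_hits,
    similarity_matrix,
)
from .encoder import ResidueEmbedding, chunked_pool
from .errors import ConfigurationError, InvalidInputError
from .vector_index import IvfSq8Index, SearchParams


@dataclass(frozen=True)
class RetrievalParams:
    """Retrieval stage knobs.

    ``encoders`` names the configured vector databases; queries shorter
    than ``short_len`` residues search only ``short_encoder`` (the
    encoder that handles short sequences best), all others search every
    database.  ``top_k`` matches are taken from each database searched.
    ``nprobe`` limits how many clusters each search examines; ``None``
    probes every cluster, which is exact and still cheap at the database
    sizes this package targets.
    """

    top_k: int = 1000
    short_len: int = 128
    encoders: Tuple[str, ...] = ("esm", "ankh")
    short_encoder: str = "esm"
    nprobe: Optional[int] = None

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise InvalidInputError(f"top_k must be >= 1, got {self.top_k}")
        if self.short_len < 1:
            raise InvalidInputError(f"short_len must be >= 1, got {self.short_len}")


@dataclass(frozen=True)
class AlignParams:
    """Alignment mode and affine gap penalties used for MSA rows."""

    mode: str = "semiglobal"
    gap_open: float = -0.5
    gap_extend: float = -0.1


@dataclass
class MsaRowMeta:
    """Provenance of one MSA row."""

    sequence_id: str
    score: float
    taxid: Optional[str] = None


@dataclass
class Msa:
    """Query-anchored A3M-style alignment.

    Row 0 is the ungapped query; every row's uppercase + '-' count equals
    the query length (the A3M column invariant).
    """

    rows: List[str]
    meta: List[MsaRowMeta]

    def __post_init__(self) -> None:
        if len(self.rows) < 1 or len(self.rows) != len(self.meta):
            raise InvalidInputError("Msa needs >= 1 row and matching metadata")
        q = self.rows[0]
        if "-" in q or q != q.upper():
            raise InvalidInputError("query row must be ungapped uppercase")
        L = len(q)
        for r, row in enumerate(self.rows):
            cols = sum(1 for ch in row if ch == "-" or ch.isupper())
            if cols != L:
                raise InvalidInputError(
                    f"row {r} has {cols} match columns, expected {L}"
                )

    @property
    def query_row(self) -> str:
        return self.rows[0]

    @property
    def depth(self) -> int:
        return len(self.rows)

    def match_rows(self) -> List[str]:
        """Rows with insertions (lowercase) removed; all same length."""
        return ["".join(ch for ch in row if ch == "-" or ch.isupper()) for row in self.rows]


def route_encoders(query_len: int, params: RetrievalParams) -> List[str]:
    """Databases to search for a query of the given length."""
    if query_len < 1:
        raise InvalidInputError(f"query_len must be >= 1, got {query_len}")
    if not params.encoders:
        raise ConfigurationError("no vector databases configured")
    if query_len < params.short_len:
        routed = [n for n in params.encoders if n == params.short_encoder]
        if not routed:
            raise ConfigurationError(
                f"short-sequence database {params.short_encoder!r} not configured"
            )
        return routed
    return list(params.encoders)


def alignment_to_a3m_row(
    aln: AlignmentResult, query_len: int, target_residues: str
) -> str:
    """Render an alignment as one A3M row.

    Matched query positions carry the uppercase target residue; unmatched
    query positions carry '-'; target residues falling between consecutive
    matched pairs become lowercase insertions placed after the left match.
    Target residues outside the aligned span are trimmed.
    """
    for q, t in aln.pairs:
        if not (0 <= q < query_len and 0 <= t < len(target_residues)):
            raise InvalidInputError(f"pair ({q}, {t}) out of bounds")
    out: List[str] = []
    prev_q, prev_t = -1, None
    for q, t in aln.pairs:
        if prev_t is not None:
            out.append(target_residues[prev_t + 1 : t].lower())
        out.append("-" * (q - prev_q - 1))
        out.append(target_residues[t].upper())
        prev_q, prev_t = q, t
    out.append("-" * (query_len - 1 - prev_q))
    return "".join(out)


def neff(msa: Msa, identity_threshold: float = 0.8) -> float:
    """Effective number of sequences under identity down-weighting.

    Over match columns only, row ``i`` gets weight ``1 / |{j : id(i, j) >=
    threshold}|`` (self included; '-' counts as an ordinary symbol), and
    Neff is the sum of weights.  Identical rows share one unit of weight;
    rows with no neighbour above the threshold count fully.
    """
    if not 0.0 <= identity_threshold <= 1.0:
        raise InvalidInputError("identity_threshold must be in [0, 1]")
    rows = msa.match_rows()
    n = len(rows)
    arr = np.frombuffer("".join(rows).encode("ascii"), dtype=np.uint8).reshape(n, -1)
    L = arr.shape[1]
    counts = np.zeros(n, dtype=np.int64)
    for i in range(n):
        ident = (arr == arr[i]).sum(axis=1) / L
        counts[i] = int((ident >= identity_threshold).sum())
    return float((1.0 / counts).sum())


def build_msa(
    query_id: str,
    query_seq: str,
    indexes: Mapping[str, IvfSq8Index],
    encoders: Mapping[str, Callable[..., ResidueEmbedding]],
    sequences: Mapping[str, str],
    align_encoder: Optional[Callable[..., ResidueEmbedding]] = None,
    retrieval: RetrievalParams = RetrievalParams(),
    filt: FilterParams = FilterParams(),
    align: AlignParams = AlignParams(),
    taxonomy: Optional[Mapping[str, str]] = None,
    exclude_self_hit: bool = False,
) -> Tuple[Msa, Dict]:
    """Run retrieval → alignment → filtering → A3M assembly for one query.

    Parameters
    ----------
    indexes, encoders:
        Vector databases and the encoders that produced them, keyed by the
        names in ``retrieval.encoders``.
    sequences:
        id → amino-acid string for every id retrievable from any index.
    align_encoder:
        Encoder used for the residue-level alignment stage (both query and
        targets); defaults to the encoder of the first routed database.
    taxonomy:
        Optional id → taxonomy-id mapping recorded in row metadata.
    exclude_self_hit:
        Drop a retrieved candidate whose id equals ``query_id``.

    Returns the Msa (query row first, hit rows sorted by descending
    alignment score, ties by id) and a run report with per-stage counts.
    """
    if not query_seq:
        raise InvalidInputError("query sequence must be non-empty")
    routed = route_encoders(len(query_seq), retrieval)
    for name in routed:
        if name not in indexes or name not in encoders:
            raise ConfigurationError(f"database {name!r} routed but not provided")

    # retrieval: union over routed databases, dedup keeping best score
    best_retrieval: Dict[str, float] = {}
    for name in routed:
        pooled = chunked_pool(query_seq, encoders[name], sequence_id=query_id)
        nprobe = retrieval.nprobe if retrieval.nprobe is not None else indexes[name].nlist
        hits = indexes[name].search(
            pooled, SearchParams(top_k=retrieval.top_k, nprobe=nprobe)
        )
        for hid, score in hits:
            if exclude_self_hit and hid == query_id:
                continue
            if hid not in best_retrieval or score > best_retrieval[hid]:
                best_retrieval[hid] = score
    candidates = sorted(best_retrieval, key=lambda h: (-best_retrieval[h], h))

    # alignment
    if align_encoder is None:
        align_encoder = encoders[routed[0]]
    q_emb = align_encoder(query_seq, sequence_id=query_id)
    self_score = dp_align(
        similarity_matrix(q_emb, q_emb),
        mode=align.mode,
        gap_open=align.gap_open,
        gap_extend=align.gap_extend,
    ).score
    alignments: Dict[str, AlignmentResult] = {}
    scored: List[Tuple[str, float]] = []
    for hid in candidates:
        if hid not in sequences:
            raise ConfigurationError(f"retrieved id {hid!r} missing from sequence map")
        t_emb = align_encoder(sequences[hid], sequence_id=hid)
        aln = dp_align(
            similarity_matrix(q_emb, t_emb),
            mode=align.mode,
            gap_open=align.gap_open,
            gap_extend=align.gap_extend,
        )
        alignments[hid] = aln
        scored.append((hid, aln.score))

    kept = filter_hits(scored, self_score, filt)
    kept.sort(key=lambda h: (-h[1], h[0]))

    tax = taxonomy or {}
    rows = [query_seq.upper()]
    meta = [MsaRowMeta(sequence_id=query_id, score=self_score, taxid=tax.get(query_id))]
    for hid, score in kept:
        rows.append(alignment_to_a3m_row(alignments[hid], len(query_seq), sequences[hid]))
        meta.append(MsaRowMeta(sequence_id=hid, score=score, taxid=tax.get(hid)))
    msa = Msa(rows=rows, meta=meta)

    report = {
        "query_id": query_id,
        "query_len": len(query_seq),
        "routed": routed,
        "n_retrieved": len(candidates),
        "n_aligned": len(scored),
        "n_kept": len(kept),
        "self_score": self_score,
        "neff": neff(msa),
        "params": {
            "top_k": retrieval.top_k,
            "short_len": retrieval.short_len,
            "rel_frac": filt.rel_frac,
            "abs_min": filt.abs_min,
            "mode": align.mode,
            "gap_open": align.gap_open,
            "gap_extend": align.gap_extend,
        },
    }
    return msa, report
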