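"""Embedding-based pairwise alignment and hit filtering.

Instead of a substitution matrix, alignment is driven by the per-residue
embedding similarity ``S[i, j] = cosine(q_i, t_j)``.  A three-state affine
dynamic program (match, gap-in-target, gap-in-query) maximises the summed
similarity over matched pairs plus gap penalties.  Modes:

``global``
    end-to-end alignment; terminal gaps are charged.
``semiglobal``
    free end gaps (leading/trailing unmatched residues cost nothing);
    the default for MSA construction where homologs may be partial length.
``local``
    Smith-Waterman-style best sub-path; score is never negative.

Because row-normalised embeddings bound every cell in [-1, 1], the raw
alignment score is interpretable: the absolute filter floor of 8.0 means
roughly eight confidently aligned residues, and the relative filter keeps
hits scoring at least a fixed fraction of the query's self-alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from numba import njit

from .encoder import ResidueEmbedding
from .errors import InvalidInputError

MODES = ("global", "semiglobal", "local")
_MODE_CODE = {"global": 0, "semiglobal": 1, "local": 2}

DEFAULT_GAP_OPEN = -0.5
DEFAULT_GAP_EXTEND = -0.1

_NEG = -1e30


@dataclass
class SimilarityMatrix:
    """Residue-level cosine similarity between two embeddings."""

    S: np.ndarray
    query_id: str = "query"
    target_id: str = "target"

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=np.float64)
        if self.S.ndim != 2 or min(self.S.shape) < 1:
            raise InvalidInputError(f"similarity matrix must be 2-D, got {self.S.shape}")
        if not np.all(np.isfinite(self.S)):
            raise InvalidInputError("similarity matrix contains non-finite entries")


@dataclass
class AlignmentResult:
    """Matched (query_pos, target_pos) pairs, 0-based, plus the DP score."""

    pairs: List[Tuple[int, int]]
    score: float
    mode: str

    def __post_init__(self) -> None:
        prev_q, prev_t = -1, -1
        for q, t in self.pairs:
            if q <= prev_q or t <= prev_t:
                raise InvalidInputError("alignment pairs must strictly increase")
            prev_q, prev_t = q, t


@dataclass(frozen=True)
class FilterParams:
    """Hit-filter thresholds: fraction of self score, and absolute floor."""

    rel_frac: float = 0.2
    abs_min: float = 8.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rel_frac <= 1.0:
            raise InvalidInputError(f"rel_frac must be in [0, 1], got {self.rel_frac}")
        if self.abs_min < 0:
            raise InvalidInputError(f"abs_min must be >= 0, got {self.abs_min}")


def similarity_matrix(q: ResidueEmbedding, t: ResidueEmbedding) -> SimilarityMatrix:
    """Per-cell cosine of query and target residue embeddings."""
    if q.dim != t.dim:
        raise InvalidInputError(
            f"embedding dimensions differ: {q.dim} vs {t.dim}"
        )
    qn = np.linalg.norm(q.matrix, axis=1, keepdims=True)
    tn = np.linalg.norm(t.matrix, axis=1, keepdims=True)
    if np.any(qn == 0) or np.any(tn == 0):
        raise InvalidInputError("embedding contains a zero row; cosine undefined")
    S = (q.matrix / qn) @ (t.matrix / tn).T
    return SimilarityMatrix(S=S, query_id=q.sequence_id, target_id=t.sequence_id)


@njit(cache=False)
def _dp_core(S, gap_open, gap_extend, mode):  # pragma: no cover - jitted
    L1, L2 = S.shape
    M = np.full((L1 + 1, L2 + 1), _NEG)
    Ix = np.full((L1 + 1, L2 + 1), _NEG)  # gap in target (consumes query row)
    Iy = np.full((L1 + 1, L2 + 1), _NEG)  # gap in query (consumes target col)
    pM = np.full((L1 + 1, L2 + 1), -1, dtype=np.int8)
    pX = np.full((L1 + 1, L2 + 1), -1, dtype=np.int8)
    pY = np.full((L1 + 1, L2 + 1), -1, dtype=np.int8)
    # predecessor codes: 0 = M, 1 = Ix, 2 = Iy, 3 = fresh start / free boundary

    M[0, 0] = 0.0
    if mode == 0:  # global: terminal gaps charged
        for i in range(1, L1 + 1):
            Ix[i, 0] = gap_open + (i - 1) * gap_extend
            pX[i, 0] = 0 if i == 1 else 1
        for j in range(1, L2 + 1):
            Iy[0, j] = gap_open + (j - 1) * gap_extend
            pY[0, j] = 0 if j == 1 else 2
    elif mode == 1:  # semiglobal: free leading gaps
        for i in range(1, L1 + 1):
            Ix[i, 0] = 0.0
            pX[i, 0] = 3
        for j in range(1, L2 + 1):
            Iy[0, j] = 0.0
            pY[0, j] = 3

    for i in range(1, L1 + 1):
        for j in range(1, L2 + 1):
            # match state; tie order M > Ix > Iy (> fresh start)
            best = M[i - 1, j - 1]
            p = 0
            if Ix[i - 1, j - 1] > best:
                best = Ix[i - 1, j - 1]
                p = 1
            if Iy[i - 1, j - 1] > best:
                best = Iy[i - 1, j - 1]
                p = 2
            if mode == 2 and 0.0 > best:
                best = 0.0
                p = 3
            M[i, j] = S[i - 1, j - 1] + best
            pM[i, j] = p
            # gap in target (vertical move)
            best = M[i - 1, j] + gap_open
            p = 0
            v = Ix[i - 1, j] + gap_extend
            if v > best:
                best = v
                p = 1
            v = Iy[i - 1, j] + gap_open
            if v > best:
                best = v
                p = 2
            Ix[i, j] = best
            pX[i, j] = p
            # gap in query (horizontal move)
            best = M[i, j - 1] + gap_open
            p = 0
            v = Ix[i, j - 1] + gap_open
            if v > best:
                best = v
                p = 1
            v = Iy[i, j - 1] + gap_extend
            if v > best:
                best = v
                p = 2
            Iy[i, j] = best
            pY[i, j] = p

    # locate the alignment end
    if mode == 0:
        bi, bj = L1, L2
        bstate = 0
        bscore = M[L1, L2]
        if Ix[L1, L2] > bscore:
            bscore = Ix[L1, L2]
            bstate = 1
        if Iy[L1, L2] > bscore:
            bscore = Iy[L1, L2]
            bstate = 2
    elif mode == 1:
        bscore = 0.0
        bi, bj, bstate = 0, 0, 3
        for j in range(L2 + 1):  # last row
            for s in range(3):
                v = M[L1, j] if s == 0 else (Ix[L1, j] if s == 1 else Iy[L1, j])
                if v > bscore:
                    bscore = v
                    bi, bj, bstate = L1, j, s
        for i in range(L1 + 1):  # last column
            for s in range(3):
                v = M[i, L2] if s == 0 else (Ix[i, L2] if s == 1 else Iy[i, L2])
                if v > bscore:
                    bscore = v
                    bi, bj, bstate = i, L2, s
    else:
        bscore = 0.0
        bi, bj, bstate = 0, 0, 3
        for i in range(1, L1 + 1):
            for j in range(1, L2 + 1):
                if M[i, j] > bscore:
                    bscore = M[i, j]
                    bi, bj, bstate = i, j, 0

    # traceback
    cap = L1 if L1 < L2 else L2
    pairs = np.empty((cap, 2), dtype=np.int64)
    n = 0
    i, j, state = bi, bj, bstate
    while state != 3 and not (i == 0 and j == 0):
        if state == 0:
            pairs[cap - 1 - n, 0] = i - 1
            pairs[cap - 1 - n, 1] = j - 1
            n += 1
            state = pM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            state = pX[i, j]
            i -= 1
        else:
            state = pY[i, j]
            j -= 1
    return bscore, pairs[cap - n :]


def dp_align(
    S,
    mode: str = "global",
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> AlignmentResult:
    """Affine-gap DP over a similarity matrix with deterministic traceback.

    ``gap_open`` is the penalty of the first residue of a gap run and
    ``gap_extend`` of each further residue; switching gap direction opens a
    new run, so each maximal unmatched run in either sequence costs
    ``gap_open + (len - 1) * gap_extend`` independently.  The usual affine
    convention ``gap_open <= gap_extend <= 0`` is required — otherwise the
    optimum would fragment gap runs.  Ties prefer diagonal over vertical
    over horizontal moves.
    """
    sm = S if isinstance(S, SimilarityMatrix) else SimilarityMatrix(S=np.asarray(S))
    if mode not in MODES:
        raise InvalidInputError(f"mode must be one of {MODES}, got {mode!r}")
    if not gap_open <= gap_extend <= 0:
        raise InvalidInputError(
            f"need gap_open <= gap_extend <= 0, got open={gap_open}, extend={gap_extend}"
        )
    score, pairs = _dp_core(sm.S, float(gap_open), float(gap_extend), _MODE_CODE[mode])
    if mode in ("local", "semiglobal") and score <= 0.0:
        return AlignmentResult(pairs=[], score=0.0, mode=mode)
    return AlignmentResult(
        pairs=[(int(a), int(b)) for a, b in pairs], score=float(score), mode=mode
    )


def self_alignment_score(
    q: ResidueEmbedding,
    mode: str = "global",
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> float:
    """Alignment score of a query against itself — the filter's maximum.

    With normalised rows and a diagonal-dominant self-similarity matrix
    this equals the query length in global mode.
    """
    return dp_align(similarity_matrix(q, q), mode=mode, gap_open=gap_open,
                    gap_extend=gap_extend).score


def filter_hits(
    hits: Sequence[Tuple[str, float]],
    self_score: float,
    params: FilterParams = FilterParams(),
) -> List[Tuple[str, float]]:
    """Keep hits passing both rules: score >= rel_frac * self_score and
    score >= abs_min.  Input order is preserved."""
    if not self_score > 0:
        raise InvalidInputError(f"self_score must be positive, got {self_score}")
    cut = params.rel_frac * self_score
    return [(hid, s) for hid, s in hits if s >= cut and s >= params.abs_min]
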