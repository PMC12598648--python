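"""Complex-prediction input features and the recycling controller.

Four pieces feed a multimer structure predictor:

* **Taxonomy pairing** — per-chain MSA rows that share a source-organism
  identifier are joined into combined rows so inter-chain covariation is
  visible.  Within a taxon, rows are ranked by alignment score and paired
  by rank up to the smallest per-chain count; chains lacking the taxon
  contribute all-gap segments.
* **Block-diagonal unpaired MSA** — rows not consumed by pairing are
  stacked so each covers only its own chain's column span, gaps elsewhere.
* **Template gating** — predicted monomer models are reused as structural
  templates only when their mean per-residue confidence (pLDDT, 0-100)
  strictly exceeds a threshold (default 70).
* **Early stopping** — recycling halts once the optimally superposed CA
  RMSD between consecutive iterations drops below a cutoff (default 1 Å).

Paired and block-diagonal rows are built from match-state rows (insertions
stripped), so every combined row length is the sum of chain query lengths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import InvalidInputError
from .msa_build import Msa

DEFAULT_PLDDT_THRESHOLD = 70.0
DEFAULT_RMSD_CUTOFF = 1.0


@dataclass
class PairedFeature:
    """Paired + block-diagonal rows for one complex."""

    query_row: str
    paired_rows: List[str]
    unpaired_block: List[str]
    chain_lengths: List[int]


@dataclass
class TemplateSelection:
    """Monomer models accepted as templates, with their mean pLDDT."""

    accepted: List[str]
    mean_plddt: Dict[str, float]


@dataclass
class RecycleState:
    """CA coordinates of the current and previous recycling iteration."""

    iteration: int
    current: np.ndarray
    previous: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.current = np.asarray(self.current, dtype=np.float64)
        if self.current.ndim != 2 or self.current.shape[1] != 3:
            raise InvalidInputError("coordinates must have shape [n_res, 3]")
        if not np.all(np.isfinite(self.current)):
            raise InvalidInputError("coordinates contain non-finite values")
        if self.previous is not None:
            self.previous = np.asarray(self.previous, dtype=np.float64)
            if self.previous.shape != self.current.shape:
                raise InvalidInputError("iterations have mismatched residue counts")
            if not np.all(np.isfinite(self.previous)):
                raise InvalidInputError("coordinates contain non-finite values")


def _rows_by_taxon(chain: Msa) -> Dict[str, List[int]]:
    """Hit-row indices grouped by taxid, each group sorted by descending
    alignment score then id (the pairing rank order)."""
    groups: Dict[str, List[int]] = {}
    for idx in range(1, chain.depth):
        tax = chain.meta[idx].taxid
        if tax is None:
            continue
        groups.setdefault(tax, []).append(idx)
    for tax, idxs in groups.items():
        idxs.sort(key=lambda i: (-chain.meta[i].score, chain.meta[i].sequence_id))
    return groups


def pair_msas(
    chains: Sequence[Msa], require_all_chains: bool = False
) -> Tuple[List[str], List[List[int]]]:
    """Pair per-chain MSA rows by shared taxonomy identifier.

    For every taxon present in at least two chains (all chains when
    ``require_all_chains``), rows are paired rank-by-rank up to the
    minimum count among the chains carrying the taxon; absent chains are
    filled with gaps.  Returns the combined paired rows and, per chain,
    the indices of rows left unpaired (input order preserved).
    """
    if len(chains) < 2:
        raise InvalidInputError("pairing requires at least 2 chains")
    lengths = [len(c.query_row) for c in chains]
    by_taxon = [_rows_by_taxon(c) for c in chains]
    all_taxa = sorted(set().union(*[set(g) for g in by_taxon]))
    need = len(chains) if require_all_chains else 2

    consumed: List[set] = [set() for _ in chains]
    paired_rows: List[str] = []
    match_rows = [c.match_rows() for c in chains]
    for tax in all_taxa:
        holders = [ci for ci, g in enumerate(by_taxon) if tax in g]
        if len(holders) < need:
            continue
        n_pairs = min(len(by_taxon[ci][tax]) for ci in holders)
        for rank in range(n_pairs):
            segments = []
            for ci, chain in enumerate(chains):
                if ci in holders:
                    ridx = by_taxon[ci][tax][rank]
                    segments.append(match_rows[ci][ridx])
                    consumed[ci].add(ridx)
                else:
                    segments.append("-" * lengths[ci])
            paired_rows.append("".join(segments))
    unpaired = [
        [idx for idx in range(1, c.depth) if idx not in consumed[ci]]
        for ci, c in enumerate(chains)
    ]
    return paired_rows, unpaired


def block_diagonal_unpaired(
    chains: Sequence[Msa], unpaired: Sequence[Sequence[int]]
) -> List[str]:
    """Stack unpaired rows block-diagonally: each row carries its chain's
    match-state content in its own column span and gaps elsewhere."""
    if len(chains) != len(unpaired):
        raise InvalidInputError("chains and unpaired index lists must align")
    lengths = [len(c.query_row) for c in chains]
    total = sum(lengths)
    rows: List[str] = []
    offset = 0
    for ci, chain in enumerate(chains):
        match_rows = chain.match_rows()
        left = "-" * offset
        right = "-" * (total - offset - lengths[ci])
        for ridx in unpaired[ci]:
            rows.append(left + match_rows[ridx] + right)
        offset += lengths[ci]
    return rows


def build_paired_features(
    chains: Sequence[Msa], require_all_chains: bool = False
) -> PairedFeature:
    """Convenience wrapper producing the full paired feature set."""
    paired_rows, unpaired = pair_msas(chains, require_all_chains=require_all_chains)
    block = block_diagonal_unpaired(chains, unpaired)
    return PairedFeature(
        query_row="".join(c.query_row for c in chains),
        paired_rows=paired_rows,
        unpaired_block=block,
        chain_lengths=[len(c.query_row) for c in chains],
    )


def select_templates(
    models: Sequence[Tuple[str, np.ndarray]],
    threshold: float = DEFAULT_PLDDT_THRESHOLD,
) -> TemplateSelection:
    """Accept monomer models whose mean pLDDT strictly exceeds the threshold."""
    accepted: List[str] = []
    means: Dict[str, float] = {}
    for model_id, plddt in models:
        arr = np.asarray(plddt, dtype=np.float64)
        if arr.ndim != 1 or arr.size < 1:
            raise InvalidInputError(f"model {model_id!r}: pLDDT must be a 1-D array")
        if np.any(arr < 0) or np.any(arr > 100) or not np.all(np.isfinite(arr)):
            raise InvalidInputError(f"model {model_id!r}: pLDDT values must be in [0, 100]")
        mean = float(arr.mean())
        means[model_id] = mean
        if mean > threshold:
            accepted.append(model_id)
    return TemplateSelection(accepted=accepted, mean_plddt=means)


def kabsch_rmsd(A: np.ndarray, B: np.ndarray, superpose: bool = True) -> float:
    """Minimal CA RMSD between two coordinate sets.

    With ``superpose`` (default) both sets are centred and the optimal
    proper rotation is found (Kabsch, via quaternion SVD), making the
    result invariant to rigid motion of either set.  ``superpose=False``
    compares the coordinates in their shared frame as given.
    """
    A = np.asarray(A, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise InvalidInputError(f"coordinate shapes must match [n, 3]: {A.shape} vs {B.shape}")
    n = A.shape[0]
    if n < 1:
        raise InvalidInputError("need at least one point")
    if not superpose:
        return float(np.sqrt(((A - B) ** 2).sum(axis=1).mean()))
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    if n == 1:
        return 0.0
    with warnings.catch_warnings():
        # degenerate point sets (collinear) have non-unique optimal rotations;
        # the attained RMSD is still well defined
        warnings.simplefilter("ignore", UserWarning)
        _, rssd = Rotation.align_vectors(Ac, Bc)
    return float(rssd / np.sqrt(n))


def should_stop(state: RecycleState, cutoff: float = DEFAULT_RMSD_CUTOFF) -> bool:
    """True once consecutive-iteration CA RMSD falls strictly below the
    cutoff; always False on the first iteration (no previous structure)."""
    if cutoff <= 0:
        raise InvalidInputError(f"cutoff must be positive, got {cutoff}")
    if state.previous is None:
        return False
    return kabsch_rmsd(state.previous, state.current) < cutoff
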