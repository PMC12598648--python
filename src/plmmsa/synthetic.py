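"""Deterministic synthetic fixtures: protein families, decoys, coordinates.

Every stage of the pipeline can be exercised against ground truth without
any external database.  Homologous families are emulated by mutating a
random ancestor: per-site substitutions at a fixed rate (uniform over the
19 alternative residues, so per-site identity to the ancestor is exactly
``1 - rate`` in expectation) and occasional indels with geometric lengths
(p = 0.5, capped at 5).  Decoys are i.i.d. uniform-composition sequences.
Coordinate pairs for the recycling controller are 3.8 Å-step random walks
plus a rigid transform and optional Gaussian noise.

All generators are pure functions of their seeds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .encoder import AA20
from .errors import InvalidInputError

_MAX_INDEL = 5


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of the synthetic family generator."""

    n_families: int = 20
    members_per_family: int = 20
    ancestor_length: int = 60
    substitution_rate: float = 0.1
    indel_rate: float = 0.02
    taxonomy_pool_size: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_families, self.members_per_family, self.ancestor_length,
               self.taxonomy_pool_size) < 1:
            raise InvalidInputError("all counts must be >= 1")
        for rate in (self.substitution_rate, self.indel_rate):
            if not 0.0 <= rate <= 1.0:
                raise InvalidInputError(f"rates must be in [0, 1], got {rate}")


@dataclass
class FamilySet:
    """Generated family sequences plus ground truth."""

    records: List[Tuple[str, str]]  # (seq_id, sequence)
    truth: pd.DataFrame  # columns: seq_id, family_id, taxid
    ancestors: Dict[str, str]  # family_id -> ancestor sequence


def _mutate(rng: np.random.Generator, ancestor: str, sub_rate: float,
            indel_rate: float) -> str:
    aa = np.frombuffer(AA20.encode("ascii"), dtype=np.uint8)
    seq = list(ancestor)
    # substitutions: replace with one of the 19 alternatives
    for i in range(len(seq)):
        if rng.random() < sub_rate:
            alternatives = [c for c in AA20 if c != seq[i]]
            seq[i] = alternatives[rng.integers(19)]
    if indel_rate > 0:
        out: List[str] = []
        i = 0
        while i < len(seq):
            u = rng.random()
            if u < indel_rate / 2:  # insertion before this position
                g = min(int(rng.geometric(0.5)), _MAX_INDEL)
                out.extend(chr(aa[rng.integers(20)]) for _ in range(g))
                out.append(seq[i])
                i += 1
            elif u < indel_rate:  # deletion of a run starting here
                g = min(int(rng.geometric(0.5)), _MAX_INDEL)
                i += g
            else:
                out.append(seq[i])
                i += 1
        seq = out if out else [seq[0]]
    return "".join(seq)


def generate_families(spec: FamilySpec) -> FamilySet:
    """Generate homologous families with membership and taxonomy truth."""
    rng = np.random.default_rng(spec.seed)
    records: List[Tuple[str, str]] = []
    truth_rows = []
    ancestors: Dict[str, str] = {}
    for f in range(spec.n_families):
        fam_id = f"F{f:03d}"
        ancestor = "".join(AA20[rng.integers(20)] for _ in range(spec.ancestor_length))
        ancestors[fam_id] = ancestor
        for m in range(spec.members_per_family):
            seq = _mutate(rng, ancestor, spec.substitution_rate, spec.indel_rate)
            seq_id = f"{fam_id}_M{m:03d}"
            taxid = f"tax{rng.integers(spec.taxonomy_pool_size):03d}"
            records.append((seq_id, seq))
            truth_rows.append({"seq_id": seq_id, "family_id": fam_id, "taxid": taxid})
    return FamilySet(
        records=records,
        truth=pd.DataFrame(truth_rows, columns=["seq_id", "family_id", "taxid"]),
        ancestors=ancestors,
    )


def generate_decoys(
    n: int, length_range: Tuple[int, int] = (50, 80), seed: int = 0
) -> List[Tuple[str, str]]:
    """i.i.d. uniform-composition decoy sequences."""
    lo, hi = length_range
    if n < 0 or lo < 1 or hi < lo:
        raise InvalidInputError("invalid decoy count or length range")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        L = int(rng.integers(lo, hi + 1))
        seq = "".join(AA20[rng.integers(20)] for _ in range(L))
        records.append((f"D{i:04d}", seq))
    return records


def generate_coords(
    n_res: int, sigma: float = 0.0, seed: int = 0
) -> Tuple[np.ndarray, np.ndarray]:
    """Two CA coordinate sets for the early-stopping controller.

    The first is a random walk with 3.8 Å steps (the CA-CA virtual bond
    length); the second is a random rigid transform of it plus isotropic
    Gaussian noise of scale ``sigma``.  With ``sigma = 0`` the superposed
    RMSD is zero.
    """
    if n_res < 1:
        raise InvalidInputError(f"n_res must be >= 1, got {n_res}")
    if sigma < 0:
        raise InvalidInputError(f"sigma must be >= 0, got {sigma}")
    rng = np.random.default_rng(seed)
    steps = rng.normal(size=(n_res, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    A = np.cumsum(3.8 * steps, axis=0)
    R = Rotation.from_rotvec(rng.uniform(-np.pi, np.pi, size=3))
    t = rng.uniform(-10.0, 10.0, size=3)
    B = A @ R.as_matrix().T + t
    if sigma > 0:
        B = B + rng.normal(scale=sigma, size=B.shape)
    return A, B
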