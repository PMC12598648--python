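"""Independent reference implementations used to check the package.

Everything here is deliberately naive (nested loops, exhaustive
enumeration, numerical search) and shares no code with the implementation
under test.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def contrastive_loss_nested(h: np.ndarray, tau: float) -> float:
    """Literal nested-loop evaluation of the contrastive loss."""

    def sim(u, v):
        return float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))

    nq, nt, _ = h.shape
    total = 0.0
    for i in range(nq):
        pos = sum(math.exp(sim(h[i, 0], h[i, j]) / tau) for j in range(1, nt))
        neg = 0.0
        for j in range(nt):
            for k in range(nq):
                if k != i:
                    neg += math.exp(sim(h[i, 0], h[k, j]) / tau)
        total += -math.log(pos / (pos + neg))
    return total / nq


def per_query_loss_from_sims(s: np.ndarray, i: int, tau: float) -> float:
    """L_i evaluated directly from a similarity tensor s[k, j] for anchor i
    (s[i, 0] is the anchor's own slot and is ignored)."""
    nq, nt = s.shape
    pos = sum(math.exp(s[i, j] / tau) for j in range(1, nt))
    neg = sum(
        math.exp(s[k, j] / tau) for k in range(nq) for j in range(nt) if k != i
    )
    return -math.log(pos / (pos + neg))


def _affine(length: int, go: float, ge: float) -> float:
    return 0.0 if length == 0 else go + (length - 1) * ge


def _matching_score(S, qs, ts, mode, go, ge):
    score = sum(S[q, t] for q, t in zip(qs, ts))
    # internal gap runs between consecutive matched pairs
    for (qa, ta), (qb, tb) in zip(zip(qs, ts), zip(qs[1:], ts[1:])):
        score += _affine(qb - qa - 1, go, ge) + _affine(tb - ta - 1, go, ge)
    if mode == "global":
        Lq, Lt = S.shape
        score += _affine(qs[0], go, ge) + _affine(ts[0], go, ge)
        score += _affine(Lq - 1 - qs[-1], go, ge) + _affine(Lt - 1 - ts[-1], go, ge)
    elif mode == "semiglobal":
        # one leading and one trailing run rides the free boundary; the
        # path charges whichever remaining run is cheaper (penalties are
        # negative, so the cheaper charge is the max)
        Lq, Lt = S.shape
        score += max(_affine(qs[0], go, ge), _affine(ts[0], go, ge))
        score += max(
            _affine(Lq - 1 - qs[-1], go, ge), _affine(Lt - 1 - ts[-1], go, ge)
        )
    # local: only internal runs count
    return score


def alignment_score_exhaustive(S: np.ndarray, mode: str, go: float, ge: float) -> float:
    """Optimal alignment score by enumerating every monotone matching."""
    Lq, Lt = S.shape
    if mode == "global":
        best = _affine(Lq, go, ge) + _affine(Lt, go, ge)  # empty alignment
    else:
        best = 0.0
    for k in range(1, min(Lq, Lt) + 1):
        for qs in combinations(range(Lq), k):
            for ts in combinations(range(Lt), k):
                best = max(best, _matching_score(S, qs, ts, mode, go, ge))
    return best


def rmsd_rotation_search(A: np.ndarray, B: np.ndarray) -> float:
    """Minimal RMSD over proper rotations by multi-start numerical search
    on the rotation vector (independent of the SVD-based route)."""
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)

    def obj(rv):
        R = Rotation.from_rotvec(rv).as_matrix()
        d = Ac - Bc @ R.T
        return float(np.sqrt((d**2).sum(axis=1).mean()))

    best = np.inf
    grid = np.linspace(-2.0, 2.0, 3)
    starts = [np.zeros(3)] + [
        np.array([x, y, z]) for x in grid for y in grid for z in grid
    ]
    for rv in starts:
        res = minimize(
            obj, rv, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 3000},
        )
        best = min(best, float(res.fun))
    return best


def a3m_row_accounting(row: str, query_len: int, target: str) -> bool:
    """Column bookkeeping oracle: the row must span exactly query_len match
    columns, and its residue letters read off a contiguous subsequence of
    the target."""
    n_match = sum(1 for ch in row if ch == "-" or ch.isupper())
    if n_match != query_len:
        return False
    letters = "".join(ch for ch in row if ch != "-").upper()
    return letters in target.upper()
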