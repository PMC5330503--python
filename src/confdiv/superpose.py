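"""Rigid-body superposition and C-alpha RMSD between conformers.

The superposition is the standard least-squares fit (Kabsch, via SVD of the
cross-covariance matrix with a determinant correction so the rotation is
always proper).  RMSD between two conformers is computed on C-alpha atoms
over the pairwise intersection of observed positions — the "common folded
regions" — and the fit is performed on exactly the position set on which the
RMSD is reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from confdiv.io import EnsembleRecord

__all__ = [
    "PairComparison",
    "MaxPair",
    "kabsch_rmsd",
    "compare_pair",
    "pairwise_matrix",
    "max_rmsd_pair",
    "rmsd_excluding_union_idrs",
    "per_position_profile",
]


@dataclass(frozen=True)
class PairComparison:
    pair: tuple[str, str]  # sorted, unordered semantics
    n_common: int
    rmsd: float
    per_position_dev: dict[int, float]


@dataclass(frozen=True)
class MaxPair:
    pair: tuple[str, str]
    rmsd: float


def kabsch_rmsd(
    coords_a: np.ndarray, coords_b: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Least-squares superposition of ``coords_b`` onto ``coords_a``.

    Returns ``(rmsd, rotation, translation)`` with the proper rotation R
    (det +1) and translation t minimizing ``|| a - (b @ R.T + t) ||``.

    Degenerate (collinear/coplanar-rank-deficient) point sets still yield a
    defined answer; the caller can detect them from the singular values of
    the covariance (two near-zero singular values).
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"coordinate sets must both be (n, 3); got {a.shape} and {b.shape}")
    n = a.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    h = b0.T @ a0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.array([1.0, 1.0, d])
    rot = vt.T @ np.diag(corr) @ u.T
    e0 = (a0 * a0).sum() + (b0 * b0).sum()
    msd = max(e0 - 2.0 * (s * corr).sum(), 0.0) / n
    trans = ca - rot @ cb
    return float(np.sqrt(msd)), rot, trans


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def compare_pair(
    ens: EnsembleRecord,
    a: str,
    b: str,
    positions: Optional[Iterable[int]] = None,
) -> PairComparison:
    """Superpose two conformers on their common observed C-alpha positions.

    When ``positions`` is given the common set is further intersected with it
    (e.g. to restrict to loop residues or to exclude disorder-affected
    positions); the fit uses exactly the reported set.
    """
    common = ens.common_observed_positions(a, b)
    if positions is not None:
        allowed = set(positions)
        common = [p for p in common if p in allowed]
    if len(common) < 3:
        raise ValueError(
            f"{ens.protein_id}: conformers {a},{b} share only {len(common)} usable positions"
        )
    xa = ens.conformer(a).ca_coords(common)
    xb = ens.conformer(b).ca_coords(common)
    rmsd, rot, trans = kabsch_rmsd(xa, xb)
    moved = xb @ rot.T + trans
    dev = np.linalg.norm(xa - moved, axis=1)
    return PairComparison(_pair_key(a, b), len(common), rmsd, dict(zip(common, dev.tolist())))


def pairwise_matrix(
    ens: EnsembleRecord, positions: Optional[Iterable[int]] = None
) -> list[PairComparison]:
    """All n(n-1)/2 unordered conformer comparisons of an ensemble."""
    ids = sorted(c.conformer_id for c in ens.conformers)
    if len(ids) < 2:
        raise ValueError(f"{ens.protein_id}: need at least 2 conformers")
    pos = None if positions is None else set(positions)
    out = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            out.append(compare_pair(ens, a, b, pos))
    return out


def max_rmsd_pair(
    ens: EnsembleRecord, comparisons: Optional[Sequence[PairComparison]] = None
) -> MaxPair:
    """The pair of conformers with maximum C-alpha RMSD.

    Ties are broken by lexicographic pair order, so the result is
    deterministic.  Precomputed ``comparisons`` may be supplied to avoid
    recomputation.
    """
    comps = pairwise_matrix(ens) if comparisons is None else list(comparisons)
    best_rmsd = max(c.rmsd for c in comps)
    tied = sorted(c.pair for c in comps if c.rmsd == best_rmsd)
    return MaxPair(tied[0], best_rmsd)


def rmsd_excluding_union_idrs(ens: EnsembleRecord, idrs) -> MaxPair:
    """Max-RMSD pair recomputed after removing every position that is inside a
    disordered segment in *any* conformer of the ensemble.

    ``idrs`` is an iterable of :class:`confdiv.disorder.IDRAnnotation`, one
    per conformer.
    """
    excluded: set[int] = set()
    for ann in idrs:
        for start, end in ann.segments:
            excluded.update(range(start, end + 1))
    allowed = set(ens.correspondence) - excluded
    if len(allowed) < 3:
        raise ValueError(
            f"{ens.protein_id}: fewer than 3 positions remain outside the IDR union"
        )
    comps = pairwise_matrix(ens, positions=allowed)
    best_rmsd = max(c.rmsd for c in comps)
    tied = sorted(c.pair for c in comps if c.rmsd == best_rmsd)
    return MaxPair(tied[0], best_rmsd)


def per_position_profile(ens: EnsembleRecord) -> dict[int, float]:
    """Root-mean-square per-position deviation over all conformer pairs.

    Each pair is globally superposed first; a position contributes to the
    profile for every pair in which it is common.  Positions common to no
    pair are absent from the result.
    """
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for comp in pairwise_matrix(ens):
        for pos, dev in comp.per_position_dev.items():
            sums[pos] = sums.get(pos, 0.0) + dev * dev
            counts[pos] = counts.get(pos, 0) + 1
    return {pos: float(np.sqrt(sums[pos] / counts[pos])) for pos in sorted(sums)}
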