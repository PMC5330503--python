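"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from confdiv.io import AtomRecord, ConformerStructure, ResidueRecord, build_ensemble


def conf_from_ca(
    ca: np.ndarray,
    name: str = "TEST",
    observed_mask: np.ndarray | None = None,
    sequence: str | None = None,
    method: str = "xray",
    resolution: float = 1.8,
    ligands=(),
) -> ConformerStructure:
    """Build a conformer from a C-alpha trace (one carbon atom per residue).

    ``observed_mask`` marks residues as unobserved (missing density) while
    keeping them in the sequence.
    """
    ca = np.asarray(ca, dtype=float)
    n = ca.shape[0]
    mask = np.ones(n, dtype=bool) if observed_mask is None else np.asarray(observed_mask)
    seq = sequence or "A" * n
    residues = []
    for i in range(n):
        if mask[i]:
            atoms = [AtomRecord("CA", "C", tuple(ca[i]))]
            residues.append(
                ResidueRecord(i + 1, seq[i], True, ca_xyz=ca[i].copy(), atoms=atoms)
            )
        else:
            residues.append(ResidueRecord(i + 1, seq[i], False))
    return ConformerStructure(
        conformer_id=f"{name}_A", residues=residues, method=method,
        resolution=resolution, ligands=list(ligands), sequence_length=n,
    )


def ensemble_from_traces(traces: dict[str, np.ndarray], protein_id: str = "prot",
                         observed_masks: dict[str, np.ndarray] | None = None):
    confs = [
        conf_from_ca(xyz, name=name,
                     observed_mask=(observed_masks or {}).get(name))
        for name, xyz in traces.items()
    ]
    return build_ensemble(confs, protein_id)


def quaternion_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Independent superposition oracle: Horn's quaternion method.

    The optimal RMSD follows from the largest eigenvalue of the 4x4 key
    matrix of the cross-covariance; no rotation matrix is ever formed, so
    the code path is disjoint from the SVD-based implementation.
    """
    a = np.asarray(coords_a, float)
    b = np.asarray(coords_b, float)
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)
    s = b0.T @ a0
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(k).max()
    e0 = (a0 * a0).sum() + (b0 * b0).sum()
    return float(np.sqrt(max(e0 - 2.0 * lam, 0.0) / a.shape[0]))


def random_rigid_motion(rng: np.random.Generator):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    return rot, rng.uniform(-30, 30, size=3)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


# --- canonical geometric fixtures ------------------------------------------


def cubic_cavity_conformer(mouth_radius: float = 1.8) -> ConformerStructure:
    """Atom shell enclosing an empty 5x5x5 A^3 cavity with a narrow mouth."""
    pts = []
    for x in np.arange(-8, 8.01, 1.5):
        for y in np.arange(-8, 8.01, 1.5):
            for z in np.arange(-8, 8.01, 1.5):
                if max(abs(x), abs(y), abs(z)) <= 2.5 + 1.7:
                    continue  # carve the cavity (1.7 = carbon vdw radius)
                if x > 0 and np.hypot(y, z) <= mouth_radius + 1.7:
                    continue  # the mouth channel
                pts.append((x, y, z))
    return conf_from_ca(np.array(pts), name="CAV")


def slab_channel_conformer(channel_radius: float = 2.0, thickness: float = 20.0):
    """Atom slab of given thickness pierced by a straight open channel."""
    pts = []
    half = thickness / 2.0
    for x in np.arange(-12, 12.01, 1.5):
        for y in np.arange(-12, 12.01, 1.5):
            for z in np.arange(-half, half + 0.01, 1.5):
                if np.hypot(x, y) <= channel_radius + 1.7:
                    continue
                pts.append((x, y, z))
    return conf_from_ca(np.array(pts), name="CHN")


def solid_ball_conformer(radius: float = 8.0, n: int = 400, seed: int = 0):
    rng = np.random.default_rng(seed)
    pts = []
    for _ in range(n):
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        pts.append(radius * rng.random() ** (1 / 3) * v)
    return conf_from_ca(np.array(pts), name="BALL")
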