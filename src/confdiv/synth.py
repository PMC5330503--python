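"""Synthetic conformer ensembles with known ground truth.

Each synthetic protein has a shared backbone fold (a three-helix bundle
built from ideal helix parameters, or a random-coil walk for degenerate
geometry), and each conformer of it is produced by a random rigid-body
motion, isotropic thermal jitter of every C-alpha, and the class-specific
flexibility mechanism:

* ``rigid`` — thermal jitter only; no residue is ever missing interiorly.
* ``partially_disordered`` — an interior flexible segment is unobserved
  (missing density) in most conformers (default 70%, the regime observed
  for this class); conformers in the disordered state also displace a
  second, ordered segment, so the largest structural differences involve
  disordered conformers and the max-RMSD pair contains one.
* ``malleable`` — the flexible segment is unobserved in few conformers
  (default 25%) and, when observed, adopts one of two opposed large-
  displacement arrangements; the max-RMSD pair is therefore a fully
  ordered pair while IDRs still occur elsewhere in the ensemble.

Generation is deterministic given the seed: the same spec and seed produce
byte-identical PDB files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from confdiv.io import (
    AtomRecord,
    ConformerStructure,
    EnsembleRecord,
    LigandRecord,
    ResidueRecord,
    build_ensemble,
    write_conformer_pdb,
)

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "build_conformers",
    "generate_ensemble",
    "generate_cohort",
    "generate_cohort_ensembles",
    "class_default_spec",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SyntheticSpec:
    target_class: str  # rigid | partially_disordered | malleable
    n_conformers: int = 8
    length: int = 110
    backbone: str = "helix_bundle"  # or "random_coil_walk"
    thermal_sd: float = 0.3  # A, isotropic C-alpha jitter
    flexible_segment: Optional[tuple[int, int]] = None
    flexible_displacement: float = 0.0  # A, amplitude of the segment arrangement
    disorder_probability: float = 0.0  # chance the flexible segment is unobserved
    coupled_segment: Optional[tuple[int, int]] = None
    coupled_displacement: float = 0.0  # A, ordered-part displacement of disordered conformers
    hinge: Optional[tuple[int, float]] = None  # (position, angle in degrees)
    ligand: Optional[tuple[str, int]] = None  # (het code, n heavy atoms)
    ligand_probability: float = 0.7
    seed: int = 0
    protein_id: str = "SYN"

    def validate(self) -> None:
        if self.target_class not in ("rigid", "partially_disordered", "malleable"):
            raise ValueError(f"unknown target_class {self.target_class!r}")
        if self.n_conformers < 5:
            raise ValueError("need at least 5 conformers")
        if self.target_class == "rigid" and self.disorder_probability > 0:
            raise ValueError("a rigid spec cannot have disorder_probability > 0")
        if self.disorder_probability > 0:
            if self.flexible_segment is None:
                raise ValueError("disorder requires a flexible_segment")
            s, e = self.flexible_segment
            if s < 21 or e > self.length - 20:
                raise ValueError(
                    f"flexible_segment {self.flexible_segment} must lie in "
                    f"[21, {self.length - 20}]"
                )


@dataclass
class GroundTruth:
    protein_id: str
    true_class: str
    true_idr_segments: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    true_hinge_positions: list[int] = field(default_factory=list)
    true_max_pair_hint: Optional[tuple[str, str]] = None


def class_default_spec(target_class: str, seed: int = 0, protein_id: str = "SYN",
                       **overrides) -> SyntheticSpec:
    """Per-class default generation parameters (the study conditions)."""
    L = int(overrides.pop("length", 110))
    seg = (L // 2 - 7, L // 2 + 7)  # 15-residue interior flexible segment
    coupled = (L // 4 - 7, L // 4 + 7)
    base = dict(seed=seed, protein_id=protein_id, length=L, ligand=("LIG", 12))
    if target_class == "rigid":
        spec = SyntheticSpec(target_class="rigid", thermal_sd=0.3, **base)
    elif target_class == "partially_disordered":
        spec = SyntheticSpec(
            target_class="partially_disordered",
            thermal_sd=0.3,
            flexible_segment=seg,
            flexible_displacement=0.6,
            disorder_probability=0.7,
            coupled_segment=coupled,
            coupled_displacement=1.7,
            **base,
        )
    elif target_class == "malleable":
        spec = SyntheticSpec(
            target_class="malleable",
            thermal_sd=0.3,
            flexible_segment=seg,
            flexible_displacement=2.0,
            disorder_probability=0.25,
            **base,
        )
    else:
        raise ValueError(f"unknown target_class {target_class!r}")
    return replace(spec, **overrides) if overrides else spec


# ---------------------------------------------------------------------------
# backbone construction
# ---------------------------------------------------------------------------


def _ideal_helix(n: int, origin: np.ndarray, direction: float) -> np.ndarray:
    """Ideal alpha-helix C-alpha trace: radius 2.3 A, rise 1.5 A, 100 deg/res."""
    i = np.arange(n)
    ang = np.deg2rad(100.0) * i
    xyz = np.stack(
        [2.3 * np.cos(ang), 2.3 * np.sin(ang), direction * 1.5 * i], axis=1
    )
    return xyz + origin


def _helix_bundle(length: int) -> np.ndarray:
    """Three antiparallel ideal helices joined by short linkers."""
    linker = 4
    per = (length - 2 * linker) // 3
    rest = (length - 2 * linker) - 3 * per
    sizes = [per + (1 if k < rest else 0) for k in range(3)]
    offsets = [np.zeros(3), np.array([10.5, 0.0, 0.0]), np.array([5.25, 9.1, 0.0])]
    coords: list[np.ndarray] = []
    for k, (n, off) in enumerate(zip(sizes, offsets)):
        direction = 1.0 if k % 2 == 0 else -1.0
        start = off if direction > 0 else off + np.array([0.0, 0.0, 1.5 * (n - 1)])
        helix = _ideal_helix(n, np.zeros(3), direction) + start
        if coords:
            prev_end = coords[-1]
            first = helix[0]
            for t in range(1, linker + 1):
                coords.append(prev_end + (first - prev_end) * t / (linker + 1))
        coords.extend(helix)
    return np.asarray(coords[:length])


def _coil_walk(length: int, rng: np.random.Generator) -> np.ndarray:
    """Self-avoiding-ish random walk with 3.8 A steps."""
    coords = [np.zeros(3)]
    for _ in range(length - 1):
        for _attempt in range(50):
            step = rng.normal(size=3)
            step *= 3.8 / np.linalg.norm(step)
            cand = coords[-1] + step
            d = np.linalg.norm(np.asarray(coords[:-1]) - cand, axis=1) if len(coords) > 1 else [99]
            if np.min(d) > 3.5:
                break
        coords.append(cand)
    return np.asarray(coords)


def _rotation_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle_rad) * k + (1 - np.cos(angle_rad)) * (k @ k)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _bump_profile(seg: tuple[int, int]) -> np.ndarray:
    s, e = seg
    n = e - s + 1
    return np.sin(np.pi * (np.arange(1, n + 1)) / (n + 1))


# ---------------------------------------------------------------------------
# conformer assembly
# ---------------------------------------------------------------------------


def build_conformers(spec: SyntheticSpec) -> tuple[list[ConformerStructure], GroundTruth]:
    """Deterministically build the conformer objects for one synthetic protein."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    L = spec.length
    sequence = "".join(rng.choice(list(_AA), size=L))

    if spec.backbone == "helix_bundle":
        ref = _helix_bundle(L)
    elif spec.backbone == "random_coil_walk":
        ref = _coil_walk(L, rng)
    else:
        raise ValueError(f"unknown backbone {spec.backbone!r}")

    # disorder states: stratified so small ensembles still realise the class
    n = spec.n_conformers
    disordered = np.zeros(n, dtype=bool)
    if spec.disorder_probability > 0:
        disordered = rng.random(n) < spec.disorder_probability
        if spec.target_class == "partially_disordered":
            disordered[0] = True
        elif spec.target_class == "malleable":
            disordered[0] = disordered[1] = False  # the opposed ordered arrangements
            disordered[n - 1] = True

    # per-conformer arrangement of the flexible segment (when observed)
    arrangement_dirs = rng.normal(size=(n, 3))
    arrangement_dirs /= np.linalg.norm(arrangement_dirs, axis=1, keepdims=True)
    signs = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
    if spec.target_class == "malleable":
        # two opposed arrangements along one axis: max pair is ordered 0 vs 1
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        arrangement_dirs = np.outer(signs, u)

    coupled_dirs = rng.normal(size=(n, 3))
    coupled_dirs /= np.linalg.norm(coupled_dirs, axis=1, keepdims=True)

    hinge_conformers = rng.random(n) < 0.5 if spec.hinge else np.zeros(n, dtype=bool)
    if spec.hinge is not None:
        hinge_conformers[0], hinge_conformers[1] = False, True
    lig_present = rng.random(n) < (spec.ligand_probability if spec.ligand else 0.0)

    jitter = rng.normal(scale=spec.thermal_sd, size=(n, L, 3)) if spec.thermal_sd > 0 else np.zeros((n, L, 3))
    rots = [_random_rotation(rng) for _ in range(n)]
    transl = rng.uniform(-20, 20, size=(n, 3))
    resolutions = np.round(rng.uniform(1.2, 2.3, size=n), 2)
    hinge_axes = rng.normal(size=(n, 3))

    truth = GroundTruth(spec.protein_id, spec.target_class)
    conformers: list[ConformerStructure] = []
    centroid = ref.mean(axis=0)

    for k in range(n):
        coords = ref.copy()
        if spec.hinge is not None and hinge_conformers[k]:
            pos, angle = spec.hinge
            rot = _rotation_matrix(hinge_axes[k], np.deg2rad(angle))
            pivot = ref[pos - 1]
            coords[pos - 1 :] = (coords[pos - 1 :] - pivot) @ rot.T + pivot
        if spec.flexible_segment is not None and not disordered[k]:
            s, e = spec.flexible_segment
            w = _bump_profile(spec.flexible_segment)
            coords[s - 1 : e] += spec.flexible_displacement * w[:, None] * arrangement_dirs[k]
        if spec.coupled_segment is not None and disordered[k] and spec.coupled_displacement > 0:
            s, e = spec.coupled_segment
            w = _bump_profile(spec.coupled_segment)
            coords[s - 1 : e] += spec.coupled_displacement * w[:, None] * coupled_dirs[k]
        coords = coords + jitter[k]
        coords = coords @ rots[k].T + transl[k]

        missing: set[int] = set()
        if spec.flexible_segment is not None and disordered[k]:
            s, e = spec.flexible_segment
            missing = set(range(s, e + 1))

        cb_dir = ref - centroid
        cb_norm = np.linalg.norm(cb_dir, axis=1, keepdims=True)
        cb_dir = cb_dir / np.where(cb_norm > 1e-9, cb_norm, 1.0)
        cb = (ref + 1.53 * cb_dir + jitter[k]) @ rots[k].T + transl[k]

        code = f"{spec.seed % 100:02d}{k:02d}"
        cid = f"{code}_A"
        residues = []
        for i in range(L):
            pos = i + 1
            if pos in missing:
                residues.append(ResidueRecord(pos, sequence[i], False))
            else:
                atoms = [
                    AtomRecord("CA", "C", tuple(np.round(coords[i], 3))),
                    AtomRecord("CB", "C", tuple(np.round(cb[i], 3))),
                ]
                residues.append(
                    ResidueRecord(pos, sequence[i], True,
                                  ca_xyz=np.array(atoms[0].xyz), atoms=atoms)
                )
        ligands = []
        if spec.ligand is not None and lig_present[k]:
            het, n_heavy = spec.ligand
            surf_dir = rng.normal(size=3)
            surf_dir /= np.linalg.norm(surf_dir)
            lig_center = centroid + surf_dir * (np.linalg.norm(ref - centroid, axis=1).max() + 3.0)
            ang = 2 * np.pi * np.arange(n_heavy) / n_heavy
            ring = np.stack([1.4 * np.cos(ang), 1.4 * np.sin(ang), 0.05 * np.arange(n_heavy)], axis=1)
            lig_xyz = (lig_center + ring) @ rots[k].T + transl[k]
            atoms = tuple(
                AtomRecord(f"C{j+1}", "C", tuple(np.round(lig_xyz[j], 3)))
                for j in range(n_heavy)
            )
            mw = float(sum(12.0107 for _ in range(n_heavy)))
            ligands.append(LigandRecord(het, n_heavy, mw, atoms, 900))

        conformers.append(
            ConformerStructure(
                conformer_id=cid,
                residues=residues,
                method="xray",
                resolution=float(resolutions[k]),
                temperature=100.0,
                ligands=ligands,
                sequence_length=L,
                chain_id="A",
            )
        )
        truth.true_idr_segments[cid] = (
            [spec.flexible_segment] if (spec.flexible_segment and disordered[k]) else []
        )

    if spec.hinge is not None:
        truth.true_hinge_positions = [spec.hinge[0]]
    if spec.target_class == "malleable":
        truth.true_max_pair_hint = tuple(sorted((conformers[0].conformer_id,
                                                 conformers[1].conformer_id)))
    return conformers, truth


def generate_ensemble(
    spec: SyntheticSpec, out_dir: str | Path
) -> tuple[list[Path], GroundTruth]:
    """Write one synthetic ensemble as PDB files; deterministic given the seed."""
    conformers, truth = build_conformers(spec)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for conf in conformers:
        p = out / f"{spec.protein_id}_{conf.conformer_id}.pdb"
        write_conformer_pdb(conf, p)
        paths.append(p)
    return paths, truth


def _cohort_specs(
    n_per_class: int, seed: int, overrides: Optional[dict] = None
) -> list[SyntheticSpec]:
    rng = np.random.default_rng(seed)
    specs = []
    classes = ("rigid", "partially_disordered", "malleable")
    for i in range(n_per_class):
        for cls in classes:  # interleaved
            child_seed = int(rng.integers(0, 2**31 - 1))
            pid = f"{cls[:3]}_{i:03d}"
            specs.append(class_default_spec(cls, seed=child_seed, protein_id=pid,
                                            **(overrides or {})))
    return specs


def generate_cohort_ensembles(
    n_per_class: int, seed: int = 0, overrides: Optional[dict] = None
) -> tuple[list[EnsembleRecord], pd.DataFrame]:
    """In-memory cohort: interleaved classes, per-protein seeds derived from
    the master seed.  Returns ensembles plus a ground-truth table."""
    ensembles, rows = [], []
    for spec in _cohort_specs(n_per_class, seed, overrides):
        conformers, truth = build_conformers(spec)
        ensembles.append(build_ensemble(conformers, spec.protein_id))
        rows.append(
            dict(protein_id=spec.protein_id, true_class=truth.true_class,
                 n_conformers=spec.n_conformers, seed=spec.seed)
        )
    return ensembles, pd.DataFrame(rows)


def generate_cohort(
    n_per_class: int, out_dir: str | Path, seed: int = 0,
    overrides: Optional[dict] = None,
) -> tuple[Path, Path]:
    """On-disk cohort: PDB files, a manifest consumable by the I/O layer and
    a ground-truth table.  Returns (manifest path, truth path)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_rows, truth_rows = [], []
    for spec in _cohort_specs(n_per_class, seed, overrides):
        paths, truth = generate_ensemble(spec, out / spec.protein_id)
        conformers, _ = build_conformers(spec)
        for p, conf in zip(paths, conformers):
            manifest_rows.append(
                dict(protein_id=spec.protein_id,
                     pdb_code=conf.conformer_id.split("_")[0],
                     chain_id=conf.chain_id,
                     path=str(p.relative_to(out)))
            )
        truth_rows.append(dict(protein_id=spec.protein_id, true_class=truth.true_class,
                               seed=spec.seed))
    manifest_path = out / "manifest.tsv"
    truth_path = out / "truth.tsv"
    pd.DataFrame(manifest_rows).to_csv(manifest_path, sep="\t", index=False)
    pd.DataFrame(truth_rows).to_csv(truth_path, sep="\t", index=False)
    return manifest_path, truth_path
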