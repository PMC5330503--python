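"""Reading, writing and grouping of crystallographic conformer structures.

PDB-format files are parsed with :mod:`gemmi`.  Each parsed chain becomes a
:class:`ConformerStructure` whose residue list covers the *full* deposited
sequence: residues without coordinates (missing electron density) are kept as
unobserved records, recovered from the union of REMARK 465 records and
numbering gaps against SEQRES.  Conformers of the same protein are grouped
into an :class:`EnsembleRecord` by author sequence numbering, and the dataset
filters (X-ray only, resolution cutoff, minimum number of conformers) are
applied by :func:`filter_dataset`.

Conventions
-----------
* Coordinates are in Angstrom; sequence positions are 1-based and intervals
  are closed.
* Alternate locations: the highest-occupancy conformation is kept, ties going
  to altloc 'A' (single coordinate per atom).
* A ligand is any non-water HETATM residue; whether it counts as a *cognate*
  ligand for apo/holo calls is decided later by a heavy-atom threshold.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "AtomRecord",
    "ResidueRecord",
    "LigandRecord",
    "ConformerStructure",
    "EnsembleRecord",
    "FilterOutcome",
    "ParseError",
    "ChainNotFoundError",
    "load_conformer",
    "write_conformer_pdb",
    "build_ensemble",
    "filter_dataset",
    "read_manifest",
    "load_ensembles",
]


class ParseError(ValueError):
    """Raised when a coordinate file cannot be interpreted."""


class ChainNotFoundError(KeyError):
    """Raised when the requested chain is absent from the file."""


@dataclass(frozen=True)
class AtomRecord:
    name: str
    element: str
    xyz: tuple[float, float, float]


@dataclass
class ResidueRecord:
    """One position of the full deposited sequence.

    ``observed`` is True iff the residue has coordinates (and then a C-alpha
    coordinate must be present); unobserved residues carry no atoms.
    """

    seq_pos: int
    aa: str
    observed: bool
    ca_xyz: Optional[np.ndarray] = None
    atoms: Optional[list[AtomRecord]] = None
    name3: str = ""

    def __post_init__(self) -> None:
        if self.observed and self.ca_xyz is None:
            raise ValueError(f"observed residue {self.seq_pos} lacks a CA coordinate")
        if not self.observed and self.ca_xyz is not None:
            raise ValueError(f"unobserved residue {self.seq_pos} carries coordinates")


@dataclass(frozen=True)
class LigandRecord:
    het_code: str
    n_heavy_atoms: int
    molecular_weight: float  # Da, summed over the atoms present in the file
    atoms: tuple[AtomRecord, ...] = ()
    seq_num: int = 0


@dataclass
class ConformerStructure:
    """One crystallographic chain of one PDB entry."""

    conformer_id: str  # pdb_code + "_" + chain_id
    residues: list[ResidueRecord]
    method: str = "other"  # {"xray", "nmr", "other"}
    resolution: Optional[float] = None  # Angstrom
    temperature: Optional[float] = None  # Kelvin
    ligands: list[LigandRecord] = field(default_factory=list)
    sequence_length: int = 0
    chain_id: str = "A"
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sequence_length == 0:
            self.sequence_length = len(self.residues)
        pos = [r.seq_pos for r in self.residues]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("residues must be strictly increasing in seq_pos")
        if self.sequence_length < sum(r.observed for r in self.residues):
            raise ValueError("sequence_length smaller than number of observed residues")

    # -- convenience accessors -------------------------------------------------
    @property
    def observed_positions(self) -> list[int]:
        return [r.seq_pos for r in self.residues if r.observed]

    @property
    def n_observed(self) -> int:
        return sum(r.observed for r in self.residues)

    def residue_at(self, seq_pos: int) -> Optional[ResidueRecord]:
        i = self._index().get(seq_pos)
        return None if i is None else self.residues[i]

    def _index(self) -> dict[int, int]:
        if not hasattr(self, "_pos_index"):
            self._pos_index = {r.seq_pos: i for i, r in enumerate(self.residues)}
        return self._pos_index

    def ca_coords(self, positions: Sequence[int]) -> np.ndarray:
        idx = self._index()
        return np.array([self.residues[idx[p]].ca_xyz for p in positions], dtype=float)

    def heavy_atoms(self, exclude_positions: Iterable[int] = ()) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """(coords, residue seq_pos per atom, element symbols) over observed residues."""
        skip = set(exclude_positions)
        coords, respos, elements = [], [], []
        for r in self.residues:
            if not r.observed or r.seq_pos in skip:
                continue
            for a in r.atoms or []:
                if a.element in ("H", "D"):
                    continue
                coords.append(a.xyz)
                respos.append(r.seq_pos)
                elements.append(a.element)
        return np.asarray(coords, dtype=float).reshape(-1, 3), np.asarray(respos, dtype=int), elements


@dataclass
class EnsembleRecord:
    """All conformers of one protein, matched by author sequence numbering."""

    protein_id: str
    conformers: list[ConformerStructure]
    correspondence: dict[int, dict[str, int]]  # seq_pos -> conformer_id -> residue index
    mutation_positions: list[int] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    @property
    def n_conformers(self) -> int:
        return len(self.conformers)

    @property
    def sequence_length(self) -> int:
        return self.conformers[0].sequence_length

    def conformer(self, conformer_id: str) -> ConformerStructure:
        for c in self.conformers:
            if c.conformer_id == conformer_id:
                return c
        raise KeyError(conformer_id)

    def common_observed_positions(self, a: str, b: str) -> list[int]:
        ca, cb = self.conformer(a), self.conformer(b)
        sa = set(ca.observed_positions)
        return sorted(sa.intersection(cb.observed_positions))


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

_REMARK465_RE = re.compile(r"^REMARK 465\s+(?:\d+\s+)?([A-Z0-9]{1,3})\s+(\S)\s+(-?\d+)([A-Za-z]?)\s*$")
_TEMPERATURE_RE = re.compile(r"TEMPERATURE\s+\(KELVIN\)\s*:\s*([\d.]+)")


def _one_letter(name3: str) -> str:
    info = gemmi.find_tabulated_residue(name3)
    if info is None:
        return "X"
    code = info.one_letter_code.upper()
    return code if code.isalpha() else "X"


def _pick_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Resolve alternate locations: highest occupancy wins, ties prefer altloc 'A'."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
            continue
        key = (atom.occ, -(ord(atom.altloc or "z")))
        prev_key = (prev.occ, -(ord(prev.altloc or "z")))
        if key > prev_key:
            by_name[atom.name] = atom
    return list(by_name.values())


def _parse_missing_residues(raw_remarks: Iterable[str], chain: str) -> dict[int, str]:
    """REMARK 465 entries for one chain: author seq number -> residue name."""
    missing: dict[int, str] = {}
    for line in raw_remarks:
        m = _REMARK465_RE.match(line.rstrip())
        if m is None:
            continue
        name3, ch, num, icode = m.groups()
        if ch != chain or name3 in ("RES", "SSSEQI"):
            continue
        if icode:
            # insertion-coded missing residues are rare; record under base number
            pass
        missing[int(num)] = name3
    return missing


def _experimental_method(st: gemmi.Structure) -> str:
    raw = (st.info["_exptl.method"] if "_exptl.method" in st.info else "").upper()
    if "X-RAY" in raw or "XRAY" in raw:
        return "xray"
    if "NMR" in raw:
        return "nmr"
    return "other"


def load_conformer(path: str | Path, chain: str, conformer_id: Optional[str] = None) -> ConformerStructure:
    """Parse one chain of a PDB-format file into a :class:`ConformerStructure`.

    Missing residues are recovered from REMARK 465 records and from numbering
    gaps against SEQRES; metadata (method, resolution, temperature) comes from
    header records when present.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path} contains no models")
    st.setup_entities()
    model = st[0]
    gchain = model.find_chain(chain)
    if gchain is None:
        raise ChainNotFoundError(f"chain {chain!r} not found in {path}")

    missing465 = _parse_missing_residues(st.raw_remarks, chain)

    # SEQRES (full deposited sequence) if present
    seqres: list[str] = []
    for ent in st.entities:
        if ent.entity_type == gemmi.EntityType.Polymer and (
            chain in ent.subchains or ent.name == chain
        ):
            seqres = list(ent.full_sequence)
            break
    if not seqres:
        for sub in gchain.subchains():
            pass  # no SEQRES; fall back to author-numbering span below

    observed: dict[int, tuple[str, list[gemmi.Atom]]] = {}
    ligands: list[LigandRecord] = []
    has_icode = False
    for res in gchain:
        info = gemmi.find_tabulated_residue(res.name)
        is_water = info is not None and info.is_water()
        is_aa = info is not None and info.is_amino_acid()
        if res.het_flag == "H" and not is_aa:
            if is_water or res.name == "HOH":
                continue
            atoms = tuple(
                AtomRecord(a.name, a.element.name, (a.pos.x, a.pos.y, a.pos.z))
                for a in _pick_altlocs(res)
            )
            heavy = sum(1 for a in atoms if a.element not in ("H", "D"))
            mw = float(sum(gemmi.Element(a.element).weight for a in atoms))
            ligands.append(LigandRecord(res.name, heavy, mw, atoms, res.seqid.num))
            continue
        if not is_aa:
            continue
        if res.seqid.icode.strip():
            has_icode = True
        observed[res.seqid.num] = (res.name, _pick_altlocs(res))

    if not observed and not missing465:
        raise ChainNotFoundError(f"chain {chain!r} in {path} has no polymer residues")

    all_nums = sorted(set(observed) | set(missing465))
    # positions follow author numbering so conformers of the same protein
    # align naturally; rebased only when the numbering dips below 1
    first = all_nums[0]
    shift = 1 - first if first < 1 else 0
    last = max(all_nums[-1], first + len(seqres) - 1)
    sequence_length = last - first + 1

    flags: list[str] = []
    if has_icode:
        flags.append("insertion_codes_present")
    if shift:
        flags.append(f"renumbered_by_{shift}")

    residues: list[ResidueRecord] = []
    for num in range(first, last + 1):
        pos = num + shift
        seqres_idx = num - first  # SEQRES assumed head-aligned at the first residue
        if num in observed:
            name3, atoms = observed[num]
            ca = next((a for a in atoms if a.name == "CA"), None)
            recs = [
                AtomRecord(a.name, a.element.name, (a.pos.x, a.pos.y, a.pos.z)) for a in atoms
            ]
            if ca is None:
                # no C-alpha: cannot use the residue in superposition; treat as unobserved
                residues.append(ResidueRecord(pos, _one_letter(name3), False, name3=name3))
                flags.append(f"no_ca_at_{num}")
                continue
            residues.append(
                ResidueRecord(
                    pos,
                    _one_letter(name3),
                    True,
                    ca_xyz=np.array([ca.pos.x, ca.pos.y, ca.pos.z], dtype=float),
                    atoms=recs,
                    name3=name3,
                )
            )
        else:
            if num in missing465:
                name3 = missing465[num]
            elif 0 <= seqres_idx < len(seqres):
                name3 = seqres[seqres_idx]
            else:
                name3 = "UNK"
            residues.append(ResidueRecord(pos, _one_letter(name3), False, name3=name3))

    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    temperature = None
    for line in st.raw_remarks:
        m = _TEMPERATURE_RE.search(line)
        if m:
            try:
                temperature = float(m.group(1))
            except ValueError:
                pass
            break

    entry_id = st.info["_entry.id"] if "_entry.id" in st.info else ""
    cid = conformer_id or f"{(entry_id or st.name or path.stem).upper()}_{chain}"
    return ConformerStructure(
        conformer_id=cid,
        residues=residues,
        method=_experimental_method(st),
        resolution=resolution,
        temperature=temperature,
        ligands=ligands,
        sequence_length=sequence_length,
        chain_id=chain,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL", "X": "UNK",
}


def _atom_line(serial: int, name: str, resname: str, chain: str, resnum: int,
               xyz: tuple[float, float, float], element: str, het: bool = False) -> str:
    record = "HETATM" if het else "ATOM  "
    aname = name if len(name) == 4 else f" {name:<3s}"
    return (
        f"{record}{serial:5d} {aname}{'':1s}{resname:>3s} {chain}{resnum:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
    )


def write_conformer_pdb(conf: ConformerStructure, path: str | Path) -> None:
    """Write a :class:`ConformerStructure` back to PDB format.

    Emits EXPDTA / REMARK 2 / REMARK 200 metadata, REMARK 465 records for
    unobserved residues, SEQRES for the full sequence and a dummy CRYST1, so
    that re-parsing with :func:`load_conformer` round-trips residues, observed
    flags and ligand inventory.
    """
    chain = conf.chain_id
    lines: list[str] = []
    pdb_code = conf.conformer_id.split("_")[0][:4].upper().ljust(4)
    # idCode occupies columns 63-66 of the HEADER record
    lines.append("HEADER    " + "SYNTHETIC PROTEIN".ljust(40) + "01-JAN-00" + "   " + pdb_code)
    if conf.method == "xray":
        lines.append("EXPDTA    X-RAY DIFFRACTION")
    elif conf.method == "nmr":
        lines.append("EXPDTA    SOLUTION NMR")
    if conf.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION. {conf.resolution:7.2f} ANGSTROMS.")
    if conf.temperature is not None:
        lines.append(f"REMARK 200  TEMPERATURE           (KELVIN) : {conf.temperature:.0f}")
    unobserved = [r for r in conf.residues if not r.observed]
    if unobserved:
        lines.append("REMARK 465 MISSING RESIDUES")
        lines.append("REMARK 465 THE FOLLOWING RESIDUES WERE NOT LOCATED IN THE")
        lines.append("REMARK 465 EXPERIMENT.")
        lines.append("REMARK 465   M RES C SSSEQI")
        for r in unobserved:
            name3 = r.name3 or _THREE.get(r.aa, "UNK")
            lines.append(f"REMARK 465     {name3:>3s} {chain} {r.seq_pos:5d}")
    seq3 = [r.name3 or _THREE.get(r.aa, "UNK") for r in conf.residues]
    for i in range(0, len(seq3), 13):
        chunk = " ".join(f"{n:>3s}" for n in seq3[i : i + 13])
        lines.append(f"SEQRES {i // 13 + 1:3d} {chain} {len(seq3):4d}  {chunk}")
    lines.append(
        "CRYST1    1.000    1.000    1.000  90.00  90.00  90.00 P 1           1"
    )
    serial = 1
    for r in conf.residues:
        if not r.observed:
            continue
        name3 = r.name3 or _THREE.get(r.aa, "UNK")
        for a in r.atoms or []:
            lines.append(_atom_line(serial, a.name, name3, chain, r.seq_pos, a.xyz, a.element))
            serial += 1
    lines.append("TER")
    for lig in conf.ligands:
        for a in lig.atoms:
            lines.append(
                _atom_line(serial, a.name, lig.het_code, chain, lig.seq_num or 900, a.xyz, a.element, het=True)
            )
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# ensembles and filters
# ---------------------------------------------------------------------------


def build_ensemble(
    conformers: list[ConformerStructure],
    protein_id: str,
    allow_length_mismatch: bool = False,
) -> EnsembleRecord:
    """Group conformers of the same protein into an :class:`EnsembleRecord`.

    The residue correspondence is by author sequence numbering (all conformers
    of one protein share the same sequence).  Residue-identity mismatches
    between observed conformers (crystallographic mutants) are counted, not
    removed.
    """
    if not conformers:
        raise ValueError("cannot build an ensemble from an empty conformer list")
    lengths = {c.sequence_length for c in conformers}
    flags: list[str] = []
    if len(lengths) > 1:
        if not allow_length_mismatch:
            raise ValueError(
                f"{protein_id}: conformers disagree on sequence_length {sorted(lengths)}; "
                "pass allow_length_mismatch=True to accept"
            )
        flags.append(f"length_mismatch:{sorted(lengths)}")
    ids = [c.conformer_id for c in conformers]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{protein_id}: duplicate conformer ids")

    correspondence: dict[int, dict[str, int]] = {}
    aa_seen: dict[int, set[str]] = {}
    for c in conformers:
        for i, r in enumerate(c.residues):
            if not r.observed:
                continue
            correspondence.setdefault(r.seq_pos, {})[c.conformer_id] = i
            if r.aa != "X":
                aa_seen.setdefault(r.seq_pos, set()).add(r.aa)
    mutations = sorted(p for p, s in aa_seen.items() if len(s) > 1)
    return EnsembleRecord(protein_id, list(conformers), correspondence, mutations, flags)


@dataclass
class FilterOutcome:
    kept: list[EnsembleRecord]
    report: pd.DataFrame  # columns: protein_id, conformer_id, action, reason


def filter_dataset(
    ensembles: Iterable[EnsembleRecord],
    min_conformers: int = 5,
    max_resolution: float = 2.5,
    xray_only: bool = True,
) -> FilterOutcome:
    """Apply the dataset filters: method/resolution per conformer first, then
    drop ensembles left with fewer than ``min_conformers`` conformers."""
    kept: list[EnsembleRecord] = []
    rows: list[dict] = []
    for ens in ensembles:
        surviving = []
        for c in ens.conformers:
            if xray_only and c.method != "xray":
                rows.append(dict(protein_id=ens.protein_id, conformer_id=c.conformer_id,
                                 action="drop_conformer", reason=f"method={c.method}"))
                continue
            if max_resolution is not None and (
                c.resolution is None or c.resolution > max_resolution
            ):
                rows.append(dict(protein_id=ens.protein_id, conformer_id=c.conformer_id,
                                 action="drop_conformer",
                                 reason=f"resolution={c.resolution}"))
                continue
            surviving.append(c)
        if len(surviving) < min_conformers:
            rows.append(dict(protein_id=ens.protein_id, conformer_id="",
                             action="drop_ensemble",
                             reason=f"{len(surviving)}<{min_conformers} conformers"))
            continue
        if len(surviving) == len(ens.conformers):
            kept.append(ens)
        else:
            kept.append(build_ensemble(surviving, ens.protein_id, allow_length_mismatch=True))
    report = pd.DataFrame(rows, columns=["protein_id", "conformer_id", "action", "reason"])
    return FilterOutcome(kept, report)


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a delimited manifest (protein_id, pdb_code, chain_id, path)."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    required = {"protein_id", "pdb_code", "chain_id", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"manifest {path} lacks columns {sorted(missing)}")
    return df


def load_ensembles(
    manifest: pd.DataFrame, base_dir: str | Path = ".", allow_length_mismatch: bool = False
) -> list[EnsembleRecord]:
    """Load every protein of a manifest into ensembles."""
    base = Path(base_dir)
    out: list[EnsembleRecord] = []
    for protein_id, grp in manifest.groupby("protein_id", sort=True):
        confs = []
        for _, row in grp.iterrows():
            cid = f"{row['pdb_code'].upper()}_{row['chain_id']}"
            confs.append(load_conformer(base / row["path"], row["chain_id"], conformer_id=cid))
        out.append(build_ensemble(confs, str(protein_id), allow_length_mismatch))
    return out
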