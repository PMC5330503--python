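"""Worked examples on published crystal structures.

Three proteins illustrate the three mechanistic classes:

* **cel48F** (processive endo-cellulase, *C. cellulolyticum*) — rigid;
  8 conformers, maximum pairwise C-alpha RMSD about 0.21 A.
* **calmodulin** — malleable; the extended 1NIW_E vs. the compact
  trifluoperazine-bound 1LIN_A differ by about 3.2 A.
* **human thymidylate synthase** — partially disordered; 15 conformers,
  max-RMSD pair (1YPV_A, 4GD7_A) at about 1.34 A, 11 of 15 conformers with
  at least one IDR, maximum disorder percentage about 9%.

The coordinate files are not distributed with the package; fetch them with
``scripts/fetch_reference_structures.py`` (or ``confdiv fetch-acceptance``),
which downloads the entries below from the PDB into ``data/reference_pdb``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

from confdiv.disorder import detect_idrs, ensemble_disorder_summary
from confdiv.io import build_ensemble, load_conformer
from confdiv.superpose import compare_pair, max_rmsd_pair

__all__ = ["WORKED_EXAMPLE_CHAINS", "all_accessions", "worked_example_results"]

WORKED_EXAMPLE_CHAINS: dict[str, list[str]] = {
    "cel48f": [
        "1F9D_A", "1F9O_A", "1G9G_A", "1FAE_A", "1FBO_A", "1FBW_A", "1FCE_A", "2QNO_A",
    ],
    "calmodulin": [
        "1LIN_A", "1NIW_E", "3G43_A", "4DCK_B", "2FOT_A", "2X0G_B", "2BE6_A",
        "2O60_A", "1CDL_A", "3GP2_A",
    ],
    "thymidylate_synthase": [
        "1HW3_A", "1HZW_A", "1HZW_B", "1I00_A", "1I00_B", "1YPV_A", "3EDW_X",
        "3EHI_X", "3GH2_X", "3N5E_A", "3N5E_B", "3N5G_A", "4G2O_X", "4G6W_X", "4GD7_A",
    ],
}


def all_accessions() -> list[str]:
    """Distinct PDB entry codes needed by the worked examples."""
    codes = {c.split("_")[0] for chains in WORKED_EXAMPLE_CHAINS.values() for c in chains}
    return sorted(codes)


def _load_ensemble(pdb_dir: Path, protein: str, chains: Iterable[str]):
    conformers = []
    for chain_spec in chains:
        code, chain = chain_spec.split("_")
        path = pdb_dir / f"{code.lower()}.pdb"
        if not path.exists():
            path = pdb_dir / f"{code.upper()}.pdb"
        if not path.exists():
            raise FileNotFoundError(
                f"{path} not found; run scripts/fetch_reference_structures.py first"
            )
        conformers.append(load_conformer(path, chain, conformer_id=chain_spec))
    return build_ensemble(conformers, protein, allow_length_mismatch=True)


def worked_example_results(pdb_dir: str | Path) -> dict:
    """Recompute the worked-example quantities from local coordinate files."""
    pdb_dir = Path(pdb_dir)
    out: dict = {}

    cel = _load_ensemble(pdb_dir, "cel48f", WORKED_EXAMPLE_CHAINS["cel48f"])
    mp = max_rmsd_pair(cel)
    out["cel48f_max_rmsd"] = mp.rmsd
    out["cel48f_max_pair"] = mp.pair

    cam = _load_ensemble(pdb_dir, "calmodulin", WORKED_EXAMPLE_CHAINS["calmodulin"])
    out["calmodulin_1lin_1niw_rmsd"] = compare_pair(cam, "1LIN_A", "1NIW_E").rmsd

    ts = _load_ensemble(
        pdb_dir, "thymidylate_synthase", WORKED_EXAMPLE_CHAINS["thymidylate_synthase"]
    )
    ts_mp = max_rmsd_pair(ts)
    idrs = [detect_idrs(c) for c in ts.conformers]
    summary = ensemble_disorder_summary(ts, idrs)
    out["ts_max_pair"] = ts_mp.pair
    out["ts_max_rmsd"] = ts_mp.rmsd
    out["ts_n_conformers_with_idr"] = summary["n_disordered_conformers"]
    out["ts_n_conformers"] = summary["n_conformers"]
    out["ts_max_disorder_percent"] = 100.0 * summary["max_disorder_fraction"]
    return out
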