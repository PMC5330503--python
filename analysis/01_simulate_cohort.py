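#!/usr/bin/env python
"""Generate the synthetic study cohort.

Writes a cohort of 10 proteins per mechanistic class (rigid, partially
disordered, malleable) as PDB files with REMARK 465 disorder records,
plus the manifest and the ground-truth class table.  Coordinate files go
under scratch/cohort; the manifest and truth tables are copied to
results/cohort for the downstream steps.
"""
import shutil
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from confdiv.synth import generate_cohort

SEED = 2024


def main() -> int:
    cohort_dir = ROOT / "scratch" / "cohort"
    manifest, truth = generate_cohort(10, cohort_dir, seed=SEED)
    out = ROOT / "results" / "cohort"
    out.mkdir(parents=True, exist_ok=True)
    shutil.copy(manifest, out / "manifest.tsv")
    shutil.copy(truth, out / "truth.tsv")
    n_files = sum(1 for _ in cohort_dir.rglob("*.pdb"))
    print(f"wrote {n_files} conformer files for 30 proteins under {cohort_dir}")
    print(f"manifest and ground truth copied to {out}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
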