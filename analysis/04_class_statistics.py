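#!/usr/bin/env python
"""Compare the three classes and plot the max-RMSD distributions.

Reads the per-protein table from step 02, reports the Kruskal-Wallis +
Nemenyi comparisons for the headline descriptors and saves the class
summary plus a distribution figure under results/.
"""
import sys
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from confdiv.stats import kruskal_wallis_nemenyi
from confdiv.pipeline import summarize_by_class


def main() -> int:
    table = ROOT / "results" / "pipeline" / "per_protein.tsv"
    if not table.exists():
        print("per-protein table not found; run analysis/02_run_pipeline.py first",
              file=sys.stderr)
        return 2
    df = pd.read_csv(table, sep="\t")
    classes = ["rigid", "partially_disordered", "malleable"]
    groups = [df.loc[df.label == c, "max_rmsd"].to_numpy() for c in classes]
    omnibus, pmat = kruskal_wallis_nemenyi(groups, labels=classes)
    print(f"Kruskal-Wallis on max RMSD: H = {omnibus.statistic:.2f}, "
          f"p = {omnibus.p_value:.2e}")
    print("Nemenyi pairwise p-values:")
    print(pmat.round(4))

    summarize_by_class(df).to_csv(ROOT / "results" / "class_summary.tsv",
                                  sep="\t", index=False)
    fig, ax = plt.subplots(figsize=(6, 4))
    for cls in classes:
        ax.hist(df.loc[df.label == cls, "max_rmsd"], bins=15, alpha=0.5,
                label=f"{cls} (n={int((df.label == cls).sum())})")
    ax.set_xlabel("maximum C-alpha RMSD (A)")
    ax.set_ylabel("proteins")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(ROOT / "scratch" / "max_rmsd_by_class.png", dpi=150)
    print(f"summary in results/class_summary.tsv; figure in scratch/")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
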