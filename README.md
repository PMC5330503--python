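# confdiv — conformational diversity of protein structure ensembles

Redundant crystal structures of the same protein are snapshots of its native
conformational ensemble.  `confdiv` is a pipeline for analysing such
ensembles: it measures conformational diversity as the maximum pairwise
C-alpha RMSD over all conformer pairs, detects intrinsically disordered
regions (IDRs) from missing electron density, splits proteins into three
mechanistic classes, and characterises each class with backbone-dependent
and backbone-independent structural descriptors.  It is aimed at structural
bioinformaticians studying flexibility/function relationships, and ships a
synthetic-ensemble generator with known ground truth so every stage is
testable without downloading a structure.

## The quantities at the core

For a protein with conformers $c_1,\dots,c_n$, every pair is superposed by
the least-squares (Kabsch) fit on the C-alpha atoms of their common observed
positions, and the ensemble is summarised by the **max-RMSD pair**

$$\mathrm{maxRMSD} = \max_{i<j} \mathrm{RMSD}(c_i, c_j).$$

An **IDR** is a run of ≥ 5 consecutive residues with missing electron
density lying outside the first/last 20 positions of the sequence.  Where
disorder occurs relative to the max-RMSD pair defines three classes:

| class | definition |
|---|---|
| rigid | no conformer has an IDR |
| partially disordered | IDRs exist, and at least one max-pair conformer has one |
| malleable | IDRs exist, but the max-RMSD pair is fully ordered |

Descriptors per protein include the normalized radius of gyration
$R_g / \sqrt{3/5}\,(3V/4\pi)^{1/3}$ (ratio to the equal-volume sphere), the
average degree $2E/N$ of the residue contact network, grid-detected pocket
volumes with the IDR-sensitivity ratio
$|\max(pV_{1,\mathrm{IDR}},pV_{2,\mathrm{IDR}})-\max(pV_1,pV_2)|/\max(\cdot)$,
tunnel lengths with the variation $|L_1-L_2|/\max(L_1,L_2)$, hinge counts
from a rigid-segment decomposition, Shrake–Rupley solvent accessibility and
cognate-ligand inventories.  Classes are compared with Kolmogorov–Smirnov,
Wilcoxon rank-sum and Kruskal–Wallis tests (Nemenyi post-hoc).

## Worked example

```bash
python analysis/01_simulate_cohort.py
python analysis/02_run_pipeline.py
```

prints (numbers from this run):

```
analysed 30 proteins; class counts: {'malleable': 10, 'partially_disordered': 10, 'rigid': 10}
median max RMSD by class: {'malleable': 1.262, 'partially_disordered': 1.125, 'rigid': 0.785}
max-RMSD disorder predictor AUC: 1.000
```

All 30 synthetic proteins are recovered in their generated class, and the
class medians reproduce the ordering seen in real ensembles: rigid proteins
have the least conformational diversity, proteins whose flexible regions are
usually disordered sit in the middle, and proteins whose flexible regions
appear ordered in different arrangements (malleable) have the most.  The
AUC of max RMSD as a protein-level disorder predictor is 1.0 here because
the synthetic classes are cleanly separated; on real data the separation is
far weaker.  `analysis/03_composition_profile.py` and
`analysis/04_class_statistics.py` continue with IDR composition profiles
and the Kruskal–Wallis/Nemenyi class comparisons;
`analysis/05_worked_examples.py` recomputes the published-structure
examples (cel48F, calmodulin, thymidylate synthase) once the reference
entries are fetched.

The same functionality is available as a CLI
(`confdiv generate | run | report | fetch-acceptance`).

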