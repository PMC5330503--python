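# Methods

## Scope and data model

`confdiv` analyses ensembles of crystallographic structures of the same
protein chain.  A conformer is one chain of one PDB entry, parsed with
gemmi into a residue list that covers the *full* deposited sequence:
residues without coordinates are kept as unobserved records, recovered
from the union of REMARK 465 records and numbering gaps against SEQRES.
Sequence positions follow the author numbering (rebased only when it dips
below 1), because conformers of the same protein are deposited with a
shared numbering scheme; correspondence between conformers is therefore a
join on position, not a structural alignment.  When SEQRES is absent, the
sequence length is the span of the author numbering; when SEQRES is longer
than the numbered span it is assumed head-aligned at the first numbered
residue.  Alternate locations are resolved to the highest-occupancy
conformation (ties to altloc 'A').  Crystallographic mutants are counted
per position and flagged, not removed: a mutated side chain still has a
C-alpha, and dropping such conformers is left to the caller.

Dataset filters mirror the standard curation of conformational-diversity
sets: X-ray entries only, resolution ≤ 2.5 Å, and at least 5 conformers
per protein after the per-conformer filters.

## Superposition and RMSD

Pairwise superposition is the least-squares rigid fit computed by SVD of
the cross-covariance matrix with the determinant correction that keeps the
rotation proper (the Kabsch algorithm).  RMSD is computed on C-alpha atoms
over the pairwise intersection of observed positions, and the fit is
performed on exactly the position set on which the RMSD is reported; no
core-trimming is applied.  The alternative convention (fit on a trimmed
core, report on all) exists in the literature, but fitting and reporting
on the same set is the simplest defensible reading and is what the
position-restricted variants (loop-only RMSD, IDR-union-excluded RMSD)
require anyway.  The test suite pins the implementation to an independent
Horn-quaternion oracle (largest eigenvalue of the 4×4 key matrix) to
1e-8 Å on 1,000 random instances.

Max-RMSD pair ties are broken lexicographically by conformer id, so runs
are deterministic.  The per-position profile is the root mean square of
per-position deviations over all pairs in which the position is common,
after each pair's global superposition.

## Intrinsic disorder

A residue missing from the electron density of an X-ray structure is
treated as disordered.  An IDR is a maximal run of ≥ 5 consecutive missing
residues lying outside the 20-residue terminal windows, which are excluded
because unresolved termini are common for reasons unrelated to intrinsic
disorder (tags, entropic fraying).  A run that straddles a terminal window
is truncated to its interior portion and re-tested against the ≥ 5
threshold (`terminal_run_policy="truncate"`); discarding such runs whole
is available as `"discard"`.  Truncation is the default because it keeps
the rule local and monotone: adding observations near a terminus can only
shrink an IDR, never create one.

The disorder fraction of a conformer divides the summed IDR length by the
full deposited sequence length; normalizing by the observed length instead
is a config switch (`fraction_denominator="observed"`).  Ensemble
summaries report the percentage of conformers with ≥ 1 IDR, the maximum
disorder fraction, the longest IDR and the number of order/disorder
transition positions (inside an IDR in ≥ 1 conformer and observed in
≥ 1 conformer).

Composition profiles compare the amino-acid frequencies of a residue set
against a fixed reference composition as (f_query − f_ref)/f_ref, with a
percentile bootstrap CI (default 10,000 iterations, 95%) obtained by
multinomial resampling of the query; the reference is treated as fixed.
The two shipped reference tables are *synthetic stand-ins* (labelled so in
their filenames) with the qualitative features of disordered-protein and
crystallizable-protein compositions; real analyses should supply their own
two-column (aa, frequency) tables.

## Classification

The three classes are a deterministic function of the IDR evidence: rigid
(no conformer has an IDR), partially disordered (IDRs exist and at least
one conformer of the max-RMSD pair has one), malleable (IDRs exist but the
max-RMSD pair is fully ordered).  "In the max pair" means at least one of
the two conformers has ≥ 1 IDR anywhere in its sequence.  The labels are
mutually exclusive and exhaustive by construction, which the suite
property-tests on random evidence patterns.

Max RMSD as a protein-level disorder predictor is evaluated with the rank
statistic AUC (Mann–Whitney U/(n₁n₀), ties half credit), accuracy at fixed
cutoffs (disordered iff max RMSD > c), and a logistic regression fitted by
IRLS with a Wald p-value, flagging perfect separation.  Enrichment above a
cutoff is reported in two forms, because the arithmetic is ambiguous in
common usage: the odds-ratio form ((D>c)/(D≤c)) / ((O>c)/(O≤c)) and the
raw count form (D>c)/(D≤c) over the disordered proteins alone.

## Structural descriptors

Descriptors are evaluated on the two conformers of the max-RMSD pair
(ligand statistics use the whole ensemble), since that pair is the
ensemble's summary of conformational diversity.

**Secondary structure** is assigned from C-alpha geometry with P-SEA-style
distance/angle windows (biotite's implementation); H/E/C only.

**Protein volume** is grid-estimated (probe 0.5 Å, grid 1.5 Å): voxels
whose centre lies within vdW+probe of any atom.  The **normalized radius
of gyration** divides the heavy-atom Rg (uniform masses) by the Rg of the
equal-volume uniform sphere, √(3/5)·(3V/4π)^{1/3}; 1 ≈ spherical, larger
means elongated or loosely packed.

**Residue contact networks** connect observed residues with any heavy-atom
pair within 5.0 Å and sequence separation ≥ 2 (both configurable; reported
as the package's own convention since reference tools do not print
theirs); the average degree is 2E/N.

**Pockets** use a two-probe grid method (1.0 Å grid): pocket voxels are
accessible to a water-sized 1.4 Å probe but not swept by a 4.0 Å probe
rolling in from bulk solvent (bulk = boundary-connected large-probe-
feasible space dilated by the large-probe radius).  6-connected clusters
are reported with volume (voxel count × 1 Å³), mouth exposure (fraction of
pocket voxels adjacent to bulk) and lining residues.  Fully enclosed
cavities count as pockets.  This is deliberately a simple, fully specified
method, not a reimplementation of Voronoi/alpha-sphere pocket software;
validation is against analytic geometry (a 5×5×5 Å cavity is recovered at
125 Å³ within grid error, convex bodies yield ≤ 30 Å³ of noise).
The pocket-IDR variation |max(pV₁,IDR, pV₂,IDR) − max(pV₁,pV₂)| / max(both)
contrasts the largest pocket volume before and after removing IDR-union
residues from the structure.

**Tunnels** are found on a clearance field (distance to the nearest atom
surface, 1.0 Å grid).  Bulk solvent is the boundary-connected region with
clearance ≥ the 3 Å origin radius, swept inward by that radius.  The
start point is the deepest buried voxel (clearance capped at 3 Å, ties by
distance from bulk).  A widest-bottleneck (best-first) path is traced from
the start to bulk over voxels with clearance ≥ the 1.25 Å interior
threshold; when a second, voxel-disjoint path exits in another direction
the two are merged into a single through-tunnel, so an open channel
crossing a slab is one tunnel of full axial length rather than two
half-tunnels.  Length is measured over the buried portion of the path;
tunnels shorter than 5 Å are dropped.  Lining residues lie within
(bottleneck + 3 Å) of the path.  The printed reference parameters (3 Å
probe/origin radius, 1.25 Å interior threshold) are honoured; everything
else is this package's own, documented semantics.  Tunnel-length variation
is |L₁−L₂|/max(L₁,L₂) over the pair's longest tunnels, and the tunnel
ratio normalizes the longest tunnel by the conformer's residue count
(chain Å-length is the config alternative).

**Hinges** come from a dynamic-programming rigid-segment decomposition of
the max pair: the minimal number of breakpoints such that every contiguous
segment of ≥ 15 common positions superposes within 1.5 Å RMSD (both
configurable; the values are this package's defaults, chosen as typical
domain-motion scales).  Segment RMSDs are O(1) via prefix sums of the
cross-covariance.  Among minimal decompositions the one with the smallest
total squared error is returned, which pins breakpoints to the actual
hinge sites (validated within ±2 residues on constructed two- and
three-domain ensembles, and against exhaustive enumeration for ≤ 2
breakpoints).  Failure to decompose with ≤ 10 breakpoints saturates the
count at 10 and flags the protein.

**Solvent accessibility** is Shrake–Rupley with a deterministic Fibonacci-
spiral point set (960 points, 1.4 Å probe), so results are reproducible
bit for bit; the isolated-sphere area is exact to ≪ 1%.

**Ligands** are non-water HETATM groups; a group with ≥ 6 heavy atoms
(configurable) counts as a cognate ligand for apo/holo calls, which
separates substrates and drugs from ions and buffer components.
Molecular weight sums the atomic weights of the atoms present in the file.
"Pocket density" style solvent-exposure readouts are available via the
pocket mouth-exposure fraction and per-atom SASA.

## Statistics

KS, rank-sum (Mann–Whitney) and Kruskal–Wallis wrap scipy with explicit
small-sample policies: exact KS when n·m ≤ 10,000, exact Mann–Whitney when
n+m ≤ 20 without ties, tie-corrected asymptotics otherwise; all p-values
two-sided.  The Nemenyi post-hoc uses the studentized-range convention on
mean ranks (q = Δ/√((N(N+1)/24)(1/nᵢ+1/nⱼ)), ∞ df); the chi-square variant
with tie correction is a flag.  Type-I error calibration in the suite uses
group sizes 40/45/50: with equal sizes the exact KS statistic's attainable
set is coarse and the discrete test's true size falls visibly below the
nominal 0.05, while unequal sizes densify the attainable set and restore a
size near nominal — a property of the test, accounted for in the
simulation design.

## The synthetic-ensemble generator

Each synthetic protein is a three-helix bundle (ideal helix parameters:
2.3 Å radius, 1.5 Å rise, 100°/residue; 4-residue linkers) of 110 residues
with C-alpha and C-beta-placeholder atoms, or a self-avoiding random walk
for degenerate-geometry tests.  Conformers apply, in order: an optional
hinge rotation, the class-specific flexible-segment mechanism, isotropic
thermal jitter (0.3 Å per coordinate, matching the ~0.4 Å reproducibility
floor of crystallographic ensembles), and a random rigid-body motion.
X-ray metadata (resolution U(1.2, 2.3) Å, 100 K) is written so the dataset
filters pass; unobserved residues are written as REMARK 465 records.

The class mechanisms mirror how disorder couples to diversity in real
ensembles.  Partially disordered proteins have an interior 15-residue
flexible segment unobserved in 70% of conformers (the observed regime for
this class, ~69% disordered conformers), and conformers in the disordered
state also displace a second, ordered 15-residue segment (amplitude
1.7 Å) — order/disorder transitions perturb the folded part, so the
max-RMSD pair contains a disordered conformer.  Malleable proteins have
the segment unobserved in only 25% of conformers (~25% observed for the
class) and, when observed, it adopts one of two opposed arrangements
(amplitude 2.0 Å), so the max pair is a fully ordered pair.  Amplitudes
were set so the cohort reproduces the reported per-class max-RMSD scale
(medians ≈ 0.8 / 1.1 / 1.3 Å for rigid / partially disordered /
malleable).  Small ensembles are stratified (one conformer forced
disordered for partially disordered; two opposed ordered arrangements and
one disordered conformer forced for malleable) so that an 8-conformer
ensemble realises its class with certainty rather than in expectation.
Generation is deterministic given the seed, to the point of byte-identical
PDB files.

What the generator does **not** emulate: side chains beyond C-beta
placeholders, real packing density (pocket/tunnel statistics on synthetic
bundles are not calibrated to real proteins), crystal contacts, sequence-
dependent disorder composition, and correlated backbone motions.  Passing
tests therefore demonstrate correctness of the measurement pipeline on
known ground truth, not that real proteins behave like the generator.

## Validation problem sizes

The suite validates classification on 300 default-spec ensembles (100 per
class), the superposition oracle on 1,000 random instances, null
calibration on 2,000 replicates per test, and bootstrap coverage on
20 × 20 CIs; `scripts/acceptance.py` re-runs the same battery from
scratch (~10 s).  The worked examples on published ensembles (cel48F,
calmodulin, thymidylate synthase; 25 PDB entries) run once the coordinate
files are fetched with `scripts/fetch_reference_structures.py`.

## Known limitations

* Residue correspondence trusts author numbering; entries that renumber a
  construct will misalign and must be fixed upstream.  Insertion codes are
  flagged but folded onto their base number.
* The pocket and tunnel detectors are grid methods with ~1 grid-unit
  discretization error and deliberately simplified semantics; absolute
  volumes/lengths are comparable within this package only.
* Dataset-scale published statistics (class means over thousands of
  proteins, predictor AUC ≈ 0.67) depend on the full curated corpus and
  are reproduced here only as qualitative orderings on synthetic cohorts.
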