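# Methods

This document describes what each stage of the workflow computes, the
numerical conventions chosen where a contract leaves room, and the scope
and known limitations of the desk-scale synthetic evaluation.

## 1. Dataset model and cleaning (`pdb_model`)

A structure is decomposed into polymer chains (ATOM records of amino-acid
residues; altloc '' or 'A' only; waters discarded). Every non-water hetero
group becomes a candidate ligand and is attached to the chain whose
C-alpha trace it is nearest to; the originating `structure_chain` is kept
on the ligand so the merge manifest can report where each ligand came
from.

Cleaning keeps chains with ≥ 28 residues, and ligands with ≥ 7 heavy atoms
whose minimum distance to the chain's C-alpha atoms is ≤ 5 Å (both bounds
inclusive).

## 2. Sequence clustering (`seq_cluster`)

All chain pairs are aligned with a Gotoh affine-gap Smith–Waterman dynamic
program over BLOSUM62. Conventions:

- a gap run of length L costs `open + (L−1)·extend`, defaults 11/1;
- tie-breaking is deterministic (diagonal > up > left; first maximum in
  row-major order), and pairs are ordered lexicographically before
  alignment so the measure is symmetric;
- similarity S = identical columns / alignment length; covering of each
  sequence = aligned span / sequence length.

Chains are joined when S > 0.8 and both coverings > 0.9 (all strict);
clusters are connected components of that graph. Correctness is anchored
in the tests by an independent oracle: recursive enumeration of all local
alignments for short sequences.

## 3. Ligand merging (`ligand_merge`)

Within a cluster, chains are sorted by ligand information (ligand count,
then total ligand atoms). A representative is accepted when it superposes
(Kabsch least-squares over the C-alpha pairs matched by the alignment,
gated at similarity > 0.9 and coverings > 0.9) with RMSD < 2 Å onto at
least half of the remaining chains. Ligands of well-fitting chains are
transplanted unless they clash with a kept ligand or the chain (heavy-atom
pair < 1.5 Å) or end farther than 5 Å from the C-alpha trace. Unmergeable
chains restart the procedure as a fresh cluster, so every chain ends as a
representative or merged away. Representative coordinates are never
modified and each source ligand is used at most once.

## 4. Featurization (`featurize`)

Atoms receive AutoDock-style type codes from residue templates (proteins)
or perceived bonds/planar rings (ligands), mapping to eight boolean
channels: hydrophobic, aromatic, acceptor, donor, positive, negative,
metal, excluded volume (the last set for every atom). The influence of an
atom at distance d is the occupancy

    occ(d) = 1 − exp(−(r_vdw / d)^12)

which falls below the ligandability threshold 1e−4 at ≈ 2.154 r_vdw
("about twice the atom's radius"). A property grid is an 8 × 19³ cube of
per-channel maxima of occupancy, 1 Å spacing, centered on a surface point;
grids are translation-equivariant by construction.

Surface points are a solvent-accessible dot surface: icosphere vertices on
each heavy atom's expanded sphere (r_vdw + 1.4 Å) with points buried in
any other expanded sphere removed. A point is labeled ligandable when some
retained ligand's excluded-volume occupancy exceeds 1e−4 there (strict).

## 5. Classifier (`cnn_model`, `nn`)

The classifier maps a property cube to two-class probabilities. The layer
stack is four 3³ convolutions with ReLU + batch normalization, 2× max
pooling after the second and fourth, dropout, then dense layers. Because
no GPU framework is assumed, the layers are implemented directly on NumPy
(float32) with manual backprop; 3D convolution is evaluated as 27 shifted
BLAS matrix products over views of the padded volume, verified in the
tests against explicit-loop oracles and finite differences.

Training is cluster-aware: a batch draws `nc` clusters, one chain per
cluster and `np` surface points per chain, with ligandable points
oversampled to equal expected class proportion. Optimization is Adam under
a one-cycle learning-rate schedule (warmup fraction 0.3, start divisor 25,
final divisor 1000). Batch-norm running statistics use momentum 0.8 —
with only a few hundred optimizer steps, a slowly-updating running mean
(e.g. momentum 0.99) would still be far from the activation statistics at
evaluation time, and inference quality collapses. Cross-validation splits
are made at cluster granularity: the tests assert that no cluster ever
straddles train/validation/test and that the ten test sets partition the
cluster universe.

## 6. Site grouping (`site_grouping`)

True sites in a reference collection are summarized by three statistics:
point count, mean distance of member points to the site center, and the
standard deviation of that distance. Their empirical 10th/90th percentiles
(linear interpolation) bound what a predicted site may look like; a
candidate is admitted when all three statistics lie inside the bounds
(inclusive).

Prediction grouping iterates: threshold the scores at c (strict >),
cluster selected points into connected components of the strict 4 Å
neighbor graph, admit components that fit the bounds and remove their
points, then move c inside a shrinking interval (a, b) with
`a ← 0.2(b−a)+a` ("increase a") or `b ← 0.2(a−b)+b` ("decrease b") and
`c = (a+b)/2`, starting from (0.3, 1.0, 0.5). The decision ladder checks,
in order: iteration cap (20), clustered fraction > 0.2, empty selection,
then the size/avg-distance/std-distance bounds. The printed form of the
avg-distance upper branch repeats "<", which would shadow the lower
branch; the implementation applies the symmetric reading (`> upper bound →
increase a`) behind a default-on flag (`fix_avg_distance_branch`), with
the literal transcription available for comparison.

## 7. Evaluation (`evaluation`)

Site level: DCC is the distance between geometric centers of the predicted
and true site's points; DVO is intersection over union of the two point
index sets (raw point sets, not convex hulls — both sites must live on the
same point universe). Each true site above a size bound is paired with the
nearest predicted site by DCC; "all", "best per chain", and "DVO > 0"
groupings are summarized, and a site counts as recovered at DCC ≤ 4 Å.
Point level: confusion-matrix metrics at thresholds {0.3, 0.5, 0.7, 0.9}
(a point is called ligandable when strictly above t), MCC = 0 for
degenerate matrices, plus the threshold-free mean cross-entropy.

## 8. Synthetic fixtures and the desk-scale run

`synthetic_fixtures` generates toy chains: a compact self-avoiding
C-alpha walk (3.8 Å steps) decorated with backbone and side-chain
pseudo-atoms. Pockets are created by placing a rigid ligand (ring, blob or
chain shaped) at a surface anchor within 5 Å of the C-alpha trace and then
carving away carvable side-chain atoms within a margin of the ligand
atoms, so the cavity is complementary to the planted ligand. Generators
are pure functions of their spec and seed.

`pipeline.run_pipeline(seed)` exercises the full chain at desk scale:
3 chains of 40 residues with 2 pockets each (plus one duplicate chain
carrying a ligand subset so clustering/merging do real work), coarse dot
surfaces (tessellation level 1) thinned on a deterministic 1.7 Å voxel
grid to ≤ 1400 points, a narrow network (4, 4, 8, 8 / 16, 2), 5 epochs of
64 clusters, peak learning rate 3e−3. Training and prediction use the
same chains: at this scale the contract is memorization capacity plus
correct site recovery, not held-out generalization.

Site-shape statistics are deliberately computed over a **wider**
population than the evaluated chains: ten extra statistics-only chains
carry small blobs, long chains and mid-size rings. Percentile bands
estimated from a narrow population reject at their own edges by
construction (a [10th, 90th] band excludes ~20% of the very population it
was fitted on, per statistic); bands from a diverse population comfortably
admit typical sites of the evaluated family. This mirrors computing
statistics over a diverse reference corpus and should be kept in mind when
supplying custom `--stats` bounds to `catsite sites`.

Across ten seeded desk-scale runs, 85% of planted sites are recovered with
DCC ≤ 4 Å (60 sites total; most misses are grouping-band rejections on
low-contrast pockets). One run takes 1–2 minutes on one CPU.

## Known limitations

- The toy geometry is not physically realistic (no rotamers, no
  energetics); it satisfies the structural contracts only.
- The NumPy network is CPU-bound and sized for desk-scale problems, not
  for corpus-scale training.
- Ligand bond/aromaticity perception is distance-based and template-free;
  exotic chemistry falls back to excluded-volume-only typing.
- `catsite evaluate` reconstructs true sites as connected components of
  the labeled points in the predictions file; when ligand identities are
  needed per site, evaluate through the Python API instead.
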