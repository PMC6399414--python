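# Methods

This note documents the models, numerical choices and limitations of
`epibind` at the level of detail a maintainer or reviewer needs. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Structural preprocessing

**Parsing.** PDB files are read through Bio.PDB. Only heavy atoms of standard
amino acids are kept: hydrogens/deuteriums, waters and HETATM ligands are
dropped; selenomethionine (MSE) is mapped to methionine; other modified
residues are dropped with a warning. For alternate locations the
highest-occupancy conformer is kept, ties broken alphabetically by altloc
identifier. Multi-MODEL files use the first model. Residues are identified by
(chain, residue number, insertion code) with PDB numbering preserved.

**Solvent accessibility.** Per-atom SASA uses the Shrake–Rupley rolling-probe
construction: 960 Fibonacci-lattice test points per atom, probe radius
1.4 Å, van der Waals radii C 1.70 / N 1.55 / O 1.52 / S 1.80 / Se 1.90 Å
(others default to 1.70 Å). The implementation is validated against the
analytic area of a free sphere, the two-sphere spherical-cap occlusion, and
Bio.PDB's independent implementation. Absolute areas from different SASA
engines agree only to a few percent; all *thresholds* in the package
(exposure at 2.5 Å²) are interpreted with this implementation.

**Exposure context.** Whether exposure should be computed on each molecule in
isolation or on the assembled complex is genuinely open: interface residues
are buried *in the complex*, yet they must count as exposed for the epitope
definition to be non-empty. The default (`context="isolated"`) removes the
partner before computing SASA; `context="complex"` is available as a switch.
All defaults in the package assume the isolated convention.

**Thresholds.** Contact: heavy-atom distance strictly < 4.0 Å. Exposure:
max per-atom SASA strictly > 2.5 Å². Surface neighbors: minimal heavy-atom
distance ≤ 6.0 Å (inclusive), anchored on heavy atoms for consistency with
the contact rule. Strict-versus-inclusive choices are exercised by tests at
the exact boundary values.

## Patch descriptors

A patch is a set of exposed residues on one molecule. Its descriptor blocks:

* **Amino-acid composition** — 20 frequencies over the alphabet
  `ACDEFGHIKLMNPQRSTVWY`; sums to 1.
* **Exposed donors/acceptors** — counts of hydrogen-bond donor and acceptor
  atoms among patch residues whose own SASA exceeds 2.5 Å², regardless of
  actual bonding. Chemistry table: backbone N donor (all residues), backbone
  O/OXT acceptor; S/T/Y hydroxyls both roles; K/R/W/N/Q side-chain N donors;
  D/E/N/Q side-chain O acceptors; His ND1/NE2 both roles. Proline's backbone
  N is counted like any other — a deliberate simplification of the table.
* **Hydrophobicity score** — number of exposed patch carbons whose minimal
  distance to *every* exposed donor/acceptor atom of the molecule exceeds
  2.5 Å (strict).
* **Aromatic / positive / negative** — residue counts with aromatic =
  {F, W, Y, H}, positive = {R, K, H}, negative = {D, E}.
* **Principal components** — the three square-rooted eigenvalues of the
  population covariance of the patch Cα coordinates, sorted descending.
  These are axis dispersions (Å), suitable as size/shape scalars and as the
  ratio features of the Monte Carlo energy. Patches with fewer than three
  residues report zeros beyond the rank of the cloud.
* **Size and density** — residue count, and the mean number of in-patch
  surface-graph neighbors per patch residue.
* **RSA max/min/mean** — residue SASA divided by the Tien et al. theoretical
  maximum ASA for the residue type, clipped to [0, 1.2]; antigen side only.
* **Structural conjoint triads** — for each patch residue X and each
  unordered pair of distinct in-patch neighbors {N1, N2}, the triple
  [C(N1), C(X), C(N2)] is tallied under the 7-class alphabet {A,G,V},
  {I,L,F,P}, {Y,M,T,S}, {H,N,Q,W}, {R,K}, {D,E}, {C}; flanks unordered,
  7 × 28 = 196 types, normalized to frequencies (all-zero when no residue
  has two in-patch neighbors).
* **3D Zernike descriptors** — seven rotation invariants F_nl for
  (n,l) ∈ {(2,0),(2,2),(3,1),(3,3),(4,0),(4,2),(4,4)}, i.e. orders 2–4
  excluding the trivial 0th/1st. The shape function is the convex-hull
  region of the patch's heavy atoms, translated to the hull centroid and
  scaled so the farthest atom sits at radius 0.95 of the unit ball, then
  voxelized on a 48³ grid. Interior voxels count fully; boundary-band
  voxels are anti-aliased by 2×2×2 subsampling against the hull planes.
  Moments are integrated numerically with orthonormal radial polynomials
  R_nl(r) = √(2n+3) · r^l · P_k^(0, l+1/2)(2r² − 1) and spherical harmonics;
  F_nl is the norm over m. Using the hull region (rather than fixed-radius
  atom spheres) makes the descriptors exactly scale-invariant after the
  unit-ball normalization; translation invariance is exact, and rotation
  invariance holds to voxelization accuracy (verified in tests to 1e-3
  relative to the largest descriptor — the smallest components are near
  zero, where componentwise relative error is ill-conditioned). The moment
  engine itself is validated against 1D radial quadrature on spherically
  symmetric occupancies and against the parity argument (odd-order
  invariants vanish for centrosymmetric shapes).

**Layouts.** Antigen block: 20+2+1+3+3+1+1+3+196+7 = 237. Paratope block:
the same without the three RSA statistics = 234. Full = 471; Minimal = the
first seven groups per side, 31 + 31 = 62. Column order is fixed and
published by `feature_names()`.

## Monte Carlo patch generation

Energy: E = Σ ((X_i − X̄_i)/σ_i)² over six ratio features — PC1, PC2, PC3
and size as patch:paratope, summed residue SASA as patch:paratope, and
density as paratope:patch (the stated orientation; kept literally and
recorded in configuration). σ is floored at 1e-6. A single-residue patch has
density 0, so the patch density is floored at 1e-3 before the ratio; this
keeps the energy finite and steers the sampler away from degenerate patches.
A paratope with zero size, dispersion or surface is rejected with an error.

Moves: add a residue adjacent to the patch, remove a patch residue (illegal
at size 1), or swap one for a neighbor; the move type is chosen uniformly
among the legal subset (the proportions are a design choice). ΔE is computed
by full re-evaluation on the proposed patch — patches are small and
correctness is easier to audit than incremental caching. Acceptance follows
min(exp(−ΔE/T), 1); the temperature is multiplied by the cooling factor
after *every* step, accepted or not. Defaults: T₀ = 20, factor 0.985, 500
steps (final T ≈ 0.01045), 300 independent simulations per antigen, each
started from a uniformly random exposed residue with a sub-seed derived from
the run seed. Patch connectivity is not enforced; removals may disconnect a
patch. Energy statistics are fitted on real epitope-paratope pairs
excluding the held-out cross-validation partition.

`EnergyStats.default()` (all ratio means 1, σ 0.25) is an uninformed prior
for single-complex CLI runs, where cross-validated fitting is impossible; it
is not used in any benchmark.

## Training set

Targets are precision × recall of the patch residue set against the true
epitope (1 for a perfect match, 0 for disjoint). Per complex: the real pair
(target 1); up to 10 patches with target > 0.0075, Hobohm-1 reduced at < 60%
overlap after sorting by target; up to 50 patches with target ≤ 0.0075,
reduced in input order (unsorted); and 10 mis-pairs — the real epitope with
paratopes drawn without replacement from other *antibody clusters* (target
0). The Hobohm overlap fraction uses the candidate patch's size as the
denominator (configurable: candidate | smaller | union). Mis-paired examples
keep the real epitope's antigen block and substitute the foreign paratope
block.

Clustering utilities: a greedy length-sorted identity clusterer (global
alignment identity = matches / alignment length, via Bio.Align) stands in
for external clustering tools; users can supply precomputed cluster labels
instead. Antibody and antigen clusters are merged by union-find, and merged
clusters are assigned to partitions intact, so no cluster ever spans two
partitions (validated by `PartitionScheme.validate`).

## Scorer

Two hidden layers of 25 sigmoid units and one sigmoid output, trained with
Adam (step 1e-3, β₁ 0.9, β₂ 0.999), batch size 32, early stopping with
patience 10 on validation loss, at most 500 epochs. The default loss is
binary cross-entropy against the continuous target in [0, 1] (well-defined
for fractional targets and matching the sigmoid output); squared error is
available by configuration. Inputs are z-scored with parameters fitted on
each member's training folds only. Nested cross-validation: for each outer
partition, the remaining partitions' examples are split into 10
sub-partitions along cluster boundaries; each of 10 members early-stops on
its own sub-partition, and the ensemble mean scores the held-out partition.
Weight initialization is Glorot-uniform from a seeded generator, so training
is reproducible; shuffling the held-out partition's targets provably leaves
the ensemble's weights unchanged (tested bit-for-bit).

The network is implemented directly on numpy arrays; it is a ~200-line
component whose training dynamics (loss, early stopping, seeding) are fully
under the package's control and unit-tested.

## Ranking

F_rank of a target among decoys = (#higher + ½·#ties) / #decoys; ties take
half credit by default (a strict mode is available). It is invariant under
monotone transforms of all scores, 0 for a perfect prediction and 0.5 in
expectation under exchangeable random scores (verified to ±0.02 over 1000
replicates). Epitope ranking scores the real pair against the antigen's MC
patches; the First-HO rank reports the best-scoring patch with overlap
target > 0.25 and is missing when none was generated. Pairing benchmarks
rank the true paratope (or epitope) among candidates from other merged
clusters; the "structurally similar" variants first cluster paratopes by
their PC vector (K-means, k = 5, 10 restarts, seeded) and rank within the
query's cluster, skipping singleton clusters; the Monte Carlo variants score
each candidate by the mean of its top-5 MC patch predictions. A
residue-score → patch-score adapter (sum over patch residues) lets
residue-level predictors be compared on the same patch ranking, and a greedy
reduction drops any patch sharing ≥ 35% of its residues with a
better-scoring kept patch, for comparisons against docking tools that emit
~30 poses.

## Synthetic pseudo-complexes

`synthfix` builds two hollow Fibonacci-lattice shells of 5-heavy-atom
pseudo-residues (N, CA, C, O, CB with approximate backbone offsets; CB
points outward, O is tucked inward) separated by a 10 Å gap, with Gaussian
positional jitter (0.15 Å). The planted interface pulls the residues nearest
the partner onto a ring between the shells; epitope and paratope may have
different residue counts (slots are paired cyclically), each side receives
an independent lateral jitter, and the CB–CB contact distance is solved to
land in 3.2–3.7 Å, while every other cross-chain atom pair stays above 6 Å.
Ground truth is therefore exact by construction and is audited by
brute-force distance checks in the tests. Interface residues draw their
identities from an aromatic/charged-biased composition (W 0.30, Y 0.25,
R 0.25, F 0.20), mimicking the enrichment of real antibody interfaces and
planting a learnable compositional signal; non-interface residues are
uniform over the 20 amino acids.

**What the fixtures do and do not show.** They exercise every pipeline stage
with exact ground truth: parsing, SASA, interface extraction, graph
construction, featurization, MC sampling, banding, leak-free training and
ranking. They are *not* physically realistic proteins: no side chains beyond
CB, no packing, no sequence continuity, and a deliberately strong
composition signal. Passing the synthetic benchmark demonstrates the
machinery is correct and that the learning pipeline can recover a planted
paratope-epitope association; it does not estimate performance on real
antibody-antigen structures, which requires training on solved complexes.

## Desk-scale study conditions

The benchmark in the acceptance tests uses 20 pseudo-complexes with
per-complex sizes drawn once from realistic ranges (antigen 50–70 residues,
antibody 36–50, epitope 6–12 with the paratope differing by up to ±2) so the
cross-complex ratio statistics have genuine variance, 100 MC patches per
antigen for the cross-validated training (the 300-patch default is verified
on one complex), and the default network settings. At these sizes the whole
benchmark trains 50 networks and featurizes ~2,000 patches in a few minutes
on one CPU. Pilot runs at these conditions put the mean annealed patch size
at 0.5–0.75 of the paratope size (the curvature of the shell penalizes
large flat patches through the PC3 ratio); the size-tracking test asserts
the pilot-derived band 0.35–1.1.

## Known limitations

* Absolute SASA values are implementation-specific; only the in-package
  thresholds are calibrated.
* The Zernike rotation invariance is exact only in the continuum; at 48³
  voxels the near-zero odd invariants carry relative voxelization noise.
* The greedy identity clusterer is a convenience, not a replacement for
  dedicated sequence-clustering tools at scale.
* `density_ratio` orientation (paratope:patch) follows the stated definition
  even though the other five ratios run patch:paratope; flipping it is a
  one-line configuration change recorded in the energy-feature table.
* mmCIF, biological-assembly reconstruction, antibody chain auto-detection
  and structure repair are out of scope; chain roles must be declared.
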