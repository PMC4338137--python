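# Methods

`pocketeer` models how small-molecule selectivity across a protein family
can be explained by the surface pockets each family member's conformational
ensemble can present, rather than by the pockets visible in any single
structure.  The pipeline has five computational stages; this note records
the model behind each stage, the parameters that matter, and the design
choices made where the design was genuinely open.

## 1. Pocket detection (Ligsite-style grid scanning)

Detection is local: a cubic grid (default edge 24 Å, spacing 0.5 Å) is
centered at the unit-mass center of mass of one or two *target residues*.
Grid points within the van der Waals radius of any protein atom are labeled
`protein`, the rest `solvent`.  Along seven lattice directions (the three
axes and four body diagonals — the classic Ligsite scan set), maximal runs
of solvent points bounded by protein at both ends mark their points as
`pocket`; a point qualifies when it is bounded in at least
`min_bounded_directions` directions (default 1).  Because only
protein/solvent labels exist at that stage, "lies on a protein-bounded run"
is equivalent to "has a protein point somewhere on each side along the scan
line", which is what the vectorized implementation computes by logarithmic
shift-propagation; an independent per-line two-pointer scan is the test
oracle.

The **deep pocket volume** — the druggability-relevant observable — is the
set of pocket points strictly more than the burial distance (2.5 Å,
Euclidean point-center distance) from every remaining solvent point,
computed with an exact Euclidean distance transform.  Pocket points are
clustered under 26-neighbor adjacency, and clusters with no point within
(atom vdW radius + 1.0 Å) of a target-residue atom are discarded; the 1.0 Å
margin is one grid shell and is configurable.  Volumes are point counts ×
spacing³.

vdW radii come from a conventional element table (C 1.70, N 1.55, O 1.52,
S 1.80, H 1.09, default 1.80 Å).  Grid spacing defaults to 0.5 Å for
analysis; the sampler uses 1.0 Å (below) to trade volume quantization for
speed.

## 2. Target-residue selection

When the pocket should sit at a protein–protein interface, the anchor pair
is chosen from a per-residue binding-energy table (ΔΔGres, e.g. computed
alanine scanning from an external server; this package only consumes the
table).  Every unordered pair of listed residues is scored by centering a
candidate cube (edge 24 Å) at the pair's center of mass and summing ΔΔGres
over residues with any atom inside the cube.  The full ranking (descending
captured ΔΔG, ties by lexicographic residue id) is returned, since the
second-best pair is occasionally the useful anchor.  Negative ΔΔG entries
count as-is by default; a clipping flag exists.

## 3. Exemplars

An exemplar is the "perfect ligand" of a pocket: a bond-free set of typed
pseudo-atoms (donor / acceptor / hydrophobe).

* **Polar probes.** For every protein H-bond donor (acceptor) whose
  idealized partner position — 2.9 Å along the group's direction — falls
  within one grid spacing of pocket volume, a complementary acceptor
  (donor) probe is placed there.  Donor directions use the explicit amide H
  when present, otherwise idealized bonded-neighbor geometry; acceptor
  lone pairs collapse to the bond-extension direction.  Probes may occupy
  any pocket volume (not only deep), reading the placement rule literally;
  hydrophobes are restricted to deep volume.
* **Hydrophobic fill.** Deep-pocket points, ordered by burial depth
  (distance to nearest solvent, descending; ties by lexicographic grid
  index), are greedily accepted as carbon-like atoms whenever they keep all
  pairwise center distances ≥ 1.7 Å (polar probes included).  The greedy
  order is a design choice — the most sequestered volume is filled first —
  and makes output fully deterministic.
* **Clustering.** Single-linkage components at 5 Å merge flanking
  sub-pockets into one exemplar; when components remain separate, the one
  whose centroid is nearest the target center of mass is kept (ties by
  larger atom count).  Keeping all components is available as a flag.

Exemplar radii are 1.70 Å for hydrophobes and 1.50 Å for polar probes.
Files use a PDB-like record format with the feature encoded in the residue
name (HPH/DON/ACC) and the radius in the B-factor column.

## 4. Gaussian shape/chemistry comparison

Shape is a sum of spherical Gaussians (amplitude p = 2.828; exponent set so
an isolated atom's Gaussian integral equals its hard-sphere volume
(4/3)πr³ — the standard Grant–Pickup parameterization).  The overlap of two
sets is the first-order pairwise analytic integral, which is *exact* for
the summed densities (the approximation relative to hard spheres lies in
the density model, not the integral); tests verify it against midpoint-rule
quadrature at 0.1 Å to within 0.1 %.

Chemistry ("color") overlap is the same integral restricted to matched
polar features (donor–donor, acceptor–acceptor) with fixed 1.0 Å color
Gaussians; hydrophobes contribute to shape only.  When *neither* set has
polar features the color Tanimoto is defined as 1 (two purely apolar sets
have identical — empty — chemistry), when exactly one side has polar
features it is 0.  This convention makes two identical apolar shapes
perfectly similar, which is the behavior the downstream distance needs.

Alignment maximizes shape + 0.5·color overlap over the six rigid degrees of
freedom.  Starts are the four proper principal-axes sign combinations with
centroids superposed, plus six seeded random rotations (degenerate inertia
tensors are thereby covered); each start is refined by Nelder–Mead (≤ 300
evaluations, tolerance 1e-4).  Scores at the final pose:

* shape Tanimoto  T_s = O_AB / (O_AA + O_BB − O_AB)
* color Tanimoto  T_c, same normalization over color overlaps
* TanimotoCombo   = T_s + T_c ∈ [0, 2]
* **exemplar distance** = 2 − TanimotoCombo ∈ [0, 2]

The numeric form of "exemplar distance" is a documented assumption: the
conventional combo-based dissimilarity.  Distances are evaluated in both
alignment directions and the smaller is reported, which bounds the
asymmetry of the local optimizer (tests require |d(A,B) − d(B,A)| ≤ 5e-3).

## 5. Biased ensemble sampling

Conformational ensembles come from independent Metropolis Monte Carlo
trajectories on a stand-in energy with a pocket-opening bias:

    E' = E + c · V_deep,   c = −0.25 energy units/Å³ (default)

V_deep is measured each step on a small grid (edge 12 Å, spacing 1.0 Å)
re-anchored at the target residues.  The stand-in energy E is a soft-sphere
repulsion plus an elastic network:

* repulsion: quartic penalty k_rep·(onset − d)⁴ for pairs closer than the
  onset, with per-pair onset = min(3.4 Å, reference separation) so the
  reference conformation is exactly clash-free (E = 0) even for densely
  packed pseudo-protein lattices; k_rep = 10 units/Å⁴.
* elastic network: k·(d − d_ref)² over all reference pairs within 10 Å;
  k = 0.05 units/Å².  The spring constant sets the overall energy scale of
  the stand-in; it was chosen so that the bias energy per grid point of
  deep volume (0.25 units at 1 Å spacing) is comparable to the elastic cost
  of the wall displacements that open a pocket — a stiffer network simply
  freezes the fixture and no sampling method would open anything.

Moves are single-atom Gaussian jitter (σ = 0.3 Å) and occasional rigid
rotation of one residue's atoms about their centroid; temperature is fixed
at 1.0 (no annealing).  Each output conformation is the end point of its
own trajectory (default 2000 steps; study-scale runs here use a few
hundred, see below), with the energy re-evaluated without the bias term.
The sampler is exactly reproducible from its seed, and with c = 0 the
deep-volume evaluation is skipped without changing the chain.

Metropolis correctness is checked against the closed-form Boltzmann
distance distribution of a two-atom harmonic toy (KS < 0.05 at 10⁴
samples).  Ensembles are **not** Boltzmann-weighted samples of the biased
system in any calibrated sense; they are a search device for reachable
pocket-open states, which is why the energy filter exists:

* **Energy filter:** biased-ensemble conformations are kept when their
  bias-free energy is within 15 units of the *median* of an unbiased
  reference ensemble.  "Within 15 units of the unbiased ensemble" names a
  distribution, not a point; the median is the reference statistic by
  default, with min/max available.

## 6. Selectivity analytics

* **Distance matrix:** all-vs-all exemplar distances, symmetrized by the
  smaller of the two alignment directions.
* **MDS:** classical (Torgerson) scaling — double-centered squared
  distances, top eigenvectors scaled by root eigenvalues, with a fixed
  eigen-sign convention (first nonzero coordinate of each axis positive)
  for reproducible maps.  For Euclidean-realizable input the embedding
  reproduces the matrix to 1e-9.
* **Distinctness** of a conformation = (distance to the nearest pocket of
  any other family member) − (distance to the nearest other pocket of its
  own ensemble).  Large values mark pockets unique to one protein.
* **Selectivity rows:** for a reference (an inhibitor-bound-pocket exemplar
  or a ligand conformer typed with the same feature classes), the minimum
  distance to each protein's ensemble exemplars, normalized across the row
  as Z-scores with the *population* SD; rows without variation are flagged
  and zeroed.  Low z predicts binding.
* **ROC:** binding classes collapse to binary (strong vs none;
  intermediate and unknown cells excluded).  AUC comes from the rank-sum
  identity, p from the tie-corrected normal-approximated one-sided
  Mann-Whitney U.
* **Spearman matrix correlation:** tie-aware Spearman over the vectorized
  upper triangles of two same-labeled matrices.

## Synthetic fixtures and what they do (and do not) show

All tests run on generated pseudo-proteins: solid balls of carbon-like
atoms on concentric Fibonacci-lattice layers (outer radius 9 Å, lattice
gap 1.7 Å — dense enough that no interstitial void reads as a pocket),
with pockets carved as cylinder/sphere subtractions and polar residues
(a glycine-like carbonyl or serine-like hydroxyl) planted on pocket walls
pointing into the cavity.  The three-member family preset gives members 1–2
a shared pocket A (radius 3 Å, depth 6 Å, +z pole) and member 3 a distinct
narrower pocket B (radius 2.2 Å, depth 7.5 Å, +x pole), with the truth
table of which member can present which pocket.

These fixtures exercise every algorithmic contract — grid labeling,
burial, packing, clustering, alignment, bias response, recovery of the
generative truth — with exact ground truth.  They do **not** emulate real
protein energetics, side-chain rotamers, cryptic pockets that require
backbone rearrangement, or crystallographic noise; a pass here shows the
machinery is correct, not that a particular real family will be predicted
correctly.  For real use, the energy interface is pluggable (any
`structure → energy` callable with a reference state can replace the
stand-in).

## Problem sizes

Study-scale defaults in the tests and the reproduction script: ~500-atom
fixtures, sampling grids of 13³–15³ points, trajectories of 200 steps for
ensemble generation and 800 steps for the bias-effect measurement,
ensembles of 12–50 conformations per protein, distance matrices over ~18
exemplars, and 10⁴ recorded samples for the sampling-correctness check.
These sizes were chosen so the full suite reproduces on a laptop-class
single core in minutes while every statistical check retains comfortable
power; all of them scale up through configuration without code changes.

## Known limitations

* The stand-in energy has no attractive nonbonded term, no solvation and
  no torsional chemistry; conformational change is diffusive rather than
  collective, so pocket "opening" here means rim relaxation, not cryptic
  pocket formation from a closed state.
* The alignment optimizer is local; global optimality is approached through
  multiple starts, verified against a 10° exhaustive rotation grid on
  small sets, but adversarial shapes could in principle defeat it.
* Ligand feature typing is element/H-count based; no protonation or
  tautomer modeling.
* Selectivity labels are user-supplied; no affinity curation is shipped.
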