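# Methods

This note documents the geometric models, the tunable parameters, the
synthetic generators the test suite is built on, and the design choices
made where the problem was genuinely open. It states no empirical result
that the tests or `scripts/acceptance.py` do not themselves compute.

## Scope and model of the data

The package operates on hierarchical atomic models — ensemble → model →
chain → residue → atom — read from PDB or mmCIF through gemmi. Three
policies are applied at parse time and are deliberate:

* **Altloc resolution.** One conformer per atom name: highest occupancy,
  ties broken by file order. Deposited quadruplex entries contain
  alternates; the analyses need a single-conformer model.
* **Hydrogens dropped.** Crystal structures carry no hydrogens while NMR
  depositions do; all geometry downstream (hydrogen bonds, planes, RMSF,
  RMSD) is therefore defined on heavy atoms only, so both input classes are
  treated uniformly.
* **Name normalization.** Old-style primed atom names (`O5*`) map to the
  PDB v3 convention (`O5'`); residue names (`DG`, `G`, `GUA`, and the
  5-bromo-dU analogue `BRU` → `T`) map to one-letter base codes so NMR and
  X-ray depositions of the same sequence compare cell-for-cell. Author
  residue numbering is kept verbatim; a derived sequential index (1..n from
  the 5′ end) provides uniform labels for cross-structure tables.

## Quartet detection

A G-quartet is modelled as a directed 4-cycle in the graph whose edge
g → h exists when d(N1(g), O6(h)) ≤ `hbond_max` and d(N2(g), N7(h)) ≤
`hbond_max` (default 3.5 Å). This is a donor→acceptor heavy-atom criterion
with no angle term — the standard fallback when hydrogens are absent — and
the cutoff is an explicit parameter. Candidate cycles must satisfy a
planarity gate: the RMS deviation of the four guanines' ring atoms from
their common best-fit plane may not exceed `planarity_max` (default 1.0 Å);
this is also what rejects spurious cycles that span two stacked layers.
When candidate quartets share a guanine, selection is greedy by planarity
(most planar first, deterministic tie-break on residue keys). Sequence
order plays no role, so a guanine outside any G-tract that folds back into
the core is detected like any other.

## Core assembly and the reference frame

Quartet layers are ordered along the principal axis of their plane
centroids; consecutive centroid separations must lie in `stack_window`
(default 2.8–4.5 Å) or a stacking-break error names the offending gap. The
layer containing the 5′-most core guanine becomes `layers[0]` and the axis
points away from it. This anchoring is the package's convention for making
"up"/"down" reproducible across files and deposition variants: the
bottom face is defined by chemistry (where the first tract starts), not by
file orientation. A global-axis convention (rather than per-nearest-face)
is used for up/down throughout.

Channel ions: a monatomic cation is a channel ion iff its axial projection
falls between the terminal layer centroids (± half a mean rise) and its
distance to the axis is ≤ `radial_max` (default 2.5 Å). Everything else is
reported as external with its nearest residue.

## Topology classification

Core columns are built by seeding with the bottom quartet's cyclic order
and matching members of each higher layer by lateral (axis-perpendicular)
distance via optimal assignment. Strand sense per column is the sign of the
backbone C1′ axial progression against sequence order, reported relative to
the first column. Tracts are maximal consecutive-sequence runs within a
column; a run of length one is a snapback residue (an isolated core
guanine). Loops are maximal non-core nucleotide runs strictly between core
residues — 5′/3′ overhangs are not loops. A loop is typed by the faces and
corners its flanking core guanines occupy: opposite faces → propeller
(groove-traversing double-chain reversal), same face and adjacent corners →
lateral, same face and opposite corners → diagonal.

## Torsions

α…ζ and χ follow the IUPAC atom definitions, computed with a single
dihedral kernel (sign: clockwise positive looking down the central bond),
degrees in (−180, 180]. An angle whose atoms are missing — 5′-terminal
residues without a phosphate lack α/β, 3′-terminal residues lack ε/ζ — is a
null cell, never an exception; comparison tables leave those cells blank.
Whether an angle exists follows atom presence in the file, not any fixed
row layout.

## Base orientation

For an extra-helical base, the ring centroid is decomposed relative to the
nearest layer centroid into a signed axial component along the core axis
and a radial component. Stacking is checked first, against core guanines
and the other extra-helical bases of the same model: partner-relative
centroid offset ≤ `stack_lateral_max` (2.5 Å) laterally and within
`stack_axial_window` (3.0–4.2 Å) axially, ring-plane angle ≤ 30°. These
defaults are canonical π-stacking geometry; no published numeric thresholds
exist for the up/down/out/stack vocabulary, so all four cuts are explicit
configuration intended to be scanned. Absent a stack, elevation =
atan2(axial, radial) splits up (> +`elevation_cut`), down
(< −`elevation_cut`) and out. Note one structural fact about sensitivity
scans: a π-stack sits at a fixed ~3.4 Å rise, so scaling *both* edges of
the axial window by ±20% produces disjoint windows — flips of stack calls
under that scan are a property of the scan, not noise; the elevation-based
categories are the ones expected to be scale-stable.

Occupancy tables report, per base, the percentage of ensemble members (or
any weighting that sums to 1, e.g. cluster populations over medoids) in
each category; rows sum to 100%.

Cleft width is the Euclidean P…P distance between two nucleotides' 
phosphorus atoms, reported to one decimal in human-readable tables.

## Flexibility

Per-residue crystallographic B is the unweighted mean of atomic B over the
residue (all atoms, or ring atoms only). Ensemble RMSF superposes every
member onto the ensemble mean using a fit selection — default in the
pipeline: core-guanine heavy atoms, so loop flexibility is not absorbed by
the fit — with one mean-refinement iteration (mean → fit → mean); full
iteration to convergence is available behind `max_iterations`.
RMSF(atom) = √⟨|r − r̄|²⟩ over members, per-residue values are atom means.
Theoretical B = (8π²/3)·RMSF². "Normalized" means per-chain z-score
(population SD; constant profiles map to zeros, normalization is
idempotent); min–max scaling is available for figure-style replotting. The
package averages per residue first, then normalizes. Cross-source
comparisons align profiles by sequential position and report Spearman rank
correlations — rank, not Pearson, because B and RMSF live on different
scales and only the ordering of flexible regions is comparable.

## Ensemble clustering

The dissimilarity is pairwise least-squares-fitted RMSD over an atom
selection. Clustering is PAM-style k-medoids: k-medoids++ seeding from the
given seed, then alternating nearest-medoid assignment (ties to the lowest
cluster id) and medoid update (member minimizing summed within-cluster
dissimilarity, ties to the lowest frame index) to label convergence —
deterministic under a fixed seed. Problems with at most 2000 candidate
medoid subsets are instead solved exactly by enumeration, so small inputs
are globally optimal. The number of clusters is the best mean silhouette
over k = 2..k_max (default cap 10), ties resolved toward smaller k; a best
silhouette below 0.25 triggers a "weak structure" warning because the
partition is then a formality. The medoid is always a physical frame.

Transitions are counted per trajectory independently: consecutive frames
with differing cluster labels increment a directed count; frame pairs
spanning a trajectory boundary contribute nothing, so concatenating
multiple runs cannot fabricate transitions. Counts are kept directed;
connectivity (and the isolated-cluster query, degree ≤ 1) treats them
undirected. Populations weight by frame count. Frame adjacency is the unit
of time — no lag parameter; a stride is available in configuration.

Intended scale is desk-sized ensembles (≤ ~5000 frames; the distance
matrix is O(n²) superpositions). Hundred-thousand-frame production
clustering is out of scope.

## Synthetic generators

The generators exist so that each analysis has at least one closed-loop
test against exactly known ground truth; all are seeded and bit-reproducible.

* **Internal-coordinate chains (NeRF).** Each atom is placed from three
  references by bond length, bond angle and dihedral (natural extension);
  the first three atoms seed a canonical frame. The backbone table maps the
  seven standard torsions onto placement dihedrals exactly, so the torsion
  module must read back the prescription to machine precision — this is
  the torsion oracle. Standard bond lengths/angles are compiled into the
  table builder. One caveat discovered and documented in the tests: with
  the backbone's heterogeneous bond angles, the all-trans chain is *not*
  the most extended conformation (the planar zigzag curls into an arc);
  maximal extension at 180° holds for uniform-geometry chains and is
  asserted there.
* **Idealized quadruplex.** Nucleotide geometry comes from the chemical
  component dictionary bundled with biotite (ideal DG/DA/DC/DT
  coordinates), re-framed on the base ring. Four guanines per layer sit at
  90° spacing; the placement radius and in-plane rotation are auto-tuned
  (coarse grid + Nelder–Mead) so neighbouring N1–O6 and N2–N7 distances hit
  2.88 Å, with a soft steric term that rejects degenerate overlapping-ring
  optima; construction fails loudly if the tuned hydrogen bonds exceed
  3.2 Å. Layers twist and rise along +z (defaults 30°/layer and
  3.3 Å/layer — canonical parallel-quadruplex helical values; both
  parameters are scan axes in the tests across 20–40° and 3.0–3.6 Å).
  Loop bases are planted at positions realizing a prescribed orientation
  category with margin; channel K⁺ go on the axis midway between layers.
  Parallel topology traverses all four columns bottom-up (propeller
  loops); the antiparallel option alternates column direction (lateral
  loops, mixed senses). The loop and sugar backbone is geometrically
  plausible but not energy-minimized — sufficient for geometric
  classifiers, not for force-field work. The B-DNA-like G:C duplex is the
  negative control: many guanines, no Hoogsteen cycle.
* **Perturbation ensembles.** Members add i.i.d. per-coordinate Gaussian
  noise with a per-residue σ profile. For isotropic noise the closed form
  ⟨|Δr|²⟩ = 3σ² gives RMSF = σ√3, which the RMSF module must recover
  (the calibration uses n = 500 members and a 5% band).
* **Planted trajectories.** Frames follow a per-trajectory schedule over
  deformation-generated centers (Gaussian deformation, *not* rigid motion —
  rigid offsets vanish under fitted RMSD) plus small noise; the planted
  partition and switch count are the clustering and transition oracles.

What the generators do **not** emulate: real sugar puckers and correlated
backbone motion, solvent, crystal packing, base-pairing energetics,
anisotropic B factors. Passing the synthetic suite therefore demonstrates
the correctness of the geometric definitions and bookkeeping, not the
biological realism of any particular threshold on noisy experimental data —
for that, the deposited-entry regression tests exist (they activate when
the published coordinate files are placed under `data/deposited/`).

## Numerical choices

Angles are degrees everywhere at module boundaries; range (−180, 180] with
−180 folded to +180. Superposition is Kabsch via SVD with the determinant
forced to +1 (reflections are forbidden — DNA is chiral). Plane fitting is
the smallest-eigenvalue eigenvector of the centered covariance; collinear
input raises. Dihedrals raise on coincident/collinear points rather than
returning a garbage value. JSON reports sort keys and fix floats at 4
decimals (1 decimal for Å distances in human-readable tables), making
reruns byte-identical under a fixed config and seed.

## Problem sizes in the standard runs

The shipped test suite and the acceptance script run entirely on synthetic
inputs at desk scale, chosen to exercise every code path with exact ground
truth: quadruplexes of 3 layers with 1–3-nucleotide loops (15–21
nucleotides), a twist × rise scan of 20 builds, a 500-member calibration
ensemble on a 6-mer, and 8–60-frame trajectory sets over 3 planted centers.

## Known limitations

* Quartet detection reports only all-guanine quartets; mixed quartets and
  bulged tracts beyond snapback labelling are out of scope.
* Dimer-interface stacking across asymmetric-unit copies requires symmetry
  expansion, which the package does not perform.
* The A:G base-pair features of long stem loops are not typed; candidate
  pairs can be found by distance but are not classified.
* Sugar-pucker pseudorotation and BI/BII substates are not computed (δ is
  reported; that is the only pucker-adjacent observable).
* The silhouette criterion inherits its known bias toward compact,
  equal-sized clusters; with genuinely continuous conformational spread the
  "weak structure" warning is the honest output.
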