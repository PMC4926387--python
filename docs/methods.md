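# Methods

This note records the models, constants and design choices behind
`excidock`, and what the synthetic test systems do and do not demonstrate.

## Coordinate model and conventions

Structures are ordered heavy-atom lists in Å with PDB author numbering
(chain, residue number, insertion code) kept verbatim. Multi-model PDB is
the only trajectory format. Hydrogens are ignored in every distance,
contact and scoring computation: all cutoffs in this package are
heavy-atom-scale. All distance cutoffs are closed intervals (a pair at
exactly 4.0 Å *is* a contact); one convention had to be fixed and ≤ is the
conservative choice. Alternate locations are resolved by keeping blank or
'A'; ATOM and HETATM are both read.

## Rigid-body score

The protein–protein score sums a softened Lennard-Jones potential

V(r) = (ασ⁶ + r⁶)⁻¹ (4εσ¹²/(ασ⁶ + r⁶) − 4εσ⁶)

over intermolecular heavy-atom pairs within 8 Å, with α = 0.4, σ = 3.3 Å,
ε = 0.5 applied uniformly to non-hydrogen atoms. The softening keeps the
potential finite through atom overlap (V(0) = 4ε(1−α)/α²), which is what
makes a coarse grid scan meaningful. σ is stored in the same unit as r; the
published parameterisation quotes 0.33 nm. With α = 0 the implementation
switches to the literal 12-6 expression so the hard limit is reproduced to
machine precision. An electrostatic term (below) is added with a small
weight, 0.1 by default.

## Electrostatics

Formal integer charges only: Asp/Glu −1, Lys/Arg +1, His 0, carried by one
designated side-chain atom; ligand atoms use their formal charge field. The
interaction is Coulomb with a distance-dependent dielectric ε(r) = 4r,
i.e. 332.0636·q₁q₂/(4r²) kcal/mol. Below r = 2.5 Å the magnitude is held at
its r = 2.5 value. This contact clamp matters: point charges sit on
heavy-atom centres, and the hydrogen-bond well (by construction) has no
repulsive core, so an unclamped screened term would make charge-on-charge
overlap the global optimum of any charged system. 2.5 Å is roughly the
closest heavy-atom contact distance; at and beyond it the stated form is
unchanged.

## Empirical flexible-docking score

E_tot = E_bind + E_pharma + E_ligpre, decomposed exactly as
(E_inter + E_intra + E_penal) + E_pharma + (WP_elec + WP_hb).

* E_inter: pair wells over target–ligand heavy pairs within 6 Å.
  Donor↔acceptor pairs take a hydrogen-bond well: zero up to 2.0 Å, ramping
  to −2.5 on [2.3, 3.1], back to zero at 3.6 Å. All other pairs take a
  steric well: +5.0 at ≤ 2.0 Å ramping to 0 at 3.3, dipping to −0.4 on
  [3.6, 4.5], zero at 6.0 Å. Pairs of formally charged atoms additionally
  receive the clamped Coulomb term. The knot positions and depths are
  constants of this package (the published description of the underlying
  linear model names the terms but not the numbers); they were chosen to
  make a hydrogen bond ≈ 6× the steric well depth and are all exposed in
  `ScoringConfig`.
* E_intra: the same wells over ligand atom pairs ≥ 4 bonds apart.
* E_penal: fixed 10000 if any ligand atom leaves the search box.
* E_ligpre: WP_elec = +5 if the ligand carries a formal charge but no
  oppositely charged target atom lies within 4 Å; WP_hb = +5 if the ligand
  has ≥ 3 donor/acceptor atoms yet forms no hydrogen-bond-typed contact.
  The published account names these penalties without trigger or
  magnitude; the realisation above is this package's.
* E_pharma: disabled by default — the method is blind, with no prior
  binding-site knowledge. It is implemented (per-hot-spot-atom weight
  awarded when the pose realises the required interaction type) for
  completeness.

Atom typing is template-driven for the 20 amino acids (all N/O are
acceptors; donors are backbone N except proline plus the usual side-chain
donors) and element-driven for ligands (N/O donor+acceptor, C/S
hydrophobic). Unknown elements are typed hydrophobic with a logged warning.

## Rigid docking search

Direct exhaustive scan instead of FFT correlation: at the problem sizes
this package targets (tens of residues per body) orientations × lattice is
tractable and exact by construction. Orientations come from
`orientation_set(n)`: the exact tetrahedral/octahedral/icosahedral rotation
groups at n = 12/24/60 (minimum pairwise geodesic angle near the
sphere-packing optimum — 72° at n = 60 against a ≈ 78.5° volume bound) and
a super-Fibonacci quaternion spiral otherwise. Translations scan the
receptor bounding box + 10 Å margin at 1 Å spacing. The best 100 poses are
refined by coordinate descent with translation steps halving 1.0 → 0.125 Å
and rotation steps 10° → 1.25°; ties break toward the lower orientation
index, then lexicographic translation. Clustering is greedy leader in
energy order at 3 Å ligand-Cα RMSD in the fixed receptor frame (all heavy
atoms for ligands without Cα); reports take the lowest-energy member of
each of the first 10 clusters.

## GA search

One seeded NumPy generator per `ga_dock` call drives everything; the same
seed gives bit-identical pose lists. Genome = translation + unit quaternion
+ torsion angles. Tournament selection (size 2), arithmetic crossover on
translation, quaternion slerp on orientation, shortest-arc blending on
torsions, per-gene Gaussian mutation (σ = 1 Å / 15° / 30°, rate 0.1),
elitism 2. Torsions apply root-outward from atom 0; rigid placement rotates
about the ligand centroid. Rotatable bonds are single, acyclic, between
non-terminal heavy atoms; when more than 5 qualify the bonds moving the
most atoms are kept (ties → lower bond index). After the last generation
the population is energy-sorted, scores with |E_tot| > 100 kcal/mol are
discarded (the published energy cut-off is read as a magnitude bound — a
literal −100 ceiling would discard every observed pose, which lie in the
−8…−45 range), distinct sites are extracted by greedy leader clustering at
2 Å all-heavy-atom RMSD, at most 100 sites are kept and the 10 best are
returned. Panel docking derives per-ligand seeds as `seed + index`.

## Hotspot consolidation

Poses connect iff they share ≥ 1 contact residue (4 Å) or their centroids
lie within 8 Å; spots are connected components ordered by best member
energy, and hotspots apply the same rule across excipients. The grouping
rule is this package's definition (the source analysis grouped poses by
inspection); 8 Å roughly spans one binding subsite and is exposed as a
parameter. Interaction maps at 3.5 Å classify each pair hbond (donor↔
acceptor in [2.0, 3.5]) > electrostatic (opposite formal charges) >
hydrophobic, keeping the minimum distance per (residue, type). Hotspot
tables compress residues into per-chain runs allowing gaps of ≤ 1.
Interface overlap counts residues (not atom contacts); a hotspot matches a
docking solution if they share ≥ 1 receptor-side residue, and the fraction
of hotspot residues covered is reported so the threshold can be tightened.

## Trajectory analyses

Contact persistence is the fraction of frames whose minimum residue–ligand
heavy-atom distance stays ≤ 4 Å; 1.0 is the criterion for a contact
"maintained throughout". RMSD uses least-squares superposition
(reflections disallowed) on the chosen selection. RMSF is computed about
the per-atom trajectory mean *without* prior superposition — snapshot
series are assumed pre-aligned, which keeps the two-frame closed form
exact — with an optional superpose flag.

## Stability correlation

Per-excipient mean binding energy averages the pose energies that feed the
consolidated hotspot table, reported at two decimals, half-up (the bundled
reference dataset's printed means are reproduced exactly by this rule).
The fit is ordinary least squares of T_m on the reported means via
`scipy.stats.linregress`. Exclusions are named flags, not hard-coded;
arginine defaults to excluded as the screen's negative control. On the
bundled dataset the fit gives R² ≈ 0.59 (n = 7) — the number the package
computes from the printed values, reported as such.

## Synthetic study systems

The generators in `excidock.fixtures` are the package's test surface; all
are bit-reproducible from their seed and return their planted ground truth.

* **Toy receptor**: ~30 residues on a jittered quasi-uniform spherical
  shell (Cα + one side pseudo-atom each, alanine-like surface), with a
  pocket at the +z pole: donor/acceptor lining atoms on a 2.6 Å ring about
  the pocket centre and charged lining atoms clustered tightly (0.9 Å
  ring) in the centre plane. The default lining is four aspartate-like
  carboxylates: a complementary charged probe then has its energy optimum
  in a small lens around the pocket centre, and *every* pose in that lens
  has all four lining residues within the 4 Å contact cutoff — recovery of
  the planted pocket is a geometric consequence of reaching the optimum,
  not a coincidence of one seed. Construction is verified at build time by
  a coarse 2 Å probe scan that must place the global optimum within 3 Å of
  the planted centre.
* **Ligand classes**: amino-acid-like (one +1 charge, 3 donors, 3
  torsions), disaccharide-like (two rings + glycosidic bridge, 2 torsions),
  polyol-like (C6 chain, 6 hydroxyls, 5 torsions), surfactant-like (polar
  head, C8 tail, 8 rotatable bonds capped at 5). Pseudo-atom chemistry
  with 1.5 Å bonds — the algorithms under test consume distances, types
  and charges, not force-field geometry.
* **Complementary pair**: two 13-residue slabs with flat 3×3 polar faces
  carrying complementary formal charges and smaller rough back layers;
  face-to-face packing is the rigid-score optimum and the face residue
  sets are the planted interface.
* **Trajectories**: Gaussian positional noise per frame; the ligand is
  re-positioned along the closest-pair axis each frame so the minimum
  distance either stays ≈ 3 Å (held contact, persistence exactly 1.0) or
  jumps to ≈ 6 Å after half the frames (persistence exactly ceil(n/2)/n).

What passing on these systems shows: the search machinery finds planted
global optima, the bookkeeping (contacts, clusters, hotspots, overlaps,
persistence) is exact, and the pipeline is deterministic. What it does not
show: force-field realism, behaviour on real protein surfaces with
water-mediated or conformationally coupled binding, or transferability of
the energy constants.

## Problem sizes and numerics

Default study sizes — 30-residue receptors, 7–17-atom ligands, 800×10 GA,
60 orientations × 1 Å lattice rigid search — keep a full pipeline run in
the minutes range on one core; the demo subcommand scales the GA down
(population 150, 8 generations) for a fast walkthrough. Degenerate inputs
fail loudly: empty structures, disconnected ligand graphs, unsorted
solution lists, mismatched trajectory frames and non-orthonormal rotations
all raise with specific messages. Reported pose lists, cluster ids and
table orderings are fully tie-broken so equal energies cannot reorder
output between runs.

## Known limitations

Formal-charge electrostatics only (no partial charges, no desolvation);
rigid receptor in flexible docking; the hydrophobic-probe term of the
original empirical score is not reproduced (its functional form is
unpublished); interface overlap has no null model, so overlap fractions
are descriptive, not significance-tested; PDB is the only structure format
(no mmCIF), and binary trajectory formats are out of scope.
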