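# Methods

`symdock` docks rigid protein building blocks into symmetric assemblies. This
note records the model, the numerical conventions, and the design choices
that were genuinely open, so that results produced with the package can be
interpreted and reproduced.

## Problem and model

A docking problem is defined by an *architecture*: a symmetry class (cyclic
Cn, dihedral Dn, coaxial stacks, the polyhedral rotation groups T/O/I, or a
planar wallpaper group) together with the axes each building-block component
is mounted on and the rigid-body degrees of freedom (DOFs) it may sample.
Components are treated as rigid: a monomer samples full orientation plus a
radial offset (cyclic docking) or all six DOFs (asymmetric docking); a cyclic
oligomer mounted on a symmetry axis samples one rotation about and one
translation along that axis, optionally preceded by a 180-degree flip about x
that covers the otherwise-redundant negative translation branch. The full
assembly is the orbit of the placed asymmetric unit under the architecture's
symmetry frames; frames for T, O, and I are generated by closure from two
generators and verified against the group orders 12, 24, and 60.

Axis conventions are frozen constants: O mounts the 4-fold on z, the 3-fold
on (1,1,1)/sqrt3, the 2-fold on (1,1,0)/sqrt2; T mounts the 2-fold on z and
3-folds on cube diagonals; I mounts 2-folds on the coordinate axes, the
5-fold through the icosahedron vertex (0,1,phi) and the 3-fold through the
adjacent face center (1/phi,0,phi). Adjacent-axis pairs are chosen so that
inter-axis angles match the canonical values (e.g. acos(1/sqrt3) for O 4/3,
37.38 deg for I 5/3), which tests pin to 1e-9.

## Scoring: residue-pair transforms

Dock quality is scored without sequence information. The interaction of two
residues across an interface is summarized by the 6D rigid transform between
their backbone frames (*stubs*: orthonormal frames built from N, CA, C by a
fixed Gram-Schmidt convention, origin at CA). That transform is binned into
a six-dimensional lattice: translations on a body-centered-cubic lattice (a
parity bit selects one of two interleaved cubic sublattices; covering radius
sqrt(5)/4 of the cell width), rotations on per-cell gnomonic grids inside
the 24 cells obtained from the bitruncated 24-cell partition of the
quaternion 3-sphere after antipodal identification (48 cell centers — the
binary octahedral group — give 24 rotation cells; empirical covering radius
62.8 deg, frozen with a Monte-Carlo test). An *hscore* table maps bin keys
to nonnegative scores at a ladder of resolutions; level L halves both the
Cartesian and angular resolution of level L-1 (defaults 10 A and 30 deg at
the top). A missing key scores zero. Scores follow a "higher is better"
convention.

Shipping tables are synthetic: the generator anchors high-score keys on
ideal helix-pair packing transforms (emulating a helix-only motif subset)
and builds coarse levels by re-binning every entry across the span of one
coarse cell, so each coarse key upper-bounds its refinements by
construction. This admissibility is what makes beam pruning safe; it is a
property of the table, asserted by tests, not of the search.

Score functions over the per-pair values (a = `weight_rpx`, default 1;
b = `weight_ncontact`, default 0.001):

* `stnd`: a * sum(RPX) + b * ncontact, where ncontact counts CA–CA pairs
  within `max_pair_dist` (default 8 A at the finest level);
* `mean` / `median`: replace the sum with the mean or median;
* `exp`: sum(RPX) − 4.6679 * ncontact^0.588; `lin`: sum(RPX) − 0.7514 * ncontact;
* `sasa_priority`: a * mean(RPX) + b * ln f(c*N), with f a log-normal density
  over the estimated buried area c*N. The conversion constant c is 24 A^2
  of buried area per contacting pair, so the default target area
  (`weight_sasa` = 1152 A^2) sits at 48 contacts. The density is
  parameterized mode-at-target: shape s = `weight_error`/4 and log-location
  ln(mu) + s^2, so the contact term peaks exactly where c*N equals
  `weight_sasa` for every tolerance — the property the tests assert. For
  this function b = 5 is the recommended weight.

Residues excluded by an allowed-residues list, or pairs failing a
secondary-structure restriction (`score_only_ss`, `score_only_sspair`),
still count as contacts but contribute no pair score.

## Search

The hierarchical search evaluates the complete top-level grid (Cartesian
cells of width `cart_resl`, angle cells of width `ori_resl`, orientation
cells subdivided so each top cell carries a grid of roughly `ori_resl`
spacing), keeps the `beam_size` best non-clashing configurations, expands
each kept cell into its children (2 per Cartesian/angle dimension, 8 per
orientation dimension), and repeats for `n_levels` levels (default 5,
reaching ~0.6 A / ~1.9 deg). Ties at the beam boundary break by (score
descending, index ascending), which makes runs bit-identical.

Pruning safety requires every coarse-level check to be conservative. Within
a level-L cell a component can move half a cell width along its axis and
rotate half an angular cell about it; rotation moves interface atoms by up
to the rotational lever (body radius x chord). The per-interface margin

    margin(L) = cart_resl/2^L + 2 (r_i + r_j) sin(ori_resl/2^L / 4)

with r the body's largest atom distance from its com or internal axis, is
added to the contact cutoff and subtracted from the clash distance (floored
at 0.05 A) at every coarse level; flatness and delta-h constraints get
analogous sin/width margins. The coarsest levels are therefore deliberately
permissive — nearly every near-contact survives level 0 — and selectivity
comes from the finer levels, which is the intended behavior of an
upper-bound search.

Geometry queries use sphere bounding-volume hierarchies (median-split binary
trees, one sphere per atom at the leaves). Spheres rather than boxes make
the tree invariant under rigid motion, so one tree serves every placement.
Tree queries (`bvh_isect`, `bvh_slide`, `collect_pairs`) prune with sphere
bounds but decide at leaves with exact distances, so they equal brute force
identically; tests check this on hundreds of random placements. The batch
evaluator used inside the search computes the same quantities with chunked
dense distance matrices, which is faster for the small bodies the package
targets; equality with the tree path is covered by the oracle tests.
`grid_search` enumerates a single-resolution grid exhaustively (capped at
2e6 cells) and doubles as the reference oracle for the hierarchical method.

Constraints: cyclic "flatness" bounds |cos| between the placed long axis
(principal CA eigenvector) and the symmetry axis; the absolute value is
used, restricting alignment and anti-alignment alike. `max_delta_h` bounds
the axial-offset spread across components. Termini handling aligns an ideal
21-residue helix (built from ideal internal coordinates, phi/psi -57/-47)
onto the 7 terminal residues; the sign of the free extension's axial
component classifies the terminus as pointing "in" (toward the global
origin, the symmetry center by construction) or "out", and `termini_dir`
prunes flip states accordingly. `term_access` keeps the aligned helix as
probe geometry that participates in clash checks only — never in scoring or
output.

## Results, filters, output

Ranked docks are stored as per-component 4x4 transforms plus metrics in an
xarray Dataset. Redundancy filtering is greedy best-first clustering on an
unaligned-RMSD proxy: the CA RMSD between two placements of the same body
without re-superposition, maximized over components (cutoff
`max_bb_redundancy`, default 3 A); only the best-scoring member of each
cluster survives. `filter_sscount` counts distinct secondary-structure
elements (maximal H or E runs from a phi/psi heuristic with minimum run
lengths 4/3) contributing interface residues, one count per contacting chain
copy; `filter_sasa` bounds the estimated buried area c*ncontact. Filters are
configured in YAML (`label: {type, confidence, ...}`); with
`confidence: false` a filter annotates every dock and removes none. An
all-removing filter yields a valid empty result.

PDB output expands the asymmetric unit by all frames (or writes the asu
alone; `closest_subunits` instead picks the frame pair with the most
contacts). Chain ids cycle A–Z, a–z, 0–9 — single characters, as the PDB
fixed-column format requires — which covers the 48-chain octahedral case and
beyond. Results serialize both to a portable `.txz` (tar.xz of JSON/PDB text
members, version-tagged) and a fast native `.pickle`; hscore tables use the
same dual scheme with a documented text schema (`meta.json` plus per-level
key/score TSVs).

## Synthetic data: what it does and does not show

The fixture generators produce ideal helices (internal-coordinate chain
building), clash-free Cn rings of helices as oligomer stand-ins, and the
synthetic tables described above — including "planted" tables whose
high-score keys come from the interface pairs of one chosen configuration,
with that configuration's ancestor-cell interfaces scored into each coarse
level so its whole refinement lineage carries an admissible bound. Passing
the planted-recovery tests shows that the search machinery — sampling,
hierarchy bookkeeping, conservative margins, beam selection, scoring — finds
the global optimum of a landscape with a known answer while evaluating a
small fraction of the space (the 4-DOF acceptance problems evaluate ~7% of
the exhaustive grid). It does not show that synthetic tables rank *real*
interfaces the way motif tables distilled from crystal structures do:
fixture helices have no side chains, no sequence, and invented energetics.
Conclusions about real design problems require real motif tables.

Problem sizes in tests and the acceptance script (12-residue helices,
trimer/tetramer rings, 3–4 hierarchy levels, beams of 100–400) were chosen
as the smallest sizes at which the planted-optimum problems are non-trivial
— the exhaustive grids run to ~2x10^5 configurations — while a full
run of the suite stays comfortable on a laptop-class single core.

## Numerical conventions and edge cases

* com = mean CA coordinate; long axis = principal CA eigenvector (sign fixed
  toward +z). Clash distance default 3.0 A over non-hydrogen backbone atoms.
* Angle dimensions sample half-open intervals [lo, hi): 0 and 360/n never
  both appear.
* Stub construction raises a degenerate-geometry error naming the residue if
  N/CA/C are collinear (tolerance on the normalized cross product, 1e-6).
* Residues missing backbone atoms are skipped with a warning; chains are
  concatenated with recorded breaks; residues renumber from 1.
* Transforms beyond the translation extent of the binning lattice (+-512
  cells) are flagged and score zero.
* An empty beam (everything clashing) returns empty stage results with
  pruning diagnostics rather than raising.
* Search determinism: identical inputs and configuration give bit-identical
  beams and outputs; all randomized tests use fixed seeds.

## Known limitations

* Helical (1D) and crystal (3D) architectures are not supported; of the
  wallpaper groups, site tables are provided for the P3/P4/P6 rotation
  sites listed in the architecture table.
* The secondary-structure heuristic is a phi/psi classifier, not a hydrogen-
  bond method; it is deliberately minimal because scoring needs only {H,E,L}.
* The batch search path computes contacts with dense distance matrices;
  bodies beyond a few thousand atoms would want the BVH path or coarser
  chunking.
* `sasa_priority`'s area estimate is linear in ncontact; the constant c is a
  convention, and absolute buried-area values should not be over-read.
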