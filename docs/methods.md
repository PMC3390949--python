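# Methods

This note documents the models, algorithms, numerical choices and synthetic
study conditions implemented in `pocketfrag`, in the spirit of a methods
appendix: what is computed, under which assumptions, and what the tests do
and do not demonstrate.

## Geometric representation

A cavity or fragment is a `MeshSolid`: a closed, consistently oriented
triangular mesh in Å, possibly comprising several disjoint shells. Normals
point out of the enclosed material, so shells bounding interior voids are
wound the opposite way and the signed-tetrahedron volume sum

V = Σ_t det(v0, v1, v2) / 6

(the divergence-theorem or "surveyor's" identity, exact for polyhedra)
subtracts void volumes automatically. Validity means: every edge shared by
exactly two triangles, once per direction. On ingest, meshes are repaired by
welding duplicate vertices (1e-6 Å) and dropping degenerate triangles;
repair can be disabled (`--no-repair`). Coordinates are kept in the input
frame — solids from different structures must arrive mutually superposed,
and the package never re-centers them.

Connectivity of shells is over shared **edges**, not shared vertices, so
two shells pinched at a single vertex stay separate components.

## Boolean operations

No robust exact mesh-CSG engine is bundled with the scientific Python
stack, so the package provides its own two-backend implementation behind a
single interface, selected automatically per call:

* **Rectilinear backend** (exact). When every operand face is axis-aligned
  (box unions, nested boxes, lattice cubes — all the solids used in the
  validation experiments), space is cut into cells by the union of both
  operands' face planes. Each cell is strictly inside or outside each
  operand, decided by counting +x ray crossings from the cell center (the
  center is nudged by an irrational sub-cell offset so it can never sit on
  a face edge of either operand). The Boolean is evaluated per cell and the
  boundary re-emitted as an exact axis-aligned mesh. Volumes are exact to
  roundoff; `vol(A∖B) + vol(A∩B) = vol(A)` holds at the 1e-12 level.

* **Voxel backend** (for curved solids). Operands are scan-line voxelized
  on a shared grid (default spacing 0.25 Å), the Boolean applied to the
  occupancy masks, and the result isosurfaced with marching cubes. Two
  details matter for correctness:

  - grids are anchored to the absolute frame (integer multiples of the
    spacing plus a fixed sub-voxel irrational shift). Independent calls
    therefore quantize shared flat surfaces identically, which prevents
    phantom half-voxel sliver fragments when a marching-cubes output is
    later compared against the solid it came from;
  - sample columns are offset from voxel centers by 1e-5 of the spacing,
    because marching-cubes vertices lie exactly on lattice edges (i.e. at
    column centers) and would otherwise graze every projected triangle
    vertex.

  Accuracy is first-order in the spacing; volumes of smooth solids at
  0.25 Å are typically within 1–2% of truth.

Coincident operand surfaces need no special jitter handling: the
rectilinear backend deduplicates coincident planes and the voxel backend
operates on masks, so degenerate overlap (A∖A, A∪A) is exact by
construction.

## Fragment separation

The boundary of a Boolean difference decomposes into edge-connected shells;
fragments are regrouped by the containment DAG:

1. For every ordered shell pair (i, j), shell j's seed point (its first
   vertex, which lies *on* j and therefore strictly inside or outside any
   other closed shell) is tested against shell i by ray-crossing parity: a
   ray in a random direction crosses i an odd number of times iff the point
   is inside. A hit within 1e-9 (barycentric/parametric) of a triangle
   edge, vertex, or the ray origin — or a ray lying in a triangle's plane —
   triggers a re-draw from a seeded RNG, up to 32 times. Parity of a closed
   shell is direction-invariant, so the output does not depend on the seed.
2. Containment edges form a DAG (a cycle would indicate a parity fault and
   raises). Each node's depth is assigned by depth-first search from every
   zero-in-degree root, re-assigning whenever a longer path arrives; this
   equals the longest-path depth from any root and is order-independent.
   The DAG is transitively redundant by construction, which is why the
   longest path (not the first-found path) is the correct nesting count.
3. Even-depth shells are fragment exteriors. Each odd-depth shell has
   exactly one immediate container — a depth-(d−1) shell with a containment
   edge to it (depth alone is not sufficient when several depth-(d−1)
   shells exist) — and becomes one of its interior voids. This grouping is
   correct for arbitrary nesting depth.

Fragments below the volume floor (default 0.1 Å³, configurable) are dropped
and counted in the log: near-zero volumes are discretization noise and
their logs would destabilize the model. Fragments are ordered by descending
volume with centroid-lexicographic tie-breaks, making "the largest
fragment" deterministic.

## The volume models

**Standard model.** Training pools the fragments from *all* unordered pairs
of same-specificity cavities, both directions. The log volumes are fit by
their sample mean x̄ and standard deviation s (unbiased n−1 denominator; an
MLE flag exists for sensitivity analysis), and a query fragment of volume v
gets

p = 1 − Φ((ln v − x̄)/s).

The log-normal has support x > 0, so the normalization over x ≥ 0 is
exactly one and no truncation correction applies. p is strictly decreasing
in v and maps (0, ∞) onto (0, 1); significance defaults to p < 0.05. No
multiple-testing correction is applied; reports carry the number of tests
so users can apply their own.

**Regionalized model.** For a cube g (default side 5 Å), every training
fragment is clipped to g by Boolean intersection; fragments that miss g are
eliminated and partial overlaps enter at their clipped volume. Survivors
above the floor are fitted as above. A cube with no survivor — or with
fewer than two, or zero log-spread, where no log-normal is definable — is
marked EMPTY: a test fragment clipped into such a cube is called
significant **categorically** (serialized as p = 0 with a distinct flag,
never silently merged with numeric p-values), because it reflects shape
variation unseen anywhere in the training set for that region. A test
fragment whose clipped volume is below the floor yields no call.

A space-filling lattice of side-s cubes is generated over the training
cavities' joint bounding box expanded by a margin (default 5 Å), with
ceiling counts per axis, so clipping over the lattice conserves fragment
volume exactly (rectilinear backend) or to 1e-4 relative.

**Goodness of fit.** `compare_distributions` fits log-normal, gamma,
Weibull, Pareto (all with location fixed at 0) and the 3-parameter GEV by
maximum likelihood, ranks them by AIC, and returns quantile-quantile pairs
for plotting. Degenerate samples or non-converging fits are flagged failed
and ranked last.

## Cavity preparation from structures

Protein heavy atoms are read from PDB (gemmi), dropping waters, ions,
other heteroatoms (unless named as the seed ligand), hydrogens/deuteriums,
and all but the first alternate location; atypical amino acids such as
selenomethionine are retained. Van der Waals radii are Bondi (1964) values
compiled into `VDW_RADII` (C 1.70, N 1.55, O 1.52, S 1.80, Se 1.90, …);
unknown elements fall back to 1.70 Å with a warning.

The cavity solid is

((∪ seed spheres, r = 5 Å) ∖ molecular surface) ∩ envelope surface,

with the molecular surface the solvent-excluded surface (SES) at probe
1.4 Å and the envelope the SES at probe 5.0 Å over the same atoms. Seed
spheres are centered on bound ligand/water atoms of the reference
structure. SES construction is grid-based morphological closing: the
union-of-balls signed distance field is thresholded at the probe radius
(dilation), then eroded via a Euclidean distance transform refined by the
signed field at the nearest background voxel. This sub-voxel correction is
exact for a single ball (one atom's SES is the atom sphere) and first-order
accurate elsewhere. All three fields are evaluated on one grid (default
0.5 Å) anchored to the seed neighborhood — the cavity is a subset of the
seed spheres, so atoms beyond the grid's reach cannot affect it — and the
Boolean combination is a pointwise minimum isosurfaced once.

Known discretization behavior: where the envelope spans a pocket mouth it
forms a "lid" whose surface has a conical crease on the mouth axis; the
distance-transform correction degrades to O(h) there. Volumes converge
cleanly under halving in the asymptotic regime (0.3 → 0.15 Å changes the
reference pocket volume by ~0.5%) but can move by ~6% from 0.5 → 0.25 Å.
For quantitative volume work use spacings ≤ 0.3 Å; the 0.5 Å default is a
speed compromise for interactive use.

## Synthetic study conditions

Real cavity families would require external structure data and a structure
aligner, so validation runs on synthetic families that emulate the
statistical structure of same-specificity cavity sets:

* **Base solid**: a box pocket, default 12 × 12 × 6 Å (864 Å³) — the scale
  of a serine-protease specificity subsite neighborhood.
* **Members** differ by small carved dents on one face, one per member by
  default, with log-normal volumes (median 8 Å³, log-sd 0.5): sub-1% of
  the pocket, i.e. the incidental variation the model should absorb.
* Dents occupy disjoint deterministic slots on the face, so each member's
  dent reappears verbatim as one fragment of any pairwise difference, and
  the training fragment-volume law equals the dent-volume law by
  construction. Draws that would overflow a slot are re-drawn (< 1% upper
  truncation at the defaults).
* A **different-specificity** cavity carries one extra dent far above the
  family's variation (the experiments use exp(x̄ + 3.5 s), above the
  99.9th training percentile).

What the generator does *not* emulate: curved atomistic surface texture,
correlated conformational variation between members, alignment error, and
fragment shapes other than compact dents. Passing calibration on these
families therefore demonstrates the statistical machinery (training,
pooling, tail probabilities, regionalization) under controlled geometry —
not robustness to the geometric noise of real structure data, which enters
through cavity preparation instead.

**Calibration experiment sizes.** For the nominal-level (null) experiment
the outgroup cavity is the pristine base — a zero-perturbation member of
the same family — so each held-out-vs-outgroup comparison produces exactly
one fragment, an i.i.d. draw from the training law; the largest-fragment
call rate is then interpretable as the test's level. Because pooled
training repeats each member's dent once per pair, a family of k members
contributes only k−1 unique training values and the plug-in test's true
level is α + O(1/(k−1)) (the usual Student/plug-in correction). The
calibration studies therefore use k = 16 members on a 20 × 20 × 6 Å base
(expected level ≈ 0.072 at α = 0.05, within two binomial standard errors of
α over 200 replicates), while the generator default stays at a paper-scale
k = 6. The leave-two-out experiment evaluates *all* fragments (not the
largest), so its p-values are approximately uniform at any family size.

All experiment drivers precompute each family pair's fragments once and
re-pool per training round; replicate counts (200) and family sizes are the
package's chosen study conditions and are echoed in every report. Reports
are byte-identical across runs at a fixed seed.

## Numerical choices, in one place

| Quantity | Default | Notes |
|---|---|---|
| vertex weld tolerance | 1e-6 Å | mesh ingest repair |
| degenerate-ray tolerance | 1e-9 | barycentric/parametric; retry ≤ 32 |
| CSG voxel spacing | 0.25 Å | curved-solid backend |
| SES grid spacing | 0.5 Å | ≤ 0.3 Å for quantitative volumes |
| fragment volume floor | 0.1 Å³ | dropped and logged |
| significance threshold α | 0.05 | no multiplicity correction |
| lattice cube side / margin | 5 Å / 5 Å | regionalized scans |
| log-sd estimator | n−1 | MLE (n) behind a flag |

## Limitations

* The exact CSG path covers axis-aligned geometry only; curved solids go
  through the first-order-accurate voxel backend.
* The regionalized EMPTY rule is extended to cubes with a single surviving
  training fragment (no spread is definable); this is a convention, and it
  makes such cubes aggressive (categorically significant) rather than
  silent.
* Structure alignment is an input contract, not a feature: cavities built
  from structures that are not superposed are meaningless, and only frame
  consistency is checked.
* p-values are marginal; scanning many cubes or many pairs multiplies the
  family-wise error, and the reports only count the tests for the user.
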