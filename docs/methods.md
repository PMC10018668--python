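# Methods

## Statistical margin model

Translational setup error is modelled as an isotropic zero-mean 3-D normal
displacement with SD σ_S (mm), identical for every point of every target.
Rotational setup error is a small random rotation about the treatment
isocenter with per-axis SD σ_D (degrees); its positional effect at distance
*d* from the isocenter is treated as an isotropic normal displacement with SD
σ_R(d) = 0.816·(π/180)·d·σ_D mm.  The 0.816 factor maps the three rotational
degrees of freedom onto an equivalent isotropic positional SD and is taken as
given.  Requiring coverage probability α for the combined displacement gives
the per-point margin

    M(d) = χ_α √(σ_S² + σ_R(d)²),   χ_α = √(quantile of χ²(3) at α).

Assumptions worth stating explicitly: errors are random (no systematic
component, no van Herk-style Σ/σ split), isotropic per axis, and independent
between translation and rotation; the small-angle approximation sin δ ≈ δ is
used for the rotational lever arm.  χ_α and the rotational coefficient are
computed at full float precision; 2.795 (α = 0.95) and 0.01424 are their
printed roundings.  The canonical stored parameter is σ_S; the translational
margin M_S = χ_α σ_S is a derived view and the two parameterizations
round-trip losslessly.  All public units are mm and degrees.

## Targets and reference isocenters

A target carries quasi-uniform boundary samples plus its volume kᵢ, surface
area aᵢ and centroid.  Analytic spheres (all bundled phantoms) get exact
closed-form kᵢ, aᵢ and subdivided-icosahedron samples; closed triangle meshes
get signed-tetrahedron volume, triangle-sum area and divergence-theorem
centroid via trimesh; bare point clouds fall back to their convex hull with a
logged warning.  COG / COV / COS are the unweighted, kᵢ-weighted and
aᵢ-weighted means of the target centroids — per-target scalar weights, not
point-cloud integrals.

**Sampling density.**  Default 4 boundary samples per mm² of surface (the
icosphere subdivision level is the smallest meeting this).  The PTV envelope
built from sample-centred balls sags between samples by ≈ e²/(8M) for
inter-sample distance e; at 1 sample/mm² this leaves a systematic ≈ 2%
deficit in a measured 2 mm shell, at 4/mm² it is below 0.5%, which is
negligible against the 0.5 mm voxel quantization.  Density is a per-target
constructor argument for convergence studies.

**Bundled phantoms.**  Two-sphere configurations place centers 100 mm apart
on the x-axis (sweep D₁ ∈ {5, 10} × D₂ ∈ {5, 10, 20, 30, 40} mm plus the
6/15 mm pair); three-sphere configurations sit at (100,0,0), (0,100,0),
(0,0,100) mm with diameters (10,10,10), (5,10,10), (5,10,15) or (5,10,20) mm.
The six-sphere configuration fixes diameters 4–18 mm; its centers are not
fixed by any source, so this package places them symmetrically at ±100 mm on
each axis — results for that phantom characterize the method, not a published
case.

## Voxelized expansion and the objective

The PTV is the union of the CTVs and balls of radius Mᵢ(dᵢ) centred on the
boundary samples ("union-of-balls" dilation).  The margin at a point is the
radius of the isotropic coverage region for the combined random error there,
so an isotropic per-point expansion is the semantics that matches the model; a
normal-offset expansion would differ only through the (slow) tangential
variation of Mᵢ and was not implemented.  Volumes are voxel-center counts ×
spacing³ on an isotropic lattice — no partial-volume weighting; convergence
is first-order in spacing and the normalized ratios the method reports are
far less sensitive than absolute volumes.

Each target gets a local lattice sized to its extent plus the largest margin
reachable from the search region plus padding; lattices whose boxes intersect
are merged so overlapping expansions are counted once.  Lattices are anchored
to the (padded) box corner.  A centroid-anchored (symmetric) lattice was
evaluated and rejected: it makes all shell-crossing thresholds coherent, which
*triples* the staircase error of measured volumes (≈ 0.8% vs ≈ 0.1% at
0.5 mm); the corner-anchored lattice dithers the thresholds instead.
Congruent-target mirror symmetry consequently holds to that ≈ 0.1–0.5% noise
rather than exactly, which the tests account for.

The inner ball-painting loop (mark every voxel centre within rᵢ of point pᵢ)
is a numba kernel; the test-suite checks it voxel-for-voxel against a
brute-force every-voxel-against-every-ball oracle on coarse instances.

Default spacings: 1.0 mm while optimizing, 0.5 mm for all reported volumes.
At 0.5 mm, a uniformly expanded sphere's shell volume is within 1% of the
closed form, and halving the spacing changes measured margin volumes by
≈ 0.1%.

## Optimization

The search region is the axis-aligned bounding box of the target centroids
(unpadded by default; the optimum stayed inside it in every configuration
studied, although for extreme size ratios it may enter the large target).
For two targets the search restricts to the segment joining the centroids,
where the optimum lies.

* **Grid search (NSO)** evaluates every lattice/segment candidate
  (default step 1 mm) and keeps the first-encountered minimum in
  lexicographic scan order — deterministic, used for all two-target results.
* **ASA** uses Ingber's fast generating distribution with per-dimension
  temperatures T_k = T₀·exp(−c·k^(1/D)) (T₀ = 1 in box-span units, c = 1),
  Metropolis acceptance with its own annealed temperature (initialized at 10%
  of the starting objective), and reannealing every 50 accepted steps that
  rescales each dimension's temperature by the finite-difference sensitivity
  of the objective at the incumbent.  It starts from COG, is capped at 2000
  evaluations (1500 in the bundled reproductions), stops after 300
  evaluations without improvement, and is a pure function of its mandatory
  seed.  These internal defaults are this package's own choices.

The coarse-lattice winner is polished by strict-descent neighbourhood moves
on the 0.5 mm lattice, bounded to 4 rounds so voxel staircase noise cannot
walk the finalist across a flat basin.  All finalists — COG, COV, COS, the
optimizer result, optionally an extra NSO row — are then measured on the same
0.5 mm lattice and normalized to COG.  Because the optimizer's candidate set
contains the reference points (ASA starts at COG), the optimizer row reports
the best of its polished result and the references; without this, flat-basin
noise can rank the coarse minimizer a fraction of a percent above COG.

**Flat basins.**  Near-equal targets make the objective extremely flat around
the midpoint, so the *position* of the minimum is ill-conditioned at coarse
spacing even though the *value* is stable; position-based checks in the tests
use the 0.5 mm lattice and millimetre-scale bands, value-based checks are
preferred elsewhere.

## Interfaces

Cases are JSON documents (schema-validated via pydantic: spheres or mesh
paths; exactly one of m_s / sigma_s; defaults α = 0.95, ASA with seed 0,
1.0 / 0.5 mm spacings).  Run reports echo the case, the comparison rows, the
package version, seed and spacings — enough to reproduce a run bit-for-bit.
The CLI exposes `optimize`, `compare`, `sweep`, `table1`, `heatmap`,
`phantom`; exit code 2 flags validation errors, 1 runtime failures.

## What the synthetic phantoms do and do not show

All bundled configurations are analytic spheres in empty space: perfectly
known volumes/areas, no contouring noise, no slice anisotropy, convex shapes,
and (except for deliberately overlapping test cases) well-separated targets.
Passing results demonstrate the statistical model, the expansion and the
optimizers — not robustness to irregular clinical contours, whose volumes and
areas enter the same formulas through the mesh path but with their own
segmentation uncertainty.  Clinical DICOM structure sets are out of scope.

## Known limitations

* Percent reductions and normalized volumes carry ≈ 0.2–0.5% discretization
  and sampling uncertainty at the default settings; absolute volumes are
  first-order in voxel spacing.
* The margin recipe itself (coverage probability → χ_α scaling, the 0.816
  rotational factor) is taken as given and not re-derived or Monte-Carlo
  verified here.
* No organ-at-risk awareness, dose calculation, collision or couch
  constraints: the optimum is purely geometric.
* Wall-clock performance claims are hardware-bound and not reproduced; the
  problem sizes used in the bundled reproductions (1 mm optimization lattice,
  0.5 mm measurement lattice, ≤ 1500 ASA evaluations) are the package's
  default desk-scale choices.
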