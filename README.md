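# isomargin

Treatment-isocenter selection for single-isocenter multiple-target (SIMT)
cranial stereotactic radiosurgery by **nonuniform-margin volume minimization**.

When several brain metastases are treated with one machine isocenter, residual
*rotational* setup error displaces each lesion in proportion to its distance
from the isocenter, so the CTV→PTV margin needed to keep a given coverage
probability grows with that distance.  Where the isocenter is placed therefore
changes the total volume of healthy tissue swept into the PTVs — a quantity
worth minimizing, since normal-brain dose (e.g. V12Gy) predicts radionecrosis.
`isomargin` computes that margin volume for any candidate isocenter and finds
the isocenter that minimizes it, comparing the optimum against the standard
reference points.  Intended users are medical physicists and treatment-planning
researchers studying isocenter placement for multi-lesion SRS.

## Model

For a CTV boundary point at distance *d*ᵢ = ‖s⃗ᵢ − s⃗₀‖ from the isocenter s⃗₀,
the required margin under an isotropic translational setup SD σ_S (mm) and a
rotational setup SD σ_D (degrees) is

    Mᵢ = χ_α · sqrt(σ_S² + σ_R(dᵢ)²),      σ_R(d) = 0.816 · (π/180) · d · σ_D
       = sqrt(M_S² + M_R(dᵢ)²),            M_S = χ_α σ_S,

where χ_α is the square root of the α-quantile of the χ²(3) distribution
(χ₀.₉₅ ≈ 2.795) and 0.816·π/180 ≈ 0.01424 mm per mm·degree.  The PTV is the
union of the CTVs with balls of radius Mᵢ centred on their boundary samples;
the objective is the voxel-measured margin volume

    V(s⃗₀) = V_PTV(s⃗₀) − V_CTV,      s⃗̂₀ = argmin V(s⃗₀).

Candidate isocenters are compared against the center-of-geometry (COG,
unweighted centroid mean), center-of-volume (COV, kᵢ-weighted) and
center-of-surface (COS, aᵢ-weighted) reference points.  The minimum is located
by exhaustive grid search (NSO — on the segment joining two targets, or a 3-D
lattice) or by adaptive simulated annealing (ASA: fast per-dimension annealing
schedule with sensitivity-based reannealing, seeded and exactly reproducible),
followed by a fine-lattice polish.

## Worked example

Two spheres of diameter 6 mm and 15 mm, centers 100 mm apart, translational
margin M_S = 2 mm, rotational SD σ_D = 0.5°:

```
$ isomargin phantom two-6-15 > case.json    # edit sigma_d to 0.5
$ isomargin compare --case case.json
label   x_mm    y_mm    z_mm    v_margin_mm3    normalized_to_cog       evaluations
COG     50.000  0.000   0.000   2580.625        1.0000  0
COV     93.985  0.000   0.000   2508.500        0.9721  0
COS     86.207  0.000   0.000   2480.375        0.9612  0
ASA     78.202  0.000   0.000   2470.750        0.9574  422
```

Reading the table: placing the isocenter at the midpoint (COG) costs
2580.6 mm³ of margin shell; the optimizer moves it 28 mm toward the larger
lesion and cuts the margin volume by ≈ 4.3%.  The surface-weighted COS point
lands closer to the optimum than the volume-weighted COV — a general pattern
for unequal lesions.  `evaluations` counts objective calls on the coarse
optimization lattice; every row in the table is re-measured on the same
0.5 mm lattice.

Other subcommands: `optimize` (JSON run report), `sweep` (normalized volume
along the two-target segment), `table1` (the full two-sphere sweep),
`heatmap` (planar normalized-volume map as x,y,z,value text).  The same
functionality is available as a library (`isomargin.compare_isocenters`,
`isomargin.sweep_line`, ...).

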