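# orthomodel

Multi-body 3D orthodontic models from two fused imaging sensors: a
structured-light optical scanner for the tissues it sees best (tooth crowns
and gingiva) and a CBCT volume for the tissues only X-rays reach (roots and
alveolar bone). The result is a per-tooth manipulable model — each tooth a
separate closed surface, seated in a socketed bone body — of the kind used
for orthodontic treatment simulation, including cases with impacted teeth.

The package is aimed at researchers in dental image analysis: it implements
the full method and ships a synthetic-phantom generator with analytic
ground truth, so every stage can be exercised and scored without clinical
data.

## The method

1. **Optical side.** Binary stripe (Gray-code class) profilometry encodes
   `l = 2^n − 1` stripe lines in `n` projected patterns; camera rays are
   intersected with decoded light planes to triangulate points, and
   turntable views are composed from known axis rotations. Two complementary
   scans — the impression's inner surface (reaches interproximal walls) and
   the plaster cast's outer surface (sees cusp tops) — are ICP-registered
   and merged within a tolerance, then meshed by marching cubes over a
   signed-distance grid.

2. **Crown segmentation.** For every point *p* with neighbourhood
   covariance eigenvalues `λ0 ≤ λ1 ≤ λ2`, the surface variation

       δ_n(p) = λ0 / (λ0 + λ1 + λ2)   ∈ [0, 1/3]

   is a curvature-like measure (0 on planes, 1/3 for isotropic scatter);
   crowns are separated from gingiva by regions bounded by closed periodic
   cubic margin splines snapped to the δ_n ridge.

3. **CBCT side.** The optical crown model is aligned into the DICOM volume
   (≥ 3 landmarks, then ICP restricted to mating pairs within
   `δ_ε = 1 mm`), and the iso-surface threshold `τ_opt` minimizing the
   crown/iso-surface discrepancy fixes both the spatial reference and the
   segmentation threshold. Each tooth is then contoured slice by slice with
   distance-regularized level-set evolution (DRLSE), minimizing

       E(φ) = μ R_p(φ) + λ ∫ g δ(φ)|∇φ| + α ∫ g H(−φ),
       g = 1 / (1 + |∇(G_σ ∗ I)|²),

   with φ < 0 inside the contour and α > 0 shrinking a contour initialized
   outside the target. The first slice is initialized from the aligned
   crown's cross-section dilated by a disk; each converged contour seeds
   the next slice, through the root until the area vanishes — root
   branching is handled natively by the level set's topology changes.

4. **Fusion.** The optical crown is kept verbatim, the CBCT mesh
   contributes the root below the margin plane, the two are stitched across
   a seam band, bone is socketed by per-slice subtraction of the tooth
   regions, and every body can be rigidly repositioned with a collision
   report.

## Worked example

Crown-guided segmentation of one synthetic tooth:

```python
from orthomodel import phantom as ph
from orthomodel import cbct_seg as cs

jaw = ph.make_jaw_phantom([ph.ToothPhantomSpec("11")])
tooth = jaw.teeth[0]
vol, labels = ph.voxelize_phantom(jaw, (0.4, 0.4, 0.4),
                                  ph.IntensityModel(noise_sd=30, seed=0))
crown = tooth.crown_mesh(0.2)          # the "optically scanned" crown
stack = cs.segment_tooth(vol, crown_mesh_aligned=crown, tooth_id="11")
print(f"slices segmented: {len(stack.slice_indices)}")
print(f"recovered volume: {stack.volume_mm3():.1f} mm^3")
print(f"analytic volume:  {tooth.volume_mm3(0.15):.1f} mm^3")
```

prints

```
slices segmented: 48
recovered volume: 526.5 mm^3
analytic volume:  541.3 mm^3
```

i.e. the propagation walked 48 slices from the cusp tip through the root
apex and recovered the tooth volume within 3% of the phantom's analytic
value (the per-slice contours are within half a voxel of the true
cross-sections on average).

The one-shot pipeline — phantom, scans, merge, crown segmentation,
threshold sweep, per-tooth DRLSE, bone socketing, fusion, STL export — runs
from the command line:

```bash
orthomodel run-all --out output_dir
```

and writes `report.json` (per-stage metrics: ICP RMS, τ_opt, per-tooth
volumes, collision flags), one STL per body and a JSON manifest.

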