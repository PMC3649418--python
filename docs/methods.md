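# Methods

This note records the models implemented by `orthomodel`, the parameter
choices that matter, what the synthetic phantoms do and do not emulate, and
the numerical decisions taken where the design was genuinely open.

## Synthetic phantoms

Every stage is exercised on parametric jaw phantoms with analytic
membership functions, so segmentation output can be scored against exact
cross-sections and volumes rather than against another segmentation.

**Tooth geometry.** Each tooth lives in a local frame with z up and the
cemento-enamel junction (CEJ) at z = 0. The crown is a superellipsoid-type
solid: the horizontal cross-section at height z is the superellipse
`(|x|/a)^4 + (|y|/b)^4 ≤ 1 − (z/h)^3`, giving a boxy, molar-like section
that bulges near the cervix and closes at the cusp tip. Roots are tapered
circular solids. The root trunk at the CEJ carries the crown's cervical
cross-section (base radius `0.92·min(a, b)`) — real teeth do not step
abruptly inward at the cervix, and an earlier steeper design defeated the
slice-to-slice contour carry. Multi-root teeth keep a single trunk down to
the furcation (at 35% of root length) and split into branches whose centres
slide outward with depth; the cross-section's connected-component count
therefore transitions 1 → 2 (or 3) below the furcation, which is the
ground truth for the topological-split checks. Teeth are laid out on a
circular arch with a configurable interproximal gap (default 0.5 mm) and
checked pairwise for interpenetration by membership sampling.

**Tissues and intensities.** Voxelization samples membership at voxel
centres with priority tooth > bone > soft tissue > background and assigns
HU-like values (−1000 / 50 / 700 / 1500 by default, the plausible CT
ordering for air, gingiva, trabecular-ish bone and enamel/dentin lumped
together), plus i.i.d. Gaussian noise (default SD 30 HU in the study
conditions) and optional streak artifacts — additive rays through a
designated "metal" point with distance-decaying amplitude, a crude stand-in
for restoration artifacts, not a physics model. The CBCT noise model is a
stand-in generally: no projection physics, beam hardening or partial-volume
averaging (voxels are winner-takes-all at their centre). Passing tests
therefore show the pipeline's correctness and noise robustness at desk
scale, not clinical-scanner performance.

**Periodontal ligament.** The socket wall is separated from the root by a
soft-tissue gap (the periodontal ligament, with a cervical collar that
follows the crown footprint). The PDL is what makes the root/bone boundary
visible in real CBCT; its width here (1.2 mm) is wider than anatomy
(0.15–0.4 mm) because the gap must span 2–3 voxels at the 0.4 mm grid to
survive the edge-indicator's Gaussian smoothing. This is the phantom's
largest deliberate departure from anatomy.

**Surface scans.** The optically visible solid (gingiva collar plus
crowns) is meshed by marching cubes; scans are area-weighted surface
samples, backface-culled per viewing direction. Impression mode drops a
band around cusp tips (unreachable by the impression material's inner
surface); cast mode drops interproximal wall bands (optical undercuts).
Their union covers the crowns; each alone does not — the motivating
complementarity. No occlusion ray-casting is performed, only normal-based
culling.

## Structured light

Plain binary stripe coding: pattern k is bit k (MSB first) of the column
code `floor(col·2^n / l_h)`, so stripe periods halve pattern to pattern and
`2^n − 1` stripe boundaries are encoded. Decoding binarizes each pixel at
the midpoint of its own min/max across the stack (albedo-robust); pixels
without temporal modulation fall back to the global midpoint — all-bright
pixels decode to the all-ones code, all-dark pixels are masked invalid
because they cannot be told from unlit ones (this also keeps the number of
distinct valid codes at `2^n − 1`). Triangulation intersects per-pixel rays
with per-code light planes; near-parallel pairs and points outside the
working volume are masked and counted. The simulated rig is telecentric
with camera columns aligned to code-band centres on the reference plane,
which makes the render → decode → triangulate round trip exact there; on
general surfaces binary coding quantizes to a code band, so only the
band-width bound holds. Phase-shift refinement is not modelled.

## Surface model

- **ICP**: point-to-point, mutual-nearest correspondences, distance
  rejection, closed-form SVD update with reflection correction. The best
  (transform, RMS) pair seen is returned, making the reported RMS
  non-increasing in the iteration budget even though raw per-iteration RMS
  fluctuates as correspondences switch. Identity initialization is reliable
  to roughly 10–15°; larger offsets are refined from a landmark (Procrustes)
  initialization, as the clinical workflow prescribes.
- **Merging**: pairs within the merge tolerance (default 0.05 mm, the
  scanner-accuracy scale) are averaged; the rest kept verbatim.
- **Reconstruction**: signed-distance grid from oriented points (distance
  projected on the nearest sample's normal near the cloud; full distance
  with the projection's sign far away), marching cubes at the voxel pitch.
  Normals, when absent, come from covariance eigenanalysis with orientation
  propagated along a Euclidean minimum spanning tree.
- **Surface variation**: covariance of the spherical neighbourhood
  (default radius 2 mm, suited to ~0.1 mm-sampled dental scans) about its
  centroid; `δ_n = λ0/Σλ` with eigenvalues clipped at zero against
  rounding. Points with fewer than 3 neighbours are flagged undefined.
- **Crown segmentation**: each margin loop (closed periodic cubic spline,
  chord-length parameterized) is projected into its best-fit plane; the
  crown region is the surface patch flood-filled inside the (slightly
  buffered) loop polygon, with contested vertices between close neighbours
  resolved to the nearest loop, and a single absorption pass pulling in
  crease vertices whose δ_n marks the ridge. Stray islands are dropped so
  each crown is one connected shell.

## CBCT segmentation

**Spatial referencing.** Iso-surfaces by marching cubes over a threshold
grid; alignment per threshold = landmark Procrustes then ICP restricted to
mating pairs within δ_ε = 1 mm; the discrepancy is the absolute
point-to-surface distance (exact point-triangle queries over KD-tree
candidates) of crown vertices with mating pairs only. τ_opt is the lowest
threshold attaining the minimal mean discrepancy. On the phantom the
optimum lands at the half-intensity boundary threshold, as linear
interpolation in marching cubes predicts.

**DRLSE.** Standard distance-regularized form: double-well potential
`p(s)` with `d_p(s) = sinc(2s)` for `s ≤ 1` and `(s−1)/s` above, smoothed
Dirac of width ε = 1.5, replicate-inward (Neumann) borders, explicit Euler
with the stability bound μ·Δt < 1/4 enforced. Defaults: μ = 0.2, λ = 3,
α = +0.2, σ = 1.2 px, Δt = 1, up to 120 iterations per slice (150 on the
first) with an early stop when the zero level is pixel-stationary over two
10-iteration windows. λ and α were calibrated on the phantom so that the
weakest relevant edge (root against the periodontal gap) holds the contour
at equilibrium — λ = 5 with α = 0.5 lets curvature collapse small root
sections, and results then depend on where the iteration cap happens to
stop them; the chosen setting is iteration-stable. α ∈ (0, 1] (shrink) for
crown-initialized contours; the expand direction uses negative α with
magnitude above the curvature force of the target's smallest feature
(α = −1.5 in the disk tests).

**Image preconditioning.** Slice images are linearly rescaled to a 0–15
dynamic range (volume-wide min/max) before the edge indicator. The raw HU
range of thousands drives `g` to ~0 in a wide flat band around strong
edges, where neither the balloon nor the ∇g attraction can move the
contour — it stalls off the edge. Gradients of order 1–10 keep `g`
informative; this is a numerical conditioning step, `edge_indicator`
itself is the plain formula.

**Slice propagation.** The converged region is carried to the next slice
as a signed distance function shifted 1.5 px outward, so a shrink-biased
contour can follow widening cross-sections; re-binarizing the carry (the
obvious alternative) introduces step-transients that overshoot on small
sections. Components below 4 px are dropped as noise. Propagation enters
the stack at the occlusal end of the crown's slice range (the end whose
first non-empty cross-section is smaller), runs through crown and root,
stops when the zero-level area falls below 2 px, and aborts with a
diagnostic if the area more than triples between adjacent slices.
Impacted teeth — absent from the optical scan — take a manual polygon,
start slice and direction instead.

With the double-well potential, |∇φ| is maintained near 1 only in the
immediate vicinity of the zero level; regions the contour has swept
through relax to the flat (s = 0) well and plateau near ±ε. This is the
expected p2 behaviour: the regularizer's own fixed point keeps a
signed-distance band (verified in the tests), but at force equilibrium
under the full energy the band profile reflects the balance of balloon and
edge forces, not a pure signed distance.

## Fusion and manipulation

The optical crown is kept vertex-for-vertex; CBCT faces on the crown side
of the margin plane (fit to the crown's open boundary loop) are discarded
and the remaining root is stitched to the margin ring by an angle-ordered
zipper whose band is oriented radially outward. Bone is meshed from the
socketed contour stack (bone region minus all tooth regions per slice).
Collision detection is a sampled signed-distance test — a vertex of one
body more than 0.3 mm behind a facing closest triangle of another — rather
than exact booleans; the 0.3 mm depth floor is the mesh-resolution scale
and keeps crease contact between neighbouring teeth from flagging.

## Problem sizes

Tests and examples run single-to-three-tooth phantoms voxelized at 0.4 mm
(grids of roughly 30–120 voxels per axis), ~10⁵-point scans, and
10-seed repetitions for the stochastic recovery suites; these sizes keep
the full suite in the low minutes while leaving every algorithmic path
exercised. Recovery results at these sizes: tooth volume within 5% (crown
guidance from the exact crown geometry; ~12% through the full optical
reconstruction path, whose marching-cubes crown rounds the cusp tip and
margin), per-slice contours within half a voxel on average, τ_opt at the
half-intensity threshold on every tested seed.

## Known limitations

- The phantom's intensity model is assignment + noise, not CT physics;
  robustness to streaks is demonstrated only against the additive-ray
  artifact model.
- Binary-coded structured light is simulated with a telecentric rig; no
  lens distortion, radiometry or real calibration.
- The DRLSE weights are calibrated for the phantom's contrast structure;
  clinical volumes would need the same calibration against their own
  crown-discrepancy metric, as the method itself prescribes.
- Seam stitching assumes a single dominant margin loop per crown and
  roughly star-shaped rings; heavily fragmented crowns would need hole
  filling first.
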