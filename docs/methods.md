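# Methods

This note records the models implemented in `livernav`, the defaults that
matter, and the design choices made where more than one reasonable option
existed. Nothing here states a number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinate frames and transforms

All coordinates are millimetres, LPS axes; the EM tracker frame is the root
world frame. Transforms are rotation (unit quaternion, stored scalar-first)
plus translation under the column-vector convention `y = R·x + t`;
`compose(A, B)` means "B first, then A". Every transform carries mandatory
`frame_from`/`frame_to` labels that are checked when transforms are chained:
the pipeline touches at least five frames (MRI, CT, CBCT, EM, rib-relative)
and an unlabeled chain turns frame mix-ups into silent geometry errors.
Quaternion convention at the tracker interface is not standardized across
vendors; files written by this package are scalar-first, stated here and in
the I/O docstrings.

## Semi-rigid tracking model

The liver region near the surface-mounted 6-DoF sensor is treated as locally
rigid: with `pose(S)` the sensor's rigid pose in EM space, the live model
transform is `pose(S_live) ∘ pose(S_ref)⁻¹` applied on top of the static
CBCT registration. The full pose — position *and* orientation — drives the
transform; a 5-DoF sensor could not (roll unobservable), which is why the
chain refuses 5-DoF input here. A `translation_only` flag ablates the
rotational lever-arm term for comparison. The reference pose `S_ref` is the
stream sample nearest the declared CBCT acquisition time, without averaging;
averaging would reduce the snapshot noise but is deliberately not done so
that the replay matches a system that saves one pose at end of acquisition.

Guidance validity is restricted to the target navigation zone, a closed ball
of radius 50 mm (configurable) around the live sensor position; outputs
outside it carry an explicit out-of-zone flag rather than being suppressed.

## Phantom

`generate_scene(config, seed)` is a pure function; identical inputs give
bitwise-identical scenes. Default study conditions:

| structure | model | default |
|---|---|---|
| liver | ellipsoid | semi-axes (120, 80, 60) mm |
| target tumor | sphere near anterior surface | radius 12 mm |
| vessels | capsule chords in the liver | 3, radius 4 mm |
| ribs | 5 arc-tube levels, radius 140 mm | tube radius 5 mm |
| spine + sternum | stacked vertebral capsules, sternum bar | on |
| clips | 4 on the liver surface ringing the tumor at ~22° tilt | Ø2 × 3 mm |
| trackers | 3 on the chest wall, 2 discs each, 20 mm apart | discs Ø8 × 2 mm |
| liver sensor | surface point nearest the tumor | 6-DoF |

Two generator choices deserve a word. First, bone is rendered with a radial
marrow→cortical intensity ramp (700→1500) rather than a constant: masked
mutual information needs intensity structure *inside* the mask, and real
bone has it. Second, the scene includes a vertebral column and sternum:
without them the circular rib arcs leave rotation about the body axis (and
axial shift) almost unconstrained, which no real thorax does. The tracker
placement is deliberately irregular — a symmetric layout makes the six-point
correspondence ambiguous up to a flip.

Tissue intensities are constant per class (air −1000, soft 50, liver 100,
vessels 300, tumor 160, metal 3000) plus Gaussian noise (CT σ=12, CBCT σ=20,
MRI σ=15); they approximate Hounsfield units ordinally and claim no CT
physics. Metal is rasterized with signed-distance partial-volume weighting,
which is what makes sub-voxel centroid detection meaningful. The CBCT
field-of-view geometry is a fully sampled Ø250 × 200 mm cylinder; the
truncated-projection preset extends to a 350 × 350 × 200 mm box whose
outside-cylinder voxels are degraded (bias +30, noise ×5) but kept — they
are usable for high-contrast landmarks (the trackers) only, and the
truncation-consistency statistic quantifies exactly that.

### Deformation model

The scene trajectory decomposes into (a) a global rigid trajectory (whole
body, ribs included), (b) breathing, a sinusoidal cranio-caudal translation
of the liver only (default amplitude 10 mm, period 4 s; the clinical
workflow breath-holds at acquisition, reproduced by sampling at fixed
phase), and (c) a manipulation field: a sum of Gaussian-kernel displacements
(length-scale 100 mm, magnitude 10 mm by default) applied to liver
structures and attenuated by a C¹ smoothstep that is exactly zero within
30 mm of the sensor and saturates at 75 mm. Kernels are centered on the lobe
far from the sensor, reflecting where retraction and packing act relative to
the tracked target zone; this construction is what gives the TRE-vs-distance
gradient its monotone shape, and the rigid-core invariant (displacement at
the sensor < 0.1 × field magnitude) is asserted numerically in tests.

EM noise defaults to σ_pos = 0.5 mm per axis and σ_rot = 0.3° (small-angle
rotation about a random axis), a tabletop-generator vendor-class figure;
both are configurable and zero sigmas reproduce ground truth exactly.

## Registration

**Point solver.** Closed-form cross-covariance SVD (Kabsch/Umeyama) with a
determinant guard against reflections; FRE is the RMS residual. Collinearity
is detected from the singular values of the centered source matrix
(σ₂ < 1e-6 σ₁) and reported with the unconstrained axis. No per-fiducial
weighting. Correspondence between unlabeled point lists (≤ 8 points) is the
permutation minimizing post-registration FRE, exhaustively searched, ties
broken lexicographically. The solver's calibration is checked against the
analytic E[FRE²] = 3σ²(1 − 2/N) expectation by Monte Carlo.

**Volume registration.** Bone mask = intensity window [600, 1600] plus a
one-voxel morphological opening (border treated as filled so the volume edge
is not "speckle"). Initialization aligns the bone-mask centers of mass
(translation only). The MI stage runs on ITK via SimpleITK: Mattes mutual
information, 64 bins, full fixed sampling (no stochastic sampling — results
are bit-reproducible; execution is forced single-threaded so reduction order
is fixed), linear interpolation, three-level multi-resolution (shrink 4/2/1,
Gaussian smoothing 4/2/1 voxels), regular-step gradient descent (learning
rate 2.0, min step 1e-4, ≤ 200 iterations/level, relaxation 0.6). The masks
passed to the metric are dilated by 3 voxels: a mask cut exactly at the bone
boundary excludes the high-contrast bone/soft-tissue edge that carries most
of the alignment information. The final-level smoothing of 1 voxel matters
on truncated CBCT input — it averages the degraded-zone noise that otherwise
biases the metric optimum by a few tenths of a degree. ROI-restricted
registration reuses the same machinery with the ROI box as fixed mask, and a
`manual` mode passes a user transform through verbatim (with frame checks),
mirroring the interactive preoperative-model alignment of the clinical
workflow; tests use the automated surrogate.

## Detection

Metal detection is 26-connected components above a 2000 threshold (between
bone ≤ 1500 and metal 3000), size-filtered in mm³ (clips ≤ 20 mm³, discs
50–300 mm³), centers as intensity-weighted centroids in world coordinates —
weighting roughly halves the quantization error of binary centroids.
Grouping the six disc detections into three trackers minimizes the summed
deviation of intra-pair distances from the configured 20 mm over all
3-disjoint-pair selections. Truncation QC matches detections from the
fully sampled and truncated reconstructions and reports raw per-center
displacement (no alignment — both live in the scanner frame).

## Accuracy statistics

The clip audit pairs the navigation distance (exact point-to-tumor-surface
distance through the live chain; k-d-tree-pruned exact point-triangle
minimum, 0 inside) against the image distance (mesh mode, or segmentation
boundary voxel centers in mask mode — the reproducible surrogate for an
observer judging the visible tumor edge). Reported: mean ± sample SD of
|d_nav − d_img|, Pearson r with two-sided p from the t-distribution (n−2
df); zero-variance input flags the correlation as undefined instead of
fabricating one. Observers are emulated as independent additive Gaussian
jitter (default σ = 1 mm, 3 observers). Repeat variability is the per-point
range (max − min) and its mean. TRE profiles bin ‖located − true‖ by each
point's snapshot distance from the sensor (bins 0–25/25–50/50–100/>100 mm).

## Problem sizes and numerical notes

Registration-study volumes are rendered at 2.5 mm spacing (CT ~1.6 M voxels)
and the pipeline CBCT at 1.2 mm — coarse enough to run on one CPU in
minutes, fine enough that every claim is tested at sub-voxel resolution; the
detection study uses the 0.66 mm clinical reconstruction grid on small local
volumes. Success tolerances in the MI study are quoted in voxels of the
render actually used. Random number use is seeded everywhere; every
generator, render, noise stream and study derives its seeds from one
integer.

## What the phantom does and does not show

Passing tests demonstrate that the *computational chain* is correct and
calibrated: exact under rigid motion, noise-floor-limited under EM noise,
and degrading away from the sensor exactly as the attenuated deformation
field dictates. The phantom's deformation is synthetic and its tissue
contrast idealized, so these results do not certify clinical accuracy on
patients — organ deformation fields, contrast washout, metal artifacts and
segmentation error are all outside the model. The clinical headline numbers
of such systems are produced from patient data that has no reproducible
ground truth; this package instead makes every quantity it reports exactly
measurable, which is the property a phantom can and should add.

## Known limitations

* Rigid transforms only; no deformable registration or biomechanical model.
* No projection-domain CBCT simulation; FOV truncation is emulated on the
  reconstructed grid.
* Mesh deformation displaces vertices (and capsule endpoints), so strongly
  bent vessels are approximated piecewise.
* The exhaustive correspondence search is limited to 8 points by design.
* One target zone per run; multi-target navigation is out of scope.
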