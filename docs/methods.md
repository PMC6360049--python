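# Methods

This note records the models, parameter choices and numerical conventions
behind `hkemidif`, and what the synthetic study can and cannot say about
real acquisitions.

## Image model and reconstruction

All four algorithms are instances of one ordered-subsets EM update on
kernel coefficients α, with the activity image λ = Kα:

    α ← α / (Kᵀ Aᵀ 1) ⊙ Kᵀ Aᵀ ( y / (A K α + s) )

- **A** is the attenuated subset projector: a parallel-beam 2-D (or
  slice-wise thin-slab) system matrix with per-bin attenuation factors
  folded into its rows. The matrix is materialised sparsely from
  interpolating line integrals — rays sampled at half the voxel size with
  bilinear weights — so the back projector is the exact transpose and the
  EM monotonicity properties hold to machine precision. A desk-scale
  parallel-beam geometry stands in for a clinical cylindrical scanner: the
  update is written for a generic system matrix, so the algorithm
  comparison does not depend on the scanner geometry. Normalisation
  factors are identically 1 in simulation.
- **y** are the prompts; **s** is the additive randoms + scatter term in
  measurement space. s enters the forward model only — it is never
  subtracted from the data, preserving the multiplicative (nonnegative)
  form of the update.
- **K** is the identity for OSEM; the anatomical kernel for KEM (fixed
  throughout); and the hybrid product kernel for HKEM, rebuilt at every
  subiteration from the current λ. OSEM+G is the OSEM output followed once
  by a 3 mm FWHM separable Gaussian (σ_vox = FWHM / (2√(2 ln 2)·spacing),
  reflective boundary) — so OSEM and OSEM+G share their iterations.

Iteration protocol: 21 subsets (interleaved angle partition, fixed natural
order — no randomisation, for bitwise determinism) × 10 iterations,
uniform initial image of 1.0. Zero-sensitivity voxels are pinned to 0; the
forward-model denominator is floored at 1e-20 before the data ratio.

### Kernel construction

Per voxel j, weights over the full (2r+1)-cube neighbourhood (27 voxels in
3-D, its 9-voxel in-plane section on single-slice grids; self included):

    k_fj = exp(−(v_f − v_j)²/2σ_m²) · exp(−‖x_f − x_j‖²/2σ_dm²)     (MR part)
    k_fj⁽ⁿ⁾ = k_m · exp(−(z_f⁽ⁿ⁾ − z_j⁽ⁿ⁾)²/2σ_p²) · exp(−‖x_f − x_j‖²/2σ_dp²)   (hybrid)

Defaults σ_m = σ_p = 1, σ_dm = σ_dp = 3. Distances are in voxel-index
units (an `axial_scale` option stretches the slice axis on anisotropic
grids). Features are scalar per voxel; both the anatomical image and the
PET iterate are standardised to zero mean / unit variance over the body
mask so that σ = 1 is meaningful regardless of image scale. A constant
iterate (the uniform initial image) has no intensity scale; its features
are defined as all-zero, so the first PET component is the pure distance
factor. Out-of-image neighbours are dropped.

**Row normalisation (design choice).** The builder functions return the
raw Gaussian weights; during reconstruction each voxel's weights are by
default normalised to unit sum, making λ_j a convex combination of
neighbouring coefficients. With raw weights the iterate-dependent hybrid
kernel is unstable at low counts: a noise spike decouples its voxel from
the neighbourhood (its PET-similarity weights vanish), the kernel degenerates
to the identity there, and the spike grows unchecked — we measured
peak-frame ROI biases from −29 % to +178 % across seeds, with the 75 %-max
ROI collapsing to 1–3 voxels. Normalisation removes the representation's
scale freedom per voxel and bounds λ by the local coefficient range, and
with it KEM and HKEM are stable across seeds. The unnormalised mode is
kept as an option (`normalise_rows=False`) for comparison.

**HKEM update cadence and output.** The PET component is rebuilt every
subiteration (a per-full-iteration option exists). The final image is
λ = Kα with the kernel used in the last subiteration; rebuilding the
kernel from the output would be circular (K needs λ, λ needs K).

## Synthetic phantom and acquisition

The phantom is a single-slice (optionally thin-slab) labelled scene at
1.56 mm in-plane spacing: a soft-tissue body disc, one large and one
mid-sized organ, and a 5 mm-diameter "aorta" (3 voxels across, 9 voxels in
cross-section) — deliberately at the scanner-resolution scale so the ROI
mean is PVE-limited. The guidance image is piecewise constant per tissue
plus Gaussian noise (σ = 0.05 on intensities in [0.3, 1.0]) to emulate MR
texture; the attenuation map is water-like (0.0096 mm⁻¹) in the body, 0 in
air.

Time-activity curves, kBq/mL vs seconds: blood follows a Feng-style
tri-exponential-times-ramp input function (peak ≈ 46 kBq/mL at ≈ 17 s,
decaying to ≈ 5 kBq/mL by the end of the study); tissues follow
mono-exponential saturation (kidney 25 kBq/mL plateau, τ = 250 s; stomach
6, τ = 700 s; background 3, τ = 900 s). No radioactive decay term is
modelled separately; decay is considered folded into the curve parameters.
Frames follow the 45-frame schedule 17×6, 4×15, 4×30, 4×60, 4×180,
12×300 s (4842 s total). Voxel values are the frame-averaged activity
(trapezoid rule at 0.1 s — the early 6 s frames change quickly), so the
aorta ROI mean of the noiseless phantom equals the frame-averaged blood
curve exactly, which is the bias reference A_k^T.

Per frame: trues = attenuation ⊙ forward-projection × (counts_scale ×
duration); randoms = a uniform sinogram holding exactly 20 % of the trues;
scatter = a broad radial Gaussian blur of the trues (σ = 5 bins) rescaled
to 15 % of the trues; prompts = Poisson(trues + randoms + scatter). The
additive term given to reconstruction is the noiseless randoms + scatter —
the idealised perfect correction of a simulation study. Ten realisations
differ only in the Poisson draws; per-(realisation, frame) seeds derive
deterministically from the base seed (base·10⁴ + realisation·10² + frame).

**Count calibration.** `counts_scale` (default 0.03 counts per
kBq/mL·mm·s; ≈ 7×10³ trues in the peak 6 s frame, ≈ 4.4×10⁶ over the whole
study) is the one free parameter of the acquisition model. It was set so
that the plain-OSEM aorta ROI operates in the high-noise regime where
short-frame IDIF estimation is actually hard (pooled CoV in the tens of
percent) while the 75 %-max ROI extraction remains workable; at much
higher counts all methods trivially agree, and at a few-fold lower counts
the OSEM ROI collapses to 1–2 voxels and its bias explodes past the
postfiltered variant, inverting the qualitative comparison the study is
about.

## ROI and figures of merit

One ROI per (algorithm, realisation): the anatomical aorta segment masks
the algorithm's own reconstruction at its peak-activity frame (highest
segment mean), and voxels ≥ 0.75 × the masked maximum are kept (ties
included). The same ROI is then applied to all 45 frames. Alternatives
(`roi_source`): the HKEM-derived ROI for every algorithm, or the raw
anatomical segment. Per frame: ROI mean, signed percent bias against
A_k^T, percent CoV (sample SD / mean over ROI voxels; undefined and
recorded as missing when the ROI has < 2 voxels or a zero mean). Study
summaries pool |bias| and CoV over the flat frame × realisation grid
(mean/max/min); a peak-frame-only summary reports, at the true-curve peak
frame (fixed across algorithms for comparability), the bias of the
realisation-mean and the CoV across realisation means.

## Problem sizes and numerical conventions

The default study runs a 96×96 grid (1.56 mm voxels), 96 projection
angles, 137 radial bins, 45 frames, 10 realisations — sized so the full
four-algorithm comparison completes in minutes on one CPU. Voxel centres
sit at (index + 0.5)·spacing; angles span [0, π); the radial FOV covers
the grid diagonal, so no voxel is outside coverage. The subset partition
is interleaved and fixed. All randomness flows through seeded NumPy
generators; reconstruction itself contains none, so identical inputs give
bitwise-identical images.

Ground-truth recovery: with noiseless prompts at high counts, the HKEM
IDIF recovers the true curve per frame to < 0.5 % by 30 iterations
(< 0.1 % by 60) — the PVE floor of this geometry with the guided ROI is
effectively nil because guidance edges coincide exactly with activity
edges. At the routine 10 iterations the late frames still carry a −2.0 to
−2.4 % EM convergence residual; the recovery acceptance check therefore
runs at 30 iterations, measuring the floor rather than convergence speed.

## What the phantom does not capture

- **Spatial heterogeneity of the real ROI.** Real aorta ROI voxels differ
  systematically (vessel geometry, orientation, axial PVE, motion,
  registration error), giving the published per-frame CoV a large
  noise-independent floor. The piecewise-constant phantom has no such
  floor, so its pooled OSEM CoV (~25 %) reflects Poisson noise alone and
  sits well below values reported for real-anatomy studies (~50 %); the
  CoV *ratios* between algorithms, not their absolute level, are the
  meaningful comparison here.
- Anatomy is geometric primitives; there is no mismatch between guidance
  and activity edges, no MR bias field, no PET/MR misregistration — so
  kernel methods are seen at their best. No motion, no decay, no detector
  normalisation non-uniformity, no dead time.
- Scatter is a calibrated smooth surrogate (radial Gaussian of the trues),
  not a physical single-scatter simulation; randoms are exactly uniform.
  Both are "corrected" perfectly, so bias from imperfect corrections is
  out of scope.
- 2-D parallel-beam geometry: axial PVE and oblique-ray effects of a
  cylindrical 3-D scanner are absent (the thin-slab mode exercises the
  3-D kernel, still with slice-wise projection).

Passing tests therefore demonstrate the algorithmic claims — relative
accuracy/noise behaviour of OSEM, OSEM+G, KEM and HKEM under Poisson
statistics with a resolution-sized target — not absolute performance on
any particular scanner.
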