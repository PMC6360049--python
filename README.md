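# hkemidif

Anatomically guided kernelised-EM PET reconstruction and image-derived
input-function (IDIF) estimation, with a self-contained dynamic-PET
simulation study.

## The problem

Kinetic modelling of dynamic PET needs the arterial input function — the
tracer concentration in arterial blood over time. Estimating it from an
aorta ROI in the images (the IDIF) avoids invasive arterial sampling, but
in small animals the aorta diameter (~5 mm) is on the order of the scanner
resolution, so the partial volume effect (PVE) biases the ROI mean, and the
very short early frames needed to catch the bolus peak are extremely noisy.

This package implements and compares four reconstructions of the same
dynamic data:

- **OSEM** — ordered-subsets expectation maximisation (the clinical default);
- **OSEM+G** — OSEM followed by a 3 mm FWHM Gaussian postfilter;
- **KEM** — kernelised EM guided by a coregistered anatomical (MR-like)
  image;
- **HKEM** — hybrid KEM, whose kernel combines the anatomical component
  with a PET component recomputed from the current iterate at every
  subiteration.

The kernel methods write the activity image as a kernel expansion

    λ_j = Σ_f α_f k_fj ,        k_fj = k_m(v_f, v_j) · k_p(z_f⁽ⁿ⁾, z_j⁽ⁿ⁾)

where, over each voxel's 3×3(×3) neighbourhood,

    k_m(v_f, v_j) = exp(−(v_f − v_j)² / 2σ_m²) · exp(−‖x_f − x_j‖² / 2σ_dm²)

with v the standardised anatomical-image intensities, x voxel coordinates,
and k_p of the same form built from the standardised current PET iterate z⁽ⁿ⁾
(HKEM only; KEM drops it). The EM update acts on the coefficients α:

    α⁽ⁿ⁺¹⁾ = α⁽ⁿ⁾ / (Kᵀ Aᵀ 1) ⊙ Kᵀ Aᵀ ( y / (A K α⁽ⁿ⁾ + s) )

with A the attenuated subset projector, y the prompts and s the additive
(randoms + scatter) term. Defaults follow the routine protocol: 21 subsets,
10 iterations, σ_m = σ_p = 1, σ_dm = σ_dp = 3, 27-voxel neighbourhood.

The aorta ROI is extracted by masking the reconstruction at its
peak-activity frame with the anatomical aorta segment and keeping voxels
≥ 75 % of the masked maximum, discarding the PVE-dominated rim. Figures of
merit per frame k: ROI mean t_k, percent bias 100·(t_k − A_k^T)/A_k^T
against the known true blood activity, and percent CoV (sample SD / mean
over ROI voxels).

No external data are needed: a synthetic phantom module generates the
anatomy (a ~3-voxel-wide aorta inside larger organs), blood and tissue
time-activity curves, a 45-frame schedule (17×6 s, 4×15 s, 4×30 s, 4×60 s,
4×180 s, 12×300 s), and Poisson-noisy sinograms with attenuation, 20 %
uniform randoms and a smooth scatter term.

## Worked example

Reconstruct one noisy realisation of the peak frame and extract the IDIF
value:

```python
import numpy as np
from hkemidif import (PhantomConfig, TissueTACTable, make_phantom,
                      make_frame_scheme, sample_activity_image, true_curve,
                      Geometry, SystemModel, ReconSettings, reconstruct,
                      simulate_frame, normalise_features, extract_roi,
                      roi_mean)

cfg = PhantomConfig(grid_size=96)
labels, mu, guidance = make_phantom(cfg)
scheme = make_frame_scheme()                  # 45 frames, 4842 s
tacs = TissueTACTable.default()
truth = true_curve(tacs, scheme)              # true aorta activity per frame
k = int(np.argmax(truth))                     # peak frame

activity = sample_activity_image(labels, tacs, scheme[k])
geom = Geometry(n_angles=96, grid_shape=labels.labels.shape,
                voxel_size_mm=cfg.voxel_size_mm)
frame = simulate_frame(activity, mu, geom, scheme[k], seed=4)

system = SystemModel(geom, mu.values, n_subsets=21)
feats = normalise_features(guidance, labels.body_mask)
lam = reconstruct(frame.prompts, frame.additive, system,
                  ReconSettings(algorithm="hkem"),
                  guidance_features=feats, body_mask=labels.body_mask)
lam /= frame.counts_scale * scheme[k][1]      # counts -> kBq/mL

roi = extract_roi(labels.mask("aorta"), lam)
idif = roi_mean(roi, lam)
print(f"true {truth[k]:.2f} kBq/mL, IDIF {idif:.2f} kBq/mL, "
      f"bias {100 * (idif - truth[k]) / truth[k]:+.1f}% ({roi.n_voxels} voxels)")
```

Output:

```
true 45.59 kBq/mL, IDIF 44.06 kBq/mL, bias -3.4% (9 voxels)
```

i.e. at the bolus peak — a 6 s frame holding only ~7×10³ true counts, the
noisiest point of the study — the HKEM ROI mean recovers the true blood
activity to within a few percent on this realisation, using the full
9-voxel aorta cross-section; single noisy frames scatter around the truth,
which is why the study pools 45 frames × 10 realisations. The same
pipeline over the full grid is driven by the CLI:

```
hkemidif run --seed 1 --out study_out
hkemidif report study_out
```

which writes the pooled |bias| / CoV tables (`metrics.tsv`,
`metrics_peak_frame.tsv`), per-realisation IDIF curves, the simulated
sinograms (HDF5) and the phantom images (NIfTI).

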