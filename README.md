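# dcflow

Desk-scale **diffuse correlation tomography (DCT)** of breast microvascular
blood flow, end to end and fully synthetic: no instrument or clinical data
required.

DCT measures blood flow by shining long-coherence near-infrared light into
tissue and watching the speckle pattern decorrelate as red blood cells move.
Each source–detector (S-D) fiber pair on the probe yields a normalized
intensity autocorrelation g₂(τ), related to the field autocorrelation by the
Siegert relation g₂ = 1 + β|g₁|². The decay of g₁ encodes the blood flow
index αD_B (cm²/s) along the photon paths between that pair. From 48 such
curves, DCT reconstructs a 3-D flow image of an 8×8×3 cm³ tissue slab, and a
classifier decides whether the imaged lesion looks benign or malignant.

`dcflow` implements the whole chain for simulation studies:

1. **phantom** — voxelized breast slab (16×16×6 voxels of 0.5 cm), a
   concentric-circle probe (8 sources, 6 detectors, separations 2–4 cm), and
   labeled cohorts of lesion phantoms with clinically anchored size priors
   (benign 11.4±8.4 mm, malignant 20.4±9.7 mm) and flow contrasts.
2. **photon_mc** — voxel Monte Carlo photon transport (numba kernel,
   bitwise-reproducible RNG) recording, per detected photon, its weight
   w(q,m,j) and per-voxel path lengths s(i,q,m,j). Validated against the
   semi-infinite diffusion-theory dipole to within a few percent.
3. **forward_dcs** — the exact forward model
   g₁(m,j,τ) = Σ_q w(q,m,j)·exp(−2τ Σ_i k₀² αD_B(i) s(i,q,m,j) μ_s′(i)),
   the Siegert transform, additive measurement noise, and the instrument's
   acquisition schedule (8 switch positions × 6 detectors × 15 s at 1 Hz =
   720 raw curves in 2 minutes, averaged to 48).
4. **nldct** — N-th order linear DCT reconstruction: the first-order Taylor
   linearization 1 − g₁ ≈ τ·(A αD_B) with
   A[(m,j), i] = 2 k₀²(i) μ_s′(i) Σ_q w s, optional higher-order data
   correction, and split-Bregman total-variation inversion
   min ‖αD_B‖_TV + (μ/2)‖A αD_B − b‖² s.t. αD_B ≥ 0, followed by
   normalization to the relative BFI (rBFI, volume mean 1).
5. **imaging** — the classification image chain: 16×16 slice at depth
   0.5–1.0 cm → 150×150 nearest-neighbor upsample → diverging cool-warm RGB
   → 8-bit TIFF → 3×224×224 cubic resize.
6. **features** — 12 rBFI image features (first-order statistics, GLCM
   texture, histogram entropy, FWHM-threshold flow segmentation) plus PCA.
7. **classify** — grid-searched RBF-SVM with five-fold CV and Platt-scaled
   probabilities, 20 repeated stratified 39/20 splits, six evaluation
   metrics (accuracy, sensitivity, specificity, AUC-ROC, AUC-PR,
   Hosmer–Lemeshow calibration p), rank-sum aggregate scoring, and
   random-forest feature importance.

## Worked example

Simulate one patient with a 12 mm, 10× flow-contrast lesion centered under
the probe, acquire noisy curves, reconstruct, and extract features:

```python
import numpy as np
from dcflow import (
    VoxelGrid, OpticalProperties, make_probe, make_phantom, LesionSpec,
    MonteCarloConfig, run_monte_carlo, simulate_acquisition, NoiseConfig,
    reconstruct, compute_features,
)
from dcflow.imaging import take_slice

grid, optics, probe = VoxelGrid(), OpticalProperties(), make_probe()
sens = run_monte_carlo(grid, optics, probe, MonteCarloConfig(n_photons=100_000, seed=1))

lesion = LesionSpec(center=(4.25, 4.25, 0.75), diameter=1.2, contrast=10.0)
phantom = make_phantom(grid, background_bfi=4.5e-8, lesions=[lesion], seed=2)

frame = simulate_acquisition(sens, phantom, optics, noise=NoiseConfig(5e-3), seed=3)
rbfi, diag = reconstruct(frame, sens, optics)

slice_z2 = take_slice(rbfi, layer=2)
iy, ix = np.unravel_index(slice_z2.argmax(), slice_z2.shape)
print(f"averaged curves: {len(frame.curves)} (raw {len(frame.curves) * frame.raw_count})")
print(f"rBFI peak {slice_z2.max():.2f} at voxel (ix={ix}, iy={iy}); "
      f"volume mean {rbfi.values.mean():.3f}")
fv = compute_features(slice_z2)
print(f"maximum {fv.maximum:.2f}  variance {fv.variance:.3f}  "
      f"textural_contrast {fv.textural_contrast:.2f}  mean_above_fwhm {fv.mean_above_fwhm:.2f}")
```

Output:

```
averaged curves: 48 (raw 720)
rBFI peak 8.90 at voxel (ix=9, iy=8); volume mean 1.000
maximum 8.90  variance 0.743  textural_contrast 3.49  mean_above_fwhm 8.64
```

The lesion's true center sits in voxel (8, 8) of the z=2 slice; the
reconstruction localizes it to within one voxel and recovers most of the 10×
flow contrast (peak 8.9), with the TV prior keeping the background flat
(volume mean is 1 by construction of the rBFI).

The same chain is scriptable from a shell via the `dcflow` CLI
(`simulate-cohort`, `mc`, `acquire`, `reconstruct`, `render`, `featurize`,
`classify`, `importance`); run `dcflow --help`.

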