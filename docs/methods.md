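# Methods

This note documents the models, numerical choices, and defaults behind
`dcflow`, and what the synthetic experiments do and do not demonstrate.

## Tissue model and optics

The measurement volume is a rectangular slab, 8×8×3 cm³, discretized into
16×16×6 voxels of 0.5 cm edge — the volume probed by a handheld 8×8 cm²
optical patch at penetration depths up to 3 cm. Optics are homogeneous at
breast-like values: reduced scattering μ_s′ = 8.0 cm⁻¹, absorption
μ_a = 0.05 cm⁻¹, refractive index 1.37, anisotropy g = 0.9. The wavelength
defaults to 785 nm (a standard long-coherence DCS laser line; it enters only
through k₀ = 2πn/λ, a uniform scale factor of the linear system). Voxels are
indexed (ix, iy, iz) with iz increasing with depth; the linear index is
iz·nx·ny + iy·nx + ix. Depth layer "z=2" (1-based) is iz = 1, covering
0.5–1.0 cm — the band where sub-surface reflectance imaging is most
accurate, and the slice used for classification.

## Probe geometry

No fiber coordinates are standard for a concentric-circle S-D array, so the
default places 8 sources on a circle of radius 3.0 cm (45° spacing) and 6
detectors on a circle of radius 1.0 cm (60° spacing), both centered on the
probe face. The resulting 48 pair separations span 2–4 cm, which maximizes
sensitivity at the imaged 5–10 mm depth band. Everything is configurable.

## Monte Carlo transport

Photons launch downward at each source and random-walk with exponential
step lengths. Default transport uses the similarity relation — isotropic
scattering at μ_s = μ_s′ — which is accurate in the diffusive regime and an
order of magnitude faster than anisotropic transport; a Henyey–Greenstein
mode (g = 0.9, μ_s = μ_s′/(1−g) = 80 cm⁻¹) is available for comparison.
Boundaries are index-matched (no Fresnel reflection): boundary reflections
perturb absolute reflectance but are second-order for the *relative*
sensitivities the reconstruction uses. Absorption is carried analytically as
w = exp(−μ_a·L) (microscopic Beer–Lambert, no roulette), so path-length
statistics are unbiased. A photon exiting the top face within 0.25 cm (half
a voxel edge) of a detector center, at any angle, is recorded for that pair;
side and bottom exits are lost; paths are capped at 100 cm. Voxel traversal
uses an exact 3-D DDA, so the per-voxel path lengths of a photon sum to its
total path to machine precision.

Randomness comes from an explicit xorshift64* generator seeded per source
via splitmix64, making runs bitwise-reproducible across platforms and
library versions.

Per-pair records keep the normalized photon weights (Σ_q w = 1), the sparse
per-voxel path lengths, and the unnormalized detected-weight sum, from
which absolute reflectance is recovered.

**Validation.** The detected reflectance is checked against the closed-form
semi-infinite diffusion dipole (isotropic source at z₀ = 1/(μ_a+μ_s′),
extrapolated boundary z_b = 2D, A = 1). Because the default probe slab is
finite and its sources sit 1 cm from the lateral edge, the check runs in a
dedicated near-semi-infinite geometry: a 22×22×12 cm slab, one central
source, and rings of detector discs at separations 2–4 cm. The closed form
is averaged over the detector aperture before comparison, since the Monte
Carlo observable is aperture-averaged. With 10⁶ photons the agreement is
within ~4–8% at all separations ≥ 2 cm.

## Forward correlation model and acquisition

The exact forward model treats each detected photon as an independent
decorrelation channel:

g₁(m,j,τ) = Σ_q w(q,m,j) · exp(−2τ·B_q),
B_q = k₀² μ_s′ Σ_i αD_B(i) s(i,q,m,j).

g₂ follows from the Siegert relation with coherence factor β = 0.5, the
typical value for single-mode-fiber detection (the β only scales the
synthetic g₂ noise path; the pipeline inverts it exactly).

Measurement noise is additive Gaussian per delay bin on g₂ (default
σ = 5×10⁻³), clipped to g₂ ≥ 1 — the simplest seedable stand-in for
photon-counting and physiological noise. The acquisition simulator emulates
the instrument schedule: the optical switch steps through the 8 sources;
each 15-s dwell records the 6 parallel detectors at 1 Hz, giving
6×8×15 = 720 raw curves in 120 s. The 15 curves per pair are
Siegert-inverted and then averaged into one g₁ curve per pair (averaging
curves rather than per-second fits: with a shared τ grid the two commute at
first order, and curve averaging uses all delay bins). The delay grid is
geometric, 64 points from 10⁻⁷ to 10⁻¹ s.

## NL-DCT reconstruction

**Slope extraction.** The first-order model predicts 1 − g₁ ≈ τ·b with
b = (A αD_B) for that pair. The decay is a photon-weighted mixture of
exponentials, so any finite-τ fit of a straight line is biased low by
curvature. The slope is therefore fitted as a through-origin quadratic
b·τ + c·τ² with 1/τ² weighting (each point contributes its ratio
(1−g₁)/τ), over the window where the raw decay 1 − g₁ < 0.3 (0.6 for
higher orders). The weighting anchors the estimate to early delays — an
unweighted fit on a geometric ladder is dominated by the largest τ in the
window — and the quadratic term absorbs the leading curvature; together
they keep ‖A·αD_B_true − b‖/‖b‖ below ~1% on noiseless data, where a plain
unweighted linear fit at the same window is ~15% biased.

**System.** A[(m,j), i] = 2 k₀²(i) μ_s′(i) Σ_q w(q,m,j) s(i,q,m,j), with
both sides of the Taylor identity negated so A, b, αD_B are all
nonnegative. Pairs with no detected photons or too few fit points are
dropped, not imputed.

**Higher orders (N > 1).** The order-2..N Taylor terms, evaluated per
photon from a current flow estimate, are added to 1 − g₁ before slope
extraction ((1−g₁) + Σ_{k=2..N} Σ_q w_q (−2B_qτ)^k/k! = τ·b + O(τ^{N+1})),
inside a fixed-point loop seeded by the first-order solution (5 outer
iterations, relative-change tolerance 10⁻³, divergence guard returning the
best iterate). The update scheme is a package design choice: the truncation
identity fixes what to subtract but not how to iterate.

**Inversion.** min ‖x‖_TV + (μ/2)‖Ax − b‖² s.t. x ≥ 0, with anisotropic
3-D TV (forward differences, reflecting boundaries), solved by split
Bregman. The problem is rescaled internally so the unknown is order unity
(units of the homogeneous least-squares fit) and ‖b‖ = 1, making μ
transferable across phantoms. The x-update solves
(μAᵀA + λDᵀD)x = rhs by a dense Cholesky factorization computed once per
solve (n = 1536), followed by projection onto x ≥ 0; the d-update is the
usual soft shrinkage. A backtracking safeguard accepts the x-update only
along a segment (toward the previous iterate) on which the convex
objective does not increase, so the recorded objective is non-increasing
by construction; in practice the safeguard triggers rarely and costs a few
matrix-vector products.

μ = 3×10⁴ and λ = 1 were calibrated once on a calibration pair — a
homogeneous slab (must reconstruct flat to <10⁻³) and a 12 mm 10×-contrast
inclusion (must localize to one voxel with monotone recovered contrast
across 2×/5×/10×) — and then frozen. Defaults: 50 Bregman iterations,
relative-change stop at 10⁻⁵.

**Normalization.** αD_B* is divided by its volume mean, giving the
dimensionless rBFI with mean exactly 1. This removes inter-subject flow
scale and leaves spatial structure, which is what the classifier consumes.

## Image chain and features

The classification image is the 16×16 rBFI slice at depth layer 2,
upsampled to 150×150 by nearest neighbor (output pixel (r,c) takes input
pixel ⌊(r+½)·16/150⌋ — no values invented), mapped through a 256-entry
diverging cool-warm table (blue (0.231, 0.298, 0.753) → near-white
(0.865, 0.865, 0.865) → red (0.706, 0.016, 0.150), linear interpolation,
per-image min-max scaling; a constant image maps to the cool endpoint),
written as 8-bit TIFF, and resized to 224×224 with cubic interpolation and
antialiasing — the 3×224×224 tensor standard CNN classifiers expect. Note
the table's channels are individually non-monotone (brightness peaks at the
midpoint); warmth (R − B) is the monotone axis.

Features are computed on the 16×16 grayscale slice, not the RGB render —
the render is a lossy visualization of the same data. The 12 features:
maximum, minimum, population variance, coefficient of variation (population
σ/mean), range, Fisher–Pearson skewness (0 for a constant image),
interquartile range (linear-interpolation quartiles), GLCM contrast and
energy (angular second moment; 16 min-max gray levels, unit offset,
symmetric, averaged over 0°/45°/90°/135° — the standard Haralick setup),
base-2 Shannon entropy of the 16-bin min-max histogram, the FWHM threshold
(min + range/2), and the mean of pixels strictly above it (the threshold
itself if none). PCA (fitted on z-scored training features only) reduces to
2 components where fusion-style inputs are needed.

Because the GLCM and entropy use per-image min-max quantization they are
scale-invariant: on raw phantoms they quantize background texture to full
range and carry no lesion signal. They become informative on *reconstructed*
images, where the TV prior flattens benign backgrounds — which is why the
malignant-vs-benign direction checks run on pipeline output.

## Classification protocol

RBF-kernel SVM on z-scored features. (C, γ) are grid-searched on the
LIBSVM-style log₂ lattice C ∈ 2⁻⁵..2¹⁵, γ ∈ 2⁻¹⁵..2³ (step 2²) by mean
stratified five-fold CV accuracy, ties broken toward smaller C then smaller
γ; the winner is refit with Platt-style sigmoid calibration fitted within
training folds. The experiment repeats 20 random stratified splits — train
11 malignant + 28 benign, test 10 + 10, mirroring a 59-subject cohort —
with replication r seeded as base_seed + r (recorded in the report).

Metrics: accuracy, sensitivity (malignant = positive), specificity,
trapezoidal AUC-ROC, AUC-PR (trapezoid on the precision-recall curve), and
the Hosmer–Lemeshow p with 10 probability-decile groups. For
model-predicted probabilities the χ² uses g−2 degrees of freedom (the
development-data convention); for externally specified probabilities (e.g.
a simulated calibrated null) the correct reference is χ²(g), exposed via
`df_reduction=0` — with g−2 the calibrated null over-rejects (~13% at the
5% level vs ~5% with g df).

The aggregate score ranks models per metric in descending order (all six
treated as higher-is-better, including calibration p), scoring 10 for the
top distinct value and one less per dense rank, ties sharing; a model's
aggregate is the sum, so six metrics give a maximum of 60. Random-forest
importances use 500 trees with the entropy (information-gain) criterion,
normalized to sum to 1.

## Synthetic cohort

The generator emulates a 59-subject study: 38 benign-like and 21
malignant-like single-lesion phantoms. Lesion diameters draw from truncated
normals matching reported size statistics — benign N(11.4, 8.4) mm,
malignant N(20.4, 9.7) mm, truncated to [3, 40] mm (and capped at the slab
depth minus 1 mm, since a sphere must fit the 30 mm slab). Flow contrast
over the healthy-breast background of 4.5×10⁻⁸ cm²/s draws from U(2, 5)
for benign and U(5, 15) for malignant (malignant lesions reach the
literature's >10× contrast); within-lesion heterogeneity is mean-preserving
lognormal texture, σ = 0.1 (benign) vs 0.4 (malignant), reflecting the
higher flow magnitude *and* heterogeneity of malignant lesions. Lesion
centers fall under the probe in the imaged depth band. Overlapping lesions
resolve by maximum contrast. All cohort randomness flows through one seeded
generator.

**What passing tests show — and don't.** The cohort encodes the qualitative
clinical contrasts (size, magnitude, heterogeneity) as clean priors; real
breast data add optical-property variability, curved anatomy, probe-contact
and motion artifacts, and class overlap far beyond these priors. The
end-to-end classification accuracy on this cohort (typically ~88–95% over
20 splits at 10⁵ photons/source) therefore demonstrates that the pipeline
is information-preserving and the protocol is correctly wired — not that
any clinical accuracy is reproduced.

## Problem sizes and determinism

Default study sizes: 10⁵ photons per source for imaging and cohort work
(sensitivity tensors are then reused across all phantoms), 10⁶ photons for
the reflectance physics check, 59-phantom cohorts, 20 split replications,
500 Monte Carlo runs for the calibration null. Every stochastic stage
(transport, textures, noise, splits, forests) takes an explicit seed, and
equal seeds reproduce results bitwise.

## Known limitations

- Homogeneous optics only; no simultaneous μ_a/μ_s′ fitting.
- Rectangular slab; no curved anatomy or chest wall.
- Index-matched boundaries; Fresnel reflection not modeled.
- The correlation-noise model is flat Gaussian, not a photon-count model;
  real correlator noise grows with τ and couples bins.
- Depth resolution is limited by the reflectance geometry: reconstructions
  concentrate contrast in the shallow layers, so quantitative recovery is
  assessed on the iz = 1 slice.
- The g−2 vs g df distinction matters for the Hosmer–Lemeshow p at these
  sample sizes; reported calibration p-values use the development-data
  convention and should be read comparatively, not as exact tail areas.
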