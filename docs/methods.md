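# Methods

This note documents the models, algorithms and numerical conventions the
package implements, the assumptions behind the synthetic phantom, and the
design choices made where the design was genuinely open.

## Problem setting

Late gadolinium enhancement (LGE) imaging visualises focal myocardial
fibrosis as bright signal against nulled normal myocardium, at the cost of
intravenous contrast. The native acquisitions of a standard CMR exam
already carry correlated signal: native T1 is elevated in fibrotic tissue,
the inversion-recovery-weighted (IRW) source images carry the raw
tissue-contrast evolution, and cine frames delineate wall motion and
borders. The package's core model learns the mapping from these native
inputs to an LGE-like ("virtually enhanced", VNE) image, and the
surrounding modules reproduce the measurement chain by which such images
are validated: geometric slice matching, ROI-anchored lesion
quantification, and method-agreement statistics.

## Generator, discriminator, objectives

**Generator.** Three parallel encoder–decoder U-Net streams process the
cine frames, the IRW images and the T1 map (each channel-stacked,
`C = cine_frames_used / irw_images_used / 1`). Every stream has
`unet_depth` resolution levels (default 3) with two 3×3 convolutions +
leaky ReLU (α = 0.1) per level, 2×2 average-pool downsampling, nearest
×2 upsampling, and skip connections from each encoder level to its
decoder level; channel width doubles per level from `base_channels`. The
three streams' final feature maps are concatenated and fused by three
further convolutions into a single output image with the same spatial
size as the T1 map. The output is linear (no squashing): the target scale
is learned.

**Discriminator.** A patch classifier conditioned on the native input
channels: the candidate image is concatenated with all normalised native
channels and reduced by three conv+pool stages to a patch response map.
The adversarial objective is least-squares (real → 1, fake → 0), a
stable choice for small-batch training. Conditioning on the native inputs
makes the discriminator judge correspondence, not just realism.

**Perceptual objective.** `perceptual_distance(a, b)` sums the mean
absolute differences of feature maps over the layers of a fixed feature
extractor, with the raw image included as layer zero (so the distance is
zero only for identical images, and the pixelwise L1 term is part of the
objective). The default extractor is two seeded random-weight
convolutions with pooling, frozen throughout; it is deliberately small so
desk-scale training is fast, and any richer pretrained extractor can be
substituted via the `feature_net` hook (`FeatureNet.features()` is the
only interface). Total generator loss:
`λ_adv·L_adv + λ_perc·L_perc`, defaults `(0.05, 1.0)` — the perceptual
term drives accuracy, the adversarial term sharpens appearance.

**Training.** Adam (lr 2·10⁻³) on both networks, alternating one
discriminator and one generator update per step on batches of 4 triplets.
The dataset is split by patient into training (90 %) and validation
(10 %); the returned parameters are those with the best validation
perceptual loss. Inputs are normalised as: T1 divided by the fixed
constant 2000 ms; cine/IRW/LGE scaled per image to [0, 1] by their
1st–99th intensity percentiles (robust to hot pixels). The same
normalisation runs at inference, so trained models are self-contained.
The default desk-scale configuration is 64×64 images, depth 3, 8 base
channels, 1200 steps — sized so a full training run completes in minutes
on one CPU while leaving the burden-agreement experiment comfortably
reproducible. All computation runs on the package's numpy reverse-mode
autodiff engine (`vne._autodiff`: im2col convolution, pooling, upsampling,
elementwise ops, Adam), so training and inference are deterministic given
the seed.

**No-leakage contract.** Inference consumes only native inputs; the LGE
member of a triplet is never read, and an LGE image offered among the
native channels raises an error. Tests assert that perturbing the LGE
input leaves the generated image bit-identical.

## Slice matching and resampling

Conventions: `pixels[r, c]`; `row_dir`/`col_dir` are patient-space unit
vectors along increasing row/column index; `position_mm` is the centre of
pixel (0, 0); orthonormality tolerance 1e-6. Two slices match when the
plane cosine similarity `|n̂_a · n̂_b|` exceeds 0.9 **and** the location
difference is below 4 mm. The location difference is defined as the
offset projected onto the *mean* of the two (sign-aligned) unit normals —
the criterion is standard, the formula is this package's choice; with the
gates passed the two normals differ by <26°, so the choice of projection
axis moves the value negligibly. Assignment is one-to-one per modality,
greedy on (smallest location difference, then smallest cosine deviation),
deterministic. Unmatched slices are logged with the violated criterion,
never fatal. Accepted cine/LGE slices are bilinearly resampled onto the
T1 grid (the T1 map itself is never resampled); out-of-field pixels take
a fill value recorded in the image metadata.

## Lesion quantification

The "percentile" of the FWHM-family thresholds is a fraction of the
remote-myocardium→blood-pool intensity range, not a rank percentile of
the histogram: `t(p) = remote_mean + (p/100)(blood_mean − remote_mean)`,
with p = 50, 25, 12.5 (FWHM/FWQM/FWEM) as the standard set and 35, 20, 10
as the adjusted VNE set. A blood-pool mean not exceeding the remote mean
is a degenerate-reference error. Pixels with intensity **≥** threshold
inside the myocardial mask count as lesion (plateaus at exactly the
threshold are included). The myocardial mask contains pixels whose
centres lie inside the epicardial and outside the endocardial polygon,
even-odd fill rule; self-intersecting or non-nested contours are
validation errors. Per-patient burden pools areas across slices
(`Σ lesion / Σ myo`), never a mean of per-slice ratios. Remote/blood
reference means default to per-slice values, with a pooled-per-study
option. Masks are scale-equivariant: rescaling an image and its ROI
references together changes nothing. `calibrate_adjusted_percentile`
grid-searches the VNE percentile whose mean burden best matches LGE at a
given percentile, ties resolved toward the larger (more conservative)
percentile.

## Agreement statistics

- `linear_fit`: simple OLS of b on a; R is Pearson (identical to the
  regression R for simple OLS with intercept).
- `icc_agreement`: ICC(2,1) — two-way random effects, absolute agreement,
  single rater — with the standard F-based 95 % CI (computed via
  pingouin). The variant is fixed but documented; degenerate-variance
  inputs return a boundary value with a warning flag rather than NaN.
- `bland_altman`: bias = mean(a−b), parametric limits bias ± 1.96 SD with
  large-sample CIs, and 2.5th/97.5th empirical percentile limits reported
  alongside because real difference distributions are often skewed (the
  percentile limits are asymmetric about the bias; the parametric ones
  are symmetric by construction).
- `wilcoxon_paired`: signed-rank test, zeros dropped (Wilcoxon's
  convention), ties mid-ranked. The null distribution is exact for ≤ 25
  non-zero pairs via a dynamic program over doubled (midrank-safe) rank
  sums — equivalent to enumerating all 2ⁿ sign patterns, verified against
  brute-force enumeration in the tests; beyond 25 pairs a normal
  approximation with tie-corrected variance and continuity correction is
  used.

## The phantom: what it emulates, what it does not

Each slice is an annular left-ventricular myocardium between two
concentric polygonal contours around a blood pool, with asymmetric septal
thickening (Gaussian bump in wall thickness, factor 1.2–1.8) and mild
apical taper along the stack. Lesions are transmural wedges placed near
the right-ventricular insertion points (±35° from the septum) — placement
is cosmetic, not load-bearing — present per slice with probability
`lesion_probability` (default 0.7) and with angular extent scaled by a
per-patient severity factor, which is what creates the across-patient
burden spread the agreement statistics measure.

Synthetic tissue conventions (configurable, not physiological claims):
normal myocardium 950 ms, blood 1600 ms, background 300 ms, lesion
elevation drawn from N(150, 40) ms clipped to [50, 500], so blood T1 >
lesion T1 > normal T1 always holds noise-free. IRW images follow
`|1 − 2·exp(−TI/T1)|` on a geometric ladder of 7 inversion times from 100
to 5000 ms. Cine frames contract the annulus sinusoidally over the cycle
(12 % endocardial, 4 % epicardial radial excursion). The LGE forward
model nulls normal myocardium at 0.05, maps lesion intensity strictly
monotonically with T1 elevation, `0.05 + 0.9(1 − exp(−ΔT1/200 ms))`
(saturating, invertible), and renders the blood pool at 0.85 — so a
lesion needs ΔT1 ≳ 118 ms to clear the FWHM threshold, and
intermediate-elevation lesions appear only at the lower progressive
thresholds, mirroring the hyper- vs intermediate-intensity distinction
the quantification is designed around. `noise_sd` (default 0.02) is
additive Gaussian noise as a fraction of each modality's dynamic range
(1000 ms for T1; 1 for the unit-scaled modalities). Metadata jitter
translates/rotates the cine/LGE acquisition geometry to exercise the
matching gates.

Ground truth is recorded at generation time by quantifying the
*noise-free* LGE image with the true ROIs, so on a noise-free phantom the
quantification module reproduces the recorded burdens exactly — an
end-to-end consistency check, not a tautology, since the quantifier runs
through the full contour→mask→threshold path.

The phantom does **not** model MR physics (k-space, coils, banding,
partial volume — lesion edges are hard), realistic anatomy, papillary
muscles, through-plane motion, or scanner/vendor variation. Passing tests
therefore demonstrate that the method chain is implemented correctly and
that the generator can learn a clean native→enhancement mapping; they do
not certify clinical performance, where the mapping is noisier and the
agreement correspondingly lower.

## The replication experiment

`vne.replication.scaled_replication` mirrors the design of the clinical
burden-agreement study at desk scale: 40 phantom patients (3 slices each,
64×64), a seeded patient-level split holding out 25 % (10 patients),
training on the remaining 30 with the default generator configuration,
plus 10 extra test patients from an independently seeded cohort (20 test
patients, 60 test slices — problem sizes chosen as the package's standard
desk-scale conditions). Per-patient FWHM burdens are computed identically
for the generated images and the phantom LGE, then compared with Pearson
R, ICC(2,1) and Bland–Altman bias. Because the phantom's forward model is
far cleaner than clinical data, the expected agreement is well above the
values reported for real cohorts; the experiment checks that the full
chain — simulation, training, inference, quantification, statistics —
holds together quantitatively.

## Known limitations

- The default perceptual feature extractor is random and small; it is a
  hook, not a claim that random features match a pretrained network's
  perceptual metric.
- The adversarial weight is deliberately small; at desk scale the
  perceptual term dominates and the discriminator mainly regularises.
- The exact Wilcoxon path assumes midranks double to integers (always
  true for rankdata output).
- ICC confidence intervals use the standard F approximation, which is
  anticonservative for very small n.
- Training determinism is guaranteed within a fixed BLAS configuration;
  exotic threading setups may reorder reductions.
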