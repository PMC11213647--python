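# Methods

This note documents the models, conventions and numerical choices behind
`sctdose`: a pipeline that quantifies how synthetic-CT (sCT) generation
strategies for MR-only prostate radiotherapy perturb dose-derived rectal
toxicity predictors.

## The question the pipeline answers

In an MR-only workflow the planning CT is replaced by an sCT derived from
MR, and dose is recalculated on it with identical beams and monitor units
(MU). Any HU error in the sCT perturbs the dose distribution and therefore
the toxicity risk predicted from the rectal dose. The pipeline measures
that perturbation for three sCT families — bulk density (one HU for the
whole body), tissue stratification (one nominal HU per tissue class) and a
voxel-wise 2D U-Net translation of the MR — against the ground-truth
calculation on the planning CT, using two predictor families: LKB NTCP
from rectal DVHs and binary dose-surface-map (DSM) parameters.

## Synthetic phantoms

No public dataset pairs planning CTs with co-registered pelvic MRs, so the
study conditions are emulated with a parametric pelvic phantom: an
elliptical body with a subcutaneous fat ring, femoral heads and a sacral
block (cortical shell around a spongy interior), bladder, prostate (CTV,
with PTV60 = CTV + 5 mm and PTV48 = CTV + 9 mm), and a gently curved
rectal tube that may contain gas pockets (three candidate pockets, each
present with probability 0.5). CT and MR are painted from one shared label
map, so the pair is co-registered by construction.

Default tissue means (HU) are realistic-CT values — fat −90, muscle 45,
spongy bone 250, cortical bone 1200, bladder 10, rectal gas −950 — with
additive Gaussian noise (SD 10 HU) inside the body. They deliberately
differ from the stratification nominals (−75 / 0 / 204 / 1067 / −500), so
tissue stratification carries a realistic systematic error. A *nominal*
phantom variant paints the nominal values noise-free; stratifying it
reproduces the CT exactly, giving the pipeline an exact null.

The pseudo-MR maps tissues to T2-like intensities (fat and urine bright,
bone and air dark), multiplies by a smooth random bias field (amplitude
0.2) and adds Rician-like magnitude noise (SD 0.03). The mapping is
intentionally not an affine function of HU (correlation with CT < 0.9 over
the body), so MR→CT translation is a genuine learning task. Residual
CT↔MR registration error is emulated by a band-limited random deformation
(default 2 mm maximum, hard-capped at 10 mm) applied to the MR-side
anatomy; the tissue-stratification sCT is built from the deformed anatomy,
its `ts_ct` control from the undeformed CT, isolating stratification error
from registration error.

Default geometry is 40 × 128 × 128 voxels at (2.5, 0.98, 0.98) mm; tests
and the acceptance script use a desk-scale 28 × 64 × 64 grid at
(2.5, 1.96, 1.96) mm, which preserves all organ dimensions in millimetres.
The rectum-to-target gap (rectal axis 25 mm posterior of the prostate
centre) was chosen once so the planned dose satisfies the clinical
constraints while the anterior rectal wall reaches the 51/61 Gy EQD2 DSM
regime — both predictors then sit inside the published ground-truth ranges
(G2 bleeding risk a few percent, 51 Gy relative area below the 0.374
cut-off). All randomness flows from a single seed through named
sub-generators (anatomy, CT noise, MR noise, calcifications).

What the phantom does **not** emulate: population anatomy variation,
MR physics (susceptibility, distortion), realistic bone texture, organ
deformation between fractions. Passing tests therefore demonstrate the
*pipeline's* correctness and sensitivity ordering, not clinical sCT
accuracy on patients.

## Synthetic-CT methods

* **Bulk density** — body ← fill HU, outside ← −1000. Fill 0 HU is the
  water variant; the population variant pools the mean body HU over a
  training cohort.
* **Tissue stratification** — threshold classes inside the body at
  (−200, −30, 100, 400) HU for inside-air / fat / muscle / spongy /
  cortical. The published source gives no breakpoints, so these are
  declared, configurable values bracketing the nominal HUs. Two clean-up
  overrides follow the clinical product's behaviour: fat/spongy/cortical
  voxels inside the CTV (calcifications, fiducials) become muscle; fat or
  muscle pockets in bone interiors (bone mask eroded by the 2.5 mm
  cortical depth) become spongy bone. Classes are then painted with the
  nominal HUs.
* **U-Net** — see below.

HU accuracy is summarized as ME, MAE and sample SD (n−1) of sct − ct over
a region (default the body).

## Dose engine

A declared, simplified stand-in for a clinical algorithm — simple enough
to be exactly reproducible, density-sensitive enough that sCT errors
propagate to dose. Seven equispaced coplanar parallel beams (a VMAT-like
arrangement) each deliver primary fluence exp(−μ_eff · d_rad) through a
beam's-eye-view aperture (PTV60 projection + 6 mm margin), where d_rad is
the running line integral of relative electron density (piecewise-linear
HU→RED calibration anchored at air 0.0 / water 1.0) and μ_eff = 0.005 mm⁻¹
(≈6 MV in water). Field edges get a 4 mm Gaussian penumbra; beams are
summed with weights. At planning time the global fluence scale (`mu_scale`,
the MU analogue) is set so the PTV60 median equals 60 Gy and then frozen;
recalculation on an sCT reuses apertures and `mu_scale` verbatim, so a
bit-identical sCT yields a bit-identical dose. Scatter kernels, dose-to-
medium conversion and arc delivery are out of scope by design.

Dose agreement uses the 3D local gamma index at 2%/2 mm over voxels above
20% of the reference maximum: per reference voxel, the evaluated dose is
trilinearly interpolated on a sphere of radius 3 × DTA sampled every
0.5 mm, and γ is the minimum combined dose/distance deviation. Offsets are
searched in increasing distance with early termination once the spatial
term alone exceeds the running minimum; an exhaustive-search oracle test
pins the result to 1 × 10⁻⁶.

## Toxicity predictors

**DVH/LKB.** Voxel doses in the rectum are converted per voxel to EQD2
with α/β = 3 Gy and d = D/20 (60 Gy in 20 fractions), histogrammed at
0.1 Gy, reduced to gEUD = (Σ vᵢ Dᵢ^{1/n})ⁿ and mapped through
NTCP = Φ((gEUD − TD50)/(m·TD50)). Endpoints: grade-2 rectal bleeding
(TD50 97.7 Gy, m 0.27, n 0.085) and late faecal incontinence (TD50
105.0 Gy, m 0.43, n 1.0 — the gEUD is then exactly the EQD2 mean dose).
The published work does not state whether its LKB tool converts per voxel
or per DVH bin; both are supported, per-voxel is the default. D-metrics
interpolate the cumulative curve linearly and are right-continuous at
jumps; the "V60 < 0.0%" planning constraint is read as V(60 Gy) < 0.05%
(the only reading under which recalculated plans can meaningfully fail it).

**DSM.** Per axial slice the rectal contour is traversed clockwise (viewed
from inferior; orientation fixed by the shoelace sign) starting at its
posterior-most vertex (ties broken toward patient-right), resampled at 100
equal-arc-length points, and the planar dose sampled bilinearly. Rows
(inferior→superior) stack into the raw map, which is bilinearly
interpolated to 42 × 42 (circumference periodic), then EQD2-converted
per cell. Binary maps at 51 and 61 Gy give (a) the 51 Gy area relative to
the full map and (b) the relative lateral extent of the moment-equivalent
ellipse of the largest 61 Gy cluster (8-connectivity with circumferential
wrap; cell second moments include the +1/12 unit-square term; lateral
extent = 4·√M_cc, the ellipse's projection on the circumferential axis,
normalized by the 42-column width). The published cut-offs for bleeding
risk are 0.374 and 0.591 respectively. The ellipse-fitting algorithm and
extent normalization are not specified in the source literature; the
moment ellipse was chosen because it is deterministic and has closed-form
behaviour on simple shapes (a solid w-column band gives extent
w·(2/√3)/42 exactly), and an empty 61 Gy map is defined to yield extent 0.

## U-Net image translation

CT targets are clipped at 2000 HU and mapped by HU/3000 + 1/3 (−1000 → 0,
2000 → 1); MR inputs are scaled by their per-volume 99.995th-percentile
intensity (values above it are not clipped). The network is a 2D U-Net:
4 levels, two 3×3 conv + ReLU layers per block, dropout 0.2 after each
block, nearest-neighbour upsampling with a halving conv and skip
concatenation, and a linear 1×1 head — about 32 weight layers, matching
the "32 layers within 4 levels" reading. Training is whole-batch Adam
with an MSE loss. Because no deep-learning framework is assumed, the
network (forward, backprop, Adam) is implemented in numpy (float32,
im2col convolutions); all randomness (He init, dropout masks) flows from
the config seed, so training is bit-reproducible and inference (dropout
off) is deterministic. The linear head's bias is initialized at 1/3
(water) so early epochs refine tissue contrast instead of climbing from
air. The faithful defaults follow the published recipe (lr 1e-4, dropout
0.2, 100 epochs, base 32 filters at 512×512); the desk-scale recipe used
by the tests and the acceptance script (8 base filters, lr 3e-3, dropout
0, 800–1200 whole-batch epochs, training on every 4th slice of one
phantom, 64×64 in-plane) is an *overfit* configuration whose purpose is
to show that a voxel-wise learned sCT beats the classical methods when it
has effectively memorized the mapping — mirroring the accuracy ordering
(bulk density worst, stratification intermediate, learned sCT best)
rather than any claim about generalization.

## Statistics

Per method and metric the per-case error (sct − truth) is summarized by
the mean (absolute) error and sample SD, Bland–Altman 95% limits of
agreement mean ± 1.96·SD (this arithmetic reproduces the published bounds
from the published mean/SD pairs), a two-sided paired t-test and a
Shapiro–Wilk normality check (3 ≤ n ≤ 50). Degenerate contracts: all-zero
differences → p = 1; zero-variance nonzero differences → p = 0 with a
warning; identical values are rejected by the normality test. No
multiplicity correction is applied (matching the source analysis); the
report records the number of tests performed.

## Numerical and testing choices

* Axis order (slice, row, col) = (inferior→superior, posterior→anterior,
  right→left); voxel-center coordinates, 0-based, even-odd rasterization.
* NIfTI + JSON contours are the canonical fixture format; DICOM
  CT/MR series I/O is supported for real data (non-oblique only).
* Test problem sizes: 28 × 64 × 64 phantoms, 8×8×8 gamma oracle grids,
  five-seed method-ordering cohorts; chosen so the whole suite runs on a
  single CPU in well under half an hour.
* Known limitations: parallel (non-divergent) beams; no scatter model;
  the phantom's rectum is a solid contour surface (no wall thickness);
  DSM parameters are computed on the contour surface, as in the source
  methodology's surface sampling.
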