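# sctdose

Synthetic-CT dosimetry and rectal-toxicity prediction for MR-only prostate
radiotherapy.

In an MR-only radiotherapy workflow the planning CT is replaced by a
synthetic CT (sCT) derived from MR, and the treatment dose is recalculated
on it with identical beams and monitor units. `sctdose` quantifies how the
choice of sCT strategy — bulk density (one HU for the whole body), tissue
stratification (one nominal HU per segmented tissue class) or a 2D U-Net
translating MR to HU voxel-wise — perturbs the dose-derived predictors of
rectal toxicity used to guide toxicity-driven adaptive radiotherapy. It is
aimed at medical-physics researchers who want a fully reproducible,
CPU-scale in-silico version of that evaluation.

## What it computes

For a 60 Gy / 20-fraction prostate plan the pipeline compares, per sCT
method, against the ground-truth planning-CT calculation:

* **DVH / LKB NTCP** — rectal voxel doses are converted to EQD2
  (α/β = 3 Gy), reduced to the generalized equivalent uniform dose
  gEUD = (Σᵢ vᵢ Dᵢ^{1/n})ⁿ, and mapped through the Lyman-Kutcher-Burman
  probit NTCP = Φ((gEUD − TD₅₀)/(m·TD₅₀)), with published parameters for
  grade-2 rectal bleeding (TD₅₀ = 97.7 Gy, m = 0.27, n = 0.085) and late
  faecal incontinence (TD₅₀ = 105.0 Gy, m = 0.43, n = 1).
* **Dose-surface maps** — the rectal surface dose is unwrapped from the
  posterior-most contour point clockwise, interpolated to 42 × 42,
  EQD2-converted, and parameterized by the relative area of the 51 Gy
  region and the relative lateral extent of an ellipse fitted to the
  largest 61 Gy cluster (risk cut-offs 0.374 and 0.591).
* **Dose agreement** — 3D local gamma at 2%/2 mm over voxels above 20% of
  the maximum dose.
* **Statistics** — per-method mean (absolute) error, SD, Bland–Altman 95%
  limits of agreement (mean ± 1.96 SD), paired t-test and Shapiro–Wilk.

Because no paired CT/MR pelvic dataset is public, the package ships a
seeded synthetic-phantom generator (co-registered CT, T2-like MR, contours
and plan) plus a simplified, density-sensitive ray-cast dose engine; see
`docs/methods.md` for the models and their limitations.

## Worked example

```python
from dataclasses import replace
from sctdose import PhantomConfig, generate_phantom, recalc_fixed_mu
from sctdose.dose_engine import plan_on_ct
from sctdose.study import build_sct, toxicity_metrics

ph = generate_phantom(PhantomConfig.small(seed=1))
dose, plan = plan_on_ct(ph.ct, ph.plan, ph.structures.masks["PTV60"])
ph = replace(ph, plan=plan)
truth = toxicity_metrics(dose, ph)
print({k: round(v, 2) for k, v in truth.items()})

sct = build_sct(ph, "bdw")                    # water bulk-density sCT
m = toxicity_metrics(recalc_fixed_mu(sct, plan), ph)
print(round(m["g2rb_ntcp_pct"] - truth["g2rb_ntcp_pct"], 3))
```

prints (seed 1):

```
{'ptv60_median_gy': 60.0, 'ptv60_d95_gy': 57.42, 'ptv48_d95_gy': 47.66,
 'rectum_v60_pct': 0.0, 'g2rb_ntcp_pct': 1.95, 'lfi_ntcp_pct': 3.09,
 'rel_area_51_pct': 7.88, 'rel_lat_extent_61_pct': 11.68}
0.111
```

i.e. the planned dose meets the clinical constraints (PTV60 median 60 Gy,
D95% ≥ 57 Gy, PTV48 D95% ≥ 45.6 Gy, rectal V60Gy ≈ 0), the ground-truth
grade-2 bleeding risk is 1.95% with both DSM parameters well below their
cut-offs, and recalculating the same plan on a water-only bulk-density sCT
shifts the predicted bleeding risk by 0.11 percentage points.

A command-line interface mirrors the library:

```bash
sctdose phantom generate --seed 1 --small --out phantom/
sctdose sct classical --method bdw --in phantom/ --out bdw.nii.gz
sctdose dose gamma --reference d1.nii.gz --evaluated d2.nii.gz
sctdose evaluate --seeds 1,2,3 --methods bdw,ts,ts_ct --out report/
```

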