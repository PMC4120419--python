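# spinecorr

Resting-state functional connectivity analysis for spinal cord fMRI,
with a synthetic cord phantom for end-to-end verification.

Spontaneous low-frequency (< 0.1 Hz) BOLD fluctuations in the spinal
cord gray matter are weak signals buried under cardiac and respiratory
pulsation, CSF flow, swallowing artifacts and slow cord motion.
`spinecorr` implements a slice-wise denoising and analysis protocol for
axial cervical-cord acquisitions (≈150 volumes at TR ≈ 3.6 s over 12
slices) and the statistics needed to decide whether the left/right
ventral (motor) and left/right dorsal (sensory) horns exhibit genuine
functional connectivity:

* **Denoising pipeline** — Gaussian weighting kernels with FWHM at the
  CSF boundaries; slice-wise within-plane translation correction
  (weighted-SSD estimation, 5-point median filtering of the motion
  trace, single sinc resampling); data-driven "regressors of no
  interest" via PCA of the not-spine (neck) compartment and of CSF,
  selected up to 80% / 50% cumulative variance or an eigenvalue gap
  < 0.02; RETROICOR cardiac/respiratory phase regressors (order 2); the
  first principal time course of white matter; zero-phase Chebyshev
  Type II band-pass (0.01–0.08 Hz).
* **Connectivity** — Pearson correlation converted to an approximately
  standard-normal score `z = atanh(r) · sqrt(dof − 3)`, where
  `dof = N (1 − r1a·r1b) / (1 + r1a·r1b)` discounts the sample size for
  first-order temporal autocorrelation. Single-voxel seed maps use
  |z| > 3.29 (two-tailed 99.9%) with a 9-voxel cluster-extent rule;
  ROI analysis produces per-slice 8×8 z matrices over the eroded
  quadrant sub-regions (LV/RV/LD/RD × gray/white matter).
* **Group inference** — per-subject median z across slices, exact
  Wilcoxon signed-rank tests across subjects, Bonferroni correction
  over the 28 ROI pairs, slice-significance tallies at z > 1.65
  (one-tailed 95%) and box-whisker summaries.
* **Phantom** — a butterfly-shaped gray-matter column inside a
  white-matter ellipse, CSF annulus and neck tissue, with *planted*
  inter-horn correlations, quasi-periodic cardiac/respiratory
  confounds, CSF flow components, swallowing events, slow in-plane
  drift and thermal noise, plus the ground truth needed to verify every
  stage without scanner data.

## Worked example

```python
import numpy as np
from spinecorr import PhantomConfig, PipelineConfig
from spinecorr.pipeline import run_group_study

study = run_group_study(phantom_cfg=PhantomConfig(),   # rho_vv=0.5, rho_dd=0.35
                        pipeline_cfg=PipelineConfig(),
                        n_subjects=22, seed=1)
gm = study.group_matrix.matrices                       # (22, 8, 8) median z
print("median GM TSNR:", round(study.tsnr_gm_pre, 1), "->",
      round(study.tsnr_gm_post, 1))
print("LV-RV group median z:", round(float(np.median(gm[:, 0, 1])), 2),
      "tier:", study.group_result.tier("LV-GM", "RV-GM"))
print("LD-RD group median z:", round(float(np.median(gm[:, 2, 3])), 2),
      "tier:", study.group_result.tier("LD-GM", "RD-GM"))
```

prints

```
median GM TSNR: 31.9 -> 38.9
LV-RV group median z: 3.76 tier: p<0.01
LD-RD group median z: 1.57 tier: p<0.01
```

i.e. the CSF/white-matter regressors raise gray-matter temporal SNR by
about 20–25%, and the two planted horn-pair couplings (Pearson 0.5
between ventral horns, 0.35 between dorsal horns) are recovered as the
two Bonferroni-significant gray-matter pairs; on this cohort no other
pair reaches significance (occasional cohorts show a weak spurious
gray–white pair near the corrected 0.05 boundary — see
`docs/methods.md` on residual couplings).

A command-line interface mirrors the library:

```bash
spinecorr simulate --seed 3 --out phantom/
spinecorr run --func phantom/func.nii.gz --masks phantom/masks.nii.gz \
              --physio phantom/physio.tsv --out proc/
spinecorr connectivity --func phantom/func.nii.gz --masks phantom/masks.nii.gz \
              --seed 40,22,5 --out seedmap/
spinecorr group --in group_medians.txt --out group/   # 8n x 8 stack of per-subject median-z matrices
```

## Coordinate conventions

Voxel indices are 0-based; axis 0 runs right → left, axis 1 runs
ventral → dorsal, axis 2 is the slice axis, axis 3 time. NIfTI affines
carry the voxel size (default 0.31 × 0.31 × 4 mm). Tissue label maps
use 0 background, 1 gray matter, 2 white matter, 3 CSF, 4 not-spine.

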