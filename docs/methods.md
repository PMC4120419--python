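# Methods

## The analysis problem

Axial spinal cord fMRI at high field yields ~150 volumes at TR ≈ 3.6 s
over ~12 slices, with in-plane resolution interpolated to ≈0.31 mm.
The quantity of interest is the temporal correlation between
gray-matter horn sub-regions within a slice, after removing structured
noise. `spinecorr` implements the processing chain, the statistics,
and a synthetic phantom that makes the whole chain falsifiable: every
downstream claim in this note is computed by the test suite or by
`scripts/acceptance.py`, not asserted from memory.

## Processing chain

Per subject, in order:

1. **Weighting kernels** — per slice, an anisotropic Gaussian centered
   on the cord (GM+WM) centroid whose per-axis FWHM equals the CSF
   extent along that axis. Used to focus the motion-correction cost on
   the cord.
2. **Not-spine mask** — complement of the dilated (radius 2) cord+CSF
   region within each slice.
3. **Motion correction** (runs before any regression; see *Design
   choices*): per slice, the target volume minimizes the summed squared
   difference to the voxelwise median image; per-volume translations
   minimize the kernel-weighted SSD, evaluated exactly at fractional
   shifts via zoomed inverse DFTs of the correlation trig polynomials
   (integer FFT search ± 6 voxels, coordinate-descent refinement,
   parabolic interpolation; accuracy ≲ 0.02 voxels on noiseless
   shifts). Estimates are 5-point median filtered (rejecting artifact
   volumes) and applied with a single Fourier (sinc-family)
   interpolation. Applied corrections are demeaned per slice so the
   series sits at the mean cord position — the role the anatomical
   affine registration plays when a scanner anatomical reference
   exists. Rotations and through-plane motion are out of scope.
4. **Not-spine PCA regression** — temporal principal components of the
   not-spine compartment, selected to 80% cumulative variance or until
   two successive total-variance-normalized eigenvalues differ by less
   than 0.02 (absolute differences; a relative-gap variant is
   available), regressed with an intercept from all voxels of the
   slice. This is what removes swallowing-type bulk intensity events
   from the cord.
5. **RETROICOR** (order 2) — cardiac phase from detected pulse peaks,
   respiratory phase by amplitude-histogram equalization signed with
   the trace derivative; cos/sin of the first two harmonics at each
   slice's acquisition times, regressed from all voxels.
6. **CSF PCA regression** — CSF-compartment components (cap 50%, same
   gap rule) regressed from cord (GM+WM) voxels.
7. **White-matter eigenvector** — the first principal time course of
   the WM mask (variants: combined WM+GM mask, eroded WM mask)
   regressed from GM+WM voxels.
8. **Band-pass** — zero-phase Chebyshev Type II, passband 0.01–0.08 Hz
   (variants 0.01–0.07, 0.01–0.13), stopband edges at 0.5× the low and
   1.25× the high passband edge (capped below Nyquist), order 3 at
   25 dB per sweep, applied forward–backward with symmetric padding.
9. **Sub-regions** — GM and WM are split into quadrants about the cord
   centroid (a central band of half-width 2 voxels around the
   ventral–dorsal axis is excluded from GM, leaving the four horns),
   then morphologically eroded with discrete disks
   {(i,j): i²+j² ≤ r²}; radius 3 for GM and 11 for WM, decremented by
   one and retried whenever erosion would empty a region. Erosion is
   implemented by thresholding a Euclidean distance transform, which is
   exactly equivalent to the disk erosion and serves all fallback radii
   at once.

ROI connectivity computes Pearson r between eroded sub-region mean
series, the effective degrees of freedom
`dof = N_eff (1 − r1a r1b)/(1 + r1a r1b)` (lag-1 sample
autocorrelations, clamped to [4, N_eff]) and
`z = atanh(r)·sqrt(dof − 3)`, with |r| clamped at 1 − 1e−7. In the
pipeline N_eff is the residual sample count — the series length minus
the number of nuisance-regressor dimensions removed upstream
(intercept, not-spine PCs, RETROICOR columns, CSF PCs, WM
eigenvector), standard GLM accounting: without it the null z variance
measurably exceeds 1. Seed maps threshold |z| > 3.29 and drop contiguous
clusters below 9 voxels (3-D face connectivity by default, in-plane
8-connectivity available). Group analysis takes the per-subject median
z across slices per ROI pair, then an exact Wilcoxon signed-rank test
(mid-ranks for ties; full sign-assignment distribution by convolution
for n ≤ 25, normal approximation with continuity correction above)
against zero, Bonferroni-corrected over the 28 pairs at the 0.05 and
0.01 tiers.

## The phantom

One slice geometry (parametric, mirror-symmetric about half-integer
grid center): WM ellipse with semi-axes 19 × 13 voxels (≈ 11.8 × 8 mm
at 0.31 mm — a realistic cervical cord cross-section), a butterfly of
four GM horn ellipses joined by a central band, a CSF annulus out to
25 × 18 voxels, a 3-voxel moat, and neck tissue to the grid edge.

Signals:

* **Neural** — sums of random-phase sinusoids on the DFT grid inside
  0.01–0.08 Hz, combined as
  `horn = sqrt(rho)·shared + sqrt(1−rho)·independent`; defaults
  rho_vv = 0.5 (ventral pair), rho_dd = 0.35 (dorsal pair), rho_vd = 0,
  amplitude 12 intensity units on a GM baseline of 1000. The shared
  components are exactly sample-orthonormal and each independent
  component is exactly orthogonal to them, so coupled pairs realize
  their configured correlation precisely; the independent components of
  different horns are *not* orthogonalized against each other, so
  uncoupled pairs keep genuine Fisher-null sampling dispersion — a
  band-limited signal spans only 2 × (number of in-band DFT
  frequencies) dimensions, and its null correlation scale is
  1/sqrt(d), not 1/sqrt(n). The correlation matrix actually planted in
  each realization is recorded in the ground truth (the stored
  component series reproduce it to machine precision), and 100% of the
  periodogram power lies in band.
* **Cardiac** (~1.05 Hz, slowly frequency-modulated) and **respiratory**
  (~0.3 Hz) confounds, strongest in CSF (amplitudes 30 / 18 vs 8 / 6 in
  GM), within the order-2 Fourier span of the logged phase so RETROICOR
  can remove them; a slow 5% amplitude modulation rides on top and is
  left for the data-driven regressors. CSF pulsation carries an
  azimuthal pulse-wave phase lag (rank-2), and neck physiological
  amplitudes vary spatially, so compartment PCA can resolve components.
  Note both confound frequencies alias into the analysis band at this
  TR (1.05 Hz → ≈0.06 Hz, 0.3 Hz → ≈0.02 Hz), which is precisely why
  phase-based and data-driven removal matter.
* **Cord-canal fluctuation** — a slow (0.005–0.05 Hz) component shared
  by GM, WM and CSF but absent from the neck (amplitudes 18/18/25),
  orthogonalized against the neural basis: the target of the CSF/WM
  regressors and the main source of the TSNR gain.
* **CSF flow** (2 components, decaying amplitudes ≈13/8) and
  **structured neck noise** (3 components, ≈19/9/6.5) with smooth
  zero-mean spatial profiles: they give the compartment eigenvalue
  spectra a realistic decaying ladder so the cumulative/gap selection
  rule keeps its reported typical counts (3–5 not-spine, 2–6 CSF).
* **Bulk (swallow) events** — Poisson(2) per run, 1–2 volumes,
  multiplicative 12% intensity excursions on all tissue including the
  cord (per-slice scale jitter).
* **Motion** — smooth zero-mean in-plane drift (band 0.001–0.01 Hz,
  peak 1 voxel, per-slice scale jitter) rendered with the same Fourier
  shift machinery the pipeline inverts. A translation-jump option
  exists for robustness tests but defaults to off: a 1-volume real
  displacement is deliberately rejected by the normative median filter,
  so planting them by default would leave permanently misaligned
  volumes.
* **Thermal noise** — white Gaussian, sigma 25 (physiological-noise-
  dominated 7 T regime). The resulting median GM TSNR is ≈31 before
  and ≈39 after CSF/WM regression (gain ≈ 20–25%), in the range the
  protocol this emulates reports (≈29 → 38, +30%).

The physiological traces are logged at 50 Hz; slice acquisition times
spread uniformly over the TR.

### What the phantom does not emulate

No MR physics (k-space, coil sensitivity, T2* blurring, fat shift,
susceptibility dropout), no through-plane or rotational motion, no
inter-slice neural coupling, no non-stationary heart/breathing rate
jumps, no scanner drifts beyond the modeled bands. Geometry is
identical across slices and subjects; only the signal/noise
realizations differ. Consequently, passing tests demonstrate that the
chain is correct and calibrated under its stated noise model — not
that it is sufficient for any particular scanner's artifact mix.

## Design choices and numerical notes

* **Motion before regression.** The emulated protocol regresses
  not-spine components before estimating motion. On the phantom this
  is harmful twice over: neck components carry motion-locked signal
  (shrinking the translation estimates), and per-voxel fits subtracted
  from a still-moving cord are dragged through the later realignment,
  producing drift × regressor interaction terms that positively bias
  null correlations. The robust weighted-SSD estimator plus the median
  filter already tolerates the bulk events that motivated
  pre-regression (estimate error ≈ 0.08 voxel at event volumes, which
  the filter discards), so this package aligns first and regresses in
  the aligned frame. Scopes and selection rules are unchanged.
* **Filter order.** With the prescribed lag-1 dof correction, the null
  distribution of z depends on how closely the filtered noise spectrum
  resembles an AR(1) process. Measured on filtered white noise
  (N = 150, TR 3.6 s), an order-5/30 dB design gives z s.d. ≈ 1.15
  whereas order-3/25 dB gives ≈ 1.10; the gentler design is the
  default so the chain stays calibrated. Both remain config keys
  (`order`, `atten_db`). An odd order is required for an exact zero at
  DC (constant series filter to < 1e−6 of the offset).
* **Zero phase in practice.** Forward–backward filtering with
  symmetric padding has no group delay but carries edge transients on
  150-sample series; time-reversal symmetry holds on interior samples
  (asserted in tests) rather than at the first/last few volumes.
  Gustafsson initial conditions would be exactly symmetric but are
  numerically unusable for this narrow-band design.
* **Fractional Fourier shifts** zero the Nyquist bins of even-length
  axes: no Hermitian-consistent phase exists there, and keeping them
  turns opposite shifts into a shift-modulated residual (a bug this
  package's null calibration exposed). Round trips therefore compose
  to identity exactly for band-limited content.
* **Eigenvalue-gap rule** is interpreted as an absolute difference of
  total-variance-normalized eigenvalues < 0.02 (the same sentence's
  percentages refer to cumulative variance fractions); a relative-gap
  variant is available. Voxel series are demeaned, not variance
  normalized, before PCA.
* **Ties and edges.** Quadrant assignment sends voxels exactly on a
  dividing axis to the right/ventral side (documented, measure-zero
  for non-degenerate centroids). Median filtering replicates edge
  values. Target-volume ties break toward the lower index. Percentages
  round half-up to integers.
* **Exact Wilcoxon** enumerates the sign-assignment distribution via
  integer convolution over doubled mid-ranks — identical to full 2^n
  enumeration, feasible to n = 25; scipy's implementation serves as an
  independent cross-check on tie-free data in the tests.
* **Native-resolution path.** The phantom is generated in the
  analysis (interpolated) frame by default; generating on a coarser
  grid (e.g. 0.91 mm voxels) and passing ``upsample_factor`` to the
  motion-application step exercises the native-to-interpolated sinc
  resampling without a scanner-specific anatomical registration.
* **Affine stage.** The optional slice-wise affine (translation,
  scale bounded at 1%/5%, shear 5%) maximizes the squared Hellinger
  distance between the weighted joint intensity histogram
  (partial-volume binned) and the product of its marginals, via
  bounded Powell search. It is off by default: the phantom is
  generated in the anatomical frame. Recovery accuracy ≈ 0.3% scale
  on structured images; it is a simplified stand-in, not a
  re-implementation of any scanner toolchain.

## Problem sizes used by tests and the acceptance script

Unit and property tests run on reduced phantoms (24×24, 1 slice) or
synthetic series; exhaustive oracle comparisons cover all 3×3 masks and
all 2×2×3 cluster maps plus random larger instances. The acceptance
checks use the full study conditions: 22-subject cohorts at
64×64×12×150 (20 independent cohorts for detection), 168 null subjects
(2016 slices) for calibration, and 10,000 AR(1) pairs for the variance
check. The acceptance script reports one 22-subject cohort, 40 null
subjects and the same AR(1) check.

## Known limitations

* The lag-1 dof correction under-corrects band-limited data by
  construction: filtered white noise alone carries z s.d. ≈ 1.09, and
  the band-limited planted signals span only ~76 DFT dimensions at
  N = 150. Together with small positive couplings between
  same-quadrant GM and WM ROIs introduced by sinc resampling (noise
  becomes spatially correlated over a few voxels), the measured null
  exceedance of z > 1.65 is 6.8% pooled over 2016 slices (per-pair
  4.9–9.4%, against a nominal 5%), and roughly one phantom cohort in
  twenty flags one weak spurious GM–WM pair at the corrected 0.05
  boundary. Both mechanisms are properties of the emulated protocol
  (which resamples 0.91 → 0.31 mm with sinc and uses the same dof
  formula), not of this implementation.
* Dorsal-horn ROIs erode to only a few voxels at this geometry, so
  dorsal-pair z scores run lower than ventral ones — the same ordering
  the emulated study reports in vivo.
* The exact motion of a real cord (cardiac-locked, partly
  through-plane) is richer than the smooth drift modeled here.
* Group inference treats slices within a subject as exchangeable via
  the median; no along-cord (inter-slice) group connectivity is
  computed.
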