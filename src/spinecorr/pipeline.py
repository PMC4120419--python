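"""End-to-end single-subject processing and group studies.

The single-subject pipeline chains, per slice: Gaussian weighting
kernels -> slice-wise translation motion correction with
median-filtered traces -> not-spine PCA regression (all voxels) ->
RETROICOR -> CSF PCA regression (cord voxels) -> white-matter
first-eigenvector regression (GM+WM voxels) -> zero-phase band-pass ->
quadrant subdivision with morphological erosion -> 8x8 ROI
connectivity matrices.  An optional slice-wise bounded-affine
registration to an anatomical reference is available (off by default;
phantom data are generated already aligned).  Gray-matter TSNR is
recorded before and after the CSF/WM regression stages.

Regressor-set permutations (skipping CSF and/or WM regression, combined
WM&GM mask, eroded WM mask) and passband variants are configuration
switches for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import connectivity as conn
from . import filtering, group, masks as masks_mod, motion, nuisance
from .core import Volume4D
from .masks import SubRegionMasks, TissueMasks
from .phantom import (PhantomConfig, PhysioRecord, generate_phantom,
                      render_motion)

REGRESSOR_VARIANTS = ("none", "csf-only", "csf+wm", "csf+wm&gm",
                      "csf+wm-eroded")


@dataclass
class PipelineConfig:
    """Switches and parameters of the processing chain."""

    regressors: str = "csf+wm"
    band: tuple[float, float] = (0.01, 0.08)
    filter_order: int = 3
    atten_db: float = 25.0
    notspine_cap: float = 0.80
    csf_cap: float = 0.50
    eig_gap: float = 0.02
    max_components: int = 10
    retroicor_order: int = 2
    motion: bool = True
    median_window: int = 5
    max_shift: int = 6
    affine: bool = False
    gm_erosion: int = 3
    wm_erosion: int = 11
    central_halfwidth: float = 2.0
    notspine_dilate: int = 2

    def __post_init__(self) -> None:
        if self.regressors not in REGRESSOR_VARIANTS:
            raise ValueError(f"regressors must be one of "
                             f"{REGRESSOR_VARIANTS}, got {self.regressors!r}")

    def notspine_rule(self) -> nuisance.EigSelectionRule:
        return nuisance.EigSelectionRule(self.notspine_cap, self.eig_gap,
                                         self.max_components)

    def csf_rule(self) -> nuisance.EigSelectionRule:
        return nuisance.EigSelectionRule(self.csf_cap, self.eig_gap,
                                         self.max_components)


@dataclass
class SubjectResult:
    """Outputs of the single-subject pipeline."""

    slice_z: np.ndarray                    # (n_slices, 8, 8)
    slice_r: np.ndarray                    # (n_slices, 8, 8)
    tsnr_gm_pre: float                     # median GM TSNR before CSF/WM reg
    tsnr_gm_post: float                    # after CSF/WM regression
    subregions: SubRegionMasks | None = None
    motion_trace: motion.MotionTrace | None = None
    notspine_k: np.ndarray | None = None   # components kept per slice
    csf_k: np.ndarray | None = None
    roi_series: np.ndarray | None = None   # (n_slices, 8, n_volumes) filtered

    @property
    def median_z(self) -> np.ndarray:
        return group.subject_median(self.slice_z)


def run_subject(volume: Volume4D, masks: TissueMasks,
                physio: PhysioRecord | None,
                cfg: PipelineConfig | None = None,
                anatomical: Volume4D | None = None) -> SubjectResult:
    """Run the full denoising + connectivity chain on one subject.

    ``anatomical`` is only consulted when ``cfg.affine`` is enabled: each
    slice's mean image is then registered to the matching anatomical
    slice with the bounded within-plane affine and the transform applied
    to every volume.
    """
    cfg = cfg or PipelineConfig()
    masks.validate()
    if cfg.affine and anatomical is None:
        raise ValueError("affine stage enabled but no anatomical "
                         "reference supplied")
    ns = volume.n_slices
    cord = masks.gm | masks.wm
    full = np.ones(masks.gm.shape, dtype=bool)

    # step 1: weighting kernels
    weights = masks_mod.make_weight_kernel(masks)
    # step 2: not-spine mask
    notspine = masks_mod.make_not_spine_mask(masks, cfg.notspine_dilate)

    # steps 4-5 first: slice-wise translation correction on the raw
    # series.  The weighted-SSD estimator with median filtering is robust
    # to the bulk intensity events that motivated pre-regression, and
    # aligning before any voxelwise regression keeps every regression in
    # a consistent spatial frame (subtracting per-voxel fits from a
    # still-moving cord would drag the subtracted fields through the
    # later realignment).
    data = volume.copy()
    trace = None
    if cfg.motion:
        data, trace = motion.correct_motion(
            data, weights, window=cfg.median_window, max_shift=cfg.max_shift)

    # steps 8-9 (optional): slice-wise bounded affine to the anatomical
    if cfg.affine:
        for s in range(ns):
            mean_img = data.slice_data(s).mean(axis=-1)
            params = motion.register_affine_slice(
                mean_img, anatomical.slice_data(s)[:, :, 0],
                weights.slice_weights(s))
            for v in range(volume.n_volumes):
                data.data[:, :, s, v] = motion._apply_affine_params(
                    data.data[:, :, s, v], params)

    # step 3: not-spine PCA regression from all voxels of each slice
    ns_rule = cfg.notspine_rule()
    notspine_k = np.zeros(ns, dtype=int)
    for s in range(ns):
        cols, labels, eig = nuisance.pca_regressors(
            data, notspine, s, ns_rule, "notspine")
        notspine_k[s] = cols.shape[1]
        regs = nuisance.RegressorSet.intercept_only(
            volume.n_volumes).with_columns(cols, labels, eig)
        data = nuisance.regress_out(data, regs, full, s, copy=False)

    # step 6: RETROICOR on the whole volume
    if physio is not None and physio.cardiac.size:
        for s in range(ns):
            cols, labels = nuisance.retroicor_regressors(
                physio, s, order=cfg.retroicor_order)
            regs = nuisance.RegressorSet.intercept_only(
                volume.n_volumes).with_columns(cols, labels)
            data = nuisance.regress_out(data, regs, full, s, copy=False)

    # TSNR bookkeeping: GM before the CSF/WM regression stages
    _, tsnr_pre = filtering.tsnr_map(data, masks.gm)

    # step 11: CSF PCA regression from cord voxels
    csf_rule = cfg.csf_rule()
    csf_k = np.zeros(ns, dtype=int)
    if cfg.regressors != "none":
        for s in range(ns):
            cols, labels, eig = nuisance.pca_regressors(
                data, masks.csf, s, csf_rule, "csf")
            csf_k[s] = cols.shape[1]
            regs = nuisance.RegressorSet.intercept_only(
                volume.n_volumes).with_columns(cols, labels, eig)
            data = nuisance.regress_out(data, regs, cord, s, copy=False)

    # step 12: white-matter first eigenvector from GM+WM voxels
    if cfg.regressors in ("csf+wm", "csf+wm&gm", "csf+wm-eroded"):
        variant = {"csf+wm": "wm", "csf+wm&gm": "wm+gm",
                   "csf+wm-eroded": "wm-eroded"}[cfg.regressors]
        for s in range(ns):
            vec, _ = nuisance.wm_eigenvector(data, masks.wm, s,
                                             variant=variant,
                                             gm_mask=masks.gm)
            regs = nuisance.RegressorSet.intercept_only(
                volume.n_volumes).with_columns(vec[:, None], ["wm-eig1"])
            data = nuisance.regress_out(data, regs, cord, s, copy=False)

    _, tsnr_post = filtering.tsnr_map(data, masks.gm)

    # step 13: zero-phase band-pass (cord + CSF voxels feed all analyses)
    spec = filtering.FilterSpec(band=cfg.band, order=cfg.filter_order,
                                atten_db=cfg.atten_db, tr=volume.tr)
    data = filtering.bandpass(data, spec, mask=cord | masks.csf)

    # step 14: quadrants + erosion, then ROI connectivity per slice
    sub = masks_mod.subdivide_quadrants(masks, cfg.central_halfwidth)
    sub = masks_mod.erode_subregions(sub, cfg.gm_erosion, cfg.wm_erosion)

    # residual-dof accounting: every regression stage removed dimensions
    # from the cord voxel series (intercept + not-spine PCs + RETROICOR +
    # CSF PCs + WM eigenvector)
    n_retro = 8 if (physio is not None and physio.cardiac.size) else 0
    n_wm = 1 if cfg.regressors in ("csf+wm", "csf+wm&gm",
                                   "csf+wm-eroded") else 0
    dof_penalty = 1 + notspine_k + n_retro + csf_k + n_wm

    slice_z = np.zeros((ns, 8, 8))
    slice_r = np.zeros((ns, 8, 8))
    roi_series = np.zeros((ns, 8, volume.n_volumes))
    for s in range(ns):
        sc = conn.roi_connectivity(data, sub, s,
                                   dof_penalty=int(dof_penalty[s]))
        slice_z[s] = sc.z
        slice_r[s] = sc.r
        roi_series[s] = conn.roi_mean_series(data, sub, s)
    return SubjectResult(slice_z=slice_z, slice_r=slice_r,
                         tsnr_gm_pre=tsnr_pre, tsnr_gm_post=tsnr_post,
                         subregions=sub, motion_trace=trace,
                         notspine_k=notspine_k, csf_k=csf_k,
                         roi_series=roi_series)


@dataclass
class GroupStudyResult:
    subjects: list[SubjectResult]
    group_matrix: group.GroupMatrix
    group_result: group.GroupResult
    tsnr_gm_pre: float
    tsnr_gm_post: float

    @property
    def slice_z_all(self) -> np.ndarray:
        """(n_subjects * n_slices, 8, 8) pooled slice matrices."""
        return np.concatenate([s.slice_z for s in self.subjects])


def subject_seeds(seed: int, n_subjects: int) -> np.ndarray:
    """Deterministic per-subject phantom seeds derived from one seed."""
    rng = np.random.default_rng(seed)
    return rng.integers(0, 2 ** 31 - 1, size=n_subjects)


def simulate_subject(cfg: PhantomConfig):
    """Generate one phantom subject with planted motion applied."""
    volume, masks, physio, truth = generate_phantom(cfg)
    moving = render_motion(volume, truth)
    return moving, masks, physio, truth


def run_group_study(phantom_cfg: PhantomConfig | None = None,
                    pipeline_cfg: PipelineConfig | None = None,
                    n_subjects: int = 22, seed: int = 0) -> GroupStudyResult:
    """Simulate and process a full group of phantom subjects."""
    phantom_cfg = phantom_cfg or PhantomConfig()
    pipeline_cfg = pipeline_cfg or PipelineConfig()
    results = []
    for sub_seed in subject_seeds(seed, n_subjects):
        cfg = phantom_cfg.replace(seed=int(sub_seed))
        vol, masks, physio, _ = simulate_subject(cfg)
        results.append(run_subject(vol, masks, physio, pipeline_cfg))
    gm = group.group_matrix_from_slices([r.slice_z for r in results])
    gr = group.group_pipeline(gm)
    return GroupStudyResult(
        subjects=results, group_matrix=gm, group_result=gr,
        tsnr_gm_pre=float(np.median([r.tsnr_gm_pre for r in results])),
        tsnr_gm_post=float(np.median([r.tsnr_gm_post for r in results])))


GM_PAIR_VV = ("LV-GM", "RV-GM")
GM_PAIR_DD = ("LD-GM", "RD-GM")


def gm_wm_pairs() -> list[tuple[str, str]]:
    """The 16 cross-tissue (GM vs WM) ROI pairs."""
    gms = [n for n in masks_mod.ROI_NAMES if n.endswith("GM")]
    wms = [n for n in masks_mod.ROI_NAMES if n.endswith("WM")]
    return [(g, w) for g in gms for w in wms]
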