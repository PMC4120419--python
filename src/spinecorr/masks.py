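"""Tissue-mask geometry: weighting kernels, the not-spine mask, quadrant
subdivision of gray/white matter and morphological erosion of sub-regions.

Coordinate convention: 0-based voxel indices, axis 0 runs right -> left,
axis 1 runs ventral -> dorsal (see README).  The cord centroid is the
center of mass of the combined gray + white matter mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

#: Canonical sub-region (ROI) ordering used for all 8x8 matrices.
ROI_NAMES = ("LV-GM", "RV-GM", "LD-GM", "RD-GM",
             "LV-WM", "RV-WM", "LD-WM", "RD-WM")

#: Gaussian FWHM = 2*sqrt(2*ln 2) * sigma
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

LABELS = {"background": 0, "gm": 1, "wm": 2, "csf": 3, "not_spine": 4}


class MaskError(ValueError):
    """Raised for degenerate or inconsistent mask inputs."""


@dataclass
class TissueMasks:
    """Per-slice binary masks for the four tissue classes.

    All arrays are boolean with shape (nx, ny, n_slices) and must be
    pairwise disjoint within every slice.
    """

    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    not_spine: np.ndarray
    voxel_size: tuple[float, float, float] = (0.31, 0.31, 4.0)

    def __post_init__(self) -> None:
        for name in ("gm", "wm", "csf", "not_spine"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=bool))
        shapes = {self.gm.shape, self.wm.shape, self.csf.shape,
                  self.not_spine.shape}
        if len(shapes) != 1 or self.gm.ndim != 3:
            raise MaskError("all tissue masks must share one 3-D shape")

    @property
    def n_slices(self) -> int:
        return self.gm.shape[2]

    @property
    def cord(self) -> np.ndarray:
        """Gray + white matter."""
        return self.gm | self.wm

    def validate(self) -> None:
        """Check pairwise disjointness and per-slice GM presence."""
        pairs = [("gm", "wm"), ("gm", "csf"), ("gm", "not_spine"),
                 ("wm", "csf"), ("wm", "not_spine"), ("csf", "not_spine")]
        for a, b in pairs:
            if (getattr(self, a) & getattr(self, b)).any():
                raise MaskError(f"masks {a} and {b} overlap")
        empty = [s for s in range(self.n_slices) if not self.gm[:, :, s].any()]
        if empty:
            raise MaskError(f"gray matter empty on slices {empty}")

    def to_labelmap(self) -> np.ndarray:
        lab = np.zeros(self.gm.shape, dtype=np.int16)
        lab[self.gm] = LABELS["gm"]
        lab[self.wm] = LABELS["wm"]
        lab[self.csf] = LABELS["csf"]
        lab[self.not_spine] = LABELS["not_spine"]
        return lab

    def save(self, path) -> None:
        aff = np.diag(list(self.voxel_size) + [1.0])
        nib.save(nib.Nifti1Image(self.to_labelmap(), aff), str(path))

    @classmethod
    def from_labelmap(cls, lab: np.ndarray,
                      voxel_size=(0.31, 0.31, 4.0)) -> "TissueMasks":
        lab = np.asarray(lab)
        return cls(gm=lab == LABELS["gm"], wm=lab == LABELS["wm"],
                   csf=lab == LABELS["csf"],
                   not_spine=lab == LABELS["not_spine"],
                   voxel_size=tuple(voxel_size))

    @classmethod
    def load(cls, path) -> "TissueMasks":
        img = nib.load(str(path))
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls.from_labelmap(np.asarray(img.dataobj), voxel_size=zooms)


@dataclass
class WeightKernel:
    """Per-slice anisotropic Gaussian weights, peak 1 at the cord centroid.

    The full width at half maximum along each in-plane axis equals the CSF
    extent along that axis, so weights fall to 0.5 at the CSF boundary.
    """

    weights: np.ndarray                      # (nx, ny, n_slices), in [0, 1]
    centroids: np.ndarray                    # (n_slices, 2) float voxel coords
    sigmas: np.ndarray                       # (n_slices, 2) voxels

    def slice_weights(self, s: int) -> np.ndarray:
        return self.weights[:, :, s]

    def evaluate(self, s: int, x: float, y: float) -> float:
        """Evaluate the continuous kernel of slice ``s`` at (x, y)."""
        cx, cy = self.centroids[s]
        sx, sy = self.sigmas[s]
        return float(np.exp(-((x - cx) ** 2 / (2 * sx ** 2)
                              + (y - cy) ** 2 / (2 * sy ** 2))))


@dataclass
class SubRegionMasks:
    """The eight quadrant sub-regions (LV/RV/LD/RD for GM and WM).

    ``masks[name]`` is a boolean (nx, ny, n_slices) array for each name in
    :data:`ROI_NAMES`; ``radius_used[name][s]`` records the erosion radius
    actually applied on slice ``s`` (after any fallback), or -1 before
    erosion.
    """

    masks: dict[str, np.ndarray]
    radius_used: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(ROI_NAMES) - set(self.masks)
        if missing:
            raise MaskError(f"missing sub-regions: {sorted(missing)}")
        if not self.radius_used:
            n_slices = next(iter(self.masks.values())).shape[2]
            self.radius_used = {n: np.full(n_slices, -1, dtype=int)
                                for n in ROI_NAMES}

    @property
    def n_slices(self) -> int:
        return next(iter(self.masks.values())).shape[2]

    def to_labelmap(self) -> np.ndarray:
        lab = np.zeros(next(iter(self.masks.values())).shape, dtype=np.int16)
        for i, name in enumerate(ROI_NAMES, start=1):
            lab[self.masks[name]] = i
        return lab

    def save(self, path, voxel_size=(0.31, 0.31, 4.0)) -> None:
        aff = np.diag(list(voxel_size) + [1.0])
        nib.save(nib.Nifti1Image(self.to_labelmap(), aff), str(path))


def disk(radius: int) -> np.ndarray:
    """Discrete Euclidean disk {(i, j): i^2 + j^2 <= r^2} as a bool array."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    r = int(radius)
    ii, jj = np.mgrid[-r:r + 1, -r:r + 1]
    return ii ** 2 + jj ** 2 <= r ** 2


def cord_centroid(masks: TissueMasks, s: int) -> tuple[float, float]:
    """Center of mass of GM+WM on slice ``s`` (float voxel coordinates)."""
    cord = masks.cord[:, :, s]
    if not cord.any():
        raise MaskError(f"cord mask empty on slice {s}")
    idx = np.argwhere(cord)
    cx, cy = idx.mean(axis=0)
    return float(cx), float(cy)


def make_weight_kernel(masks: TissueMasks) -> WeightKernel:
    """Gaussian weighting kernel with FWHM set at the CSF boundaries.

    Per slice, the kernel is centered on the cord (GM+WM) centroid and the
    per-axis FWHM equals the distance between the extreme CSF voxel
    centers along that axis.
    """
    nx, ny, ns = masks.gm.shape
    weights = np.zeros((nx, ny, ns))
    centroids = np.zeros((ns, 2))
    sigmas = np.zeros((ns, 2))
    xx, yy = np.mgrid[0:nx, 0:ny].astype(float)
    for s in range(ns):
        csf = masks.csf[:, :, s]
        if not csf.any():
            raise MaskError(f"CSF mask empty on slice {s}")
        cx, cy = cord_centroid(masks, s)
        idx = np.argwhere(csf)
        fwhm_x = float(idx[:, 0].max() - idx[:, 0].min())
        fwhm_y = float(idx[:, 1].max() - idx[:, 1].min())
        if fwhm_x <= 0 or fwhm_y <= 0:
            raise MaskError(f"CSF extent degenerate on slice {s}")
        sx, sy = fwhm_x / FWHM_TO_SIGMA, fwhm_y / FWHM_TO_SIGMA
        weights[:, :, s] = np.exp(-((xx - cx) ** 2 / (2 * sx ** 2)
                                    + (yy - cy) ** 2 / (2 * sy ** 2)))
        centroids[s] = (cx, cy)
        sigmas[s] = (sx, sy)
    return WeightKernel(weights, centroids, sigmas)


def make_not_spine_mask(masks: TissueMasks, dilate_radius: int = 2) -> np.ndarray:
    """Complement, within each slice, of the dilated cord + CSF region."""
    spine = masks.cord | masks.csf
    out = np.zeros_like(spine)
    selem = disk(dilate_radius) if dilate_radius > 0 else None
    for s in range(masks.n_slices):
        sl = spine[:, :, s]
        if selem is not None and sl.any():
            sl = ndimage.binary_dilation(sl, structure=selem)
        out[:, :, s] = ~sl
    return out


def subdivide_quadrants(masks: TissueMasks,
                        central_halfwidth: float = 2.0) -> SubRegionMasks:
    """Split GM and WM into left/right x ventral/dorsal quadrants.

    Quadrants are defined by the left-right and ventral-dorsal axes through
    the cord centroid.  GM voxels within ``central_halfwidth`` voxels of
    the ventral-dorsal axis (the central gray matter commissure) are
    excluded from all four GM quadrants; WM quadrants partition WM.

    Tie rule: a voxel exactly on a dividing axis is assigned to the
    right / ventral side.
    """
    nx, ny, ns = masks.gm.shape
    out = {name: np.zeros((nx, ny, ns), dtype=bool) for name in ROI_NAMES}
    xx, yy = np.mgrid[0:nx, 0:ny].astype(float)
    for s in range(ns):
        cx, cy = cord_centroid(masks, s)
        left = xx > cx          # axis 0 runs right -> left
        dorsal = yy > cy        # axis 1 runs ventral -> dorsal
        central = np.abs(xx - cx) <= central_halfwidth
        gm, wm = masks.gm[:, :, s], masks.wm[:, :, s]
        gm_kept = gm & ~central
        if gm.any() and not gm_kept.any():
            raise MaskError(
                f"slice {s}: all gray matter lies in the central band")
        for name, lat, vd in ((f"LV", left, ~dorsal), ("RV", ~left, ~dorsal),
                              ("LD", left, dorsal), ("RD", ~left, dorsal)):
            out[f"{name}-GM"][:, :, s] = gm_kept & lat & vd
            out[f"{name}-WM"][:, :, s] = wm & lat & vd
    return SubRegionMasks(out)


def erode_subregion(mask: np.ndarray, radius: int) -> tuple[np.ndarray, int]:
    """Erode a 2-D binary mask with a discrete disk, with radius fallback.

    If erosion at the requested radius empties the mask the radius is
    decremented by one and the erosion retried; radius 0 is the identity,
    so a non-empty input always yields a non-empty output.

    Returns
    -------
    (eroded mask, radius actually used)
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise MaskError("erode_subregion expects a single-slice 2-D mask")
    if not mask.any():
        raise MaskError("cannot erode an empty mask")
    r = int(radius)
    if r < 0:
        raise ValueError("radius must be >= 0")
    if r == 0:
        return mask.copy(), 0
    # erosion by the disk {(i,j): i^2+j^2 <= r^2} keeps a voxel iff its
    # squared Euclidean distance to the nearest background voxel (with
    # the image border counting as background) exceeds r^2, so a single
    # distance transform serves every fallback radius
    padded = np.pad(mask, 1)
    edt = ndimage.distance_transform_edt(padded)[1:-1, 1:-1]
    d2 = np.rint(edt * edt).astype(np.int64)
    while r > 0:
        eroded = d2 > r * r
        if eroded.any():
            return eroded, r
        r -= 1
    return mask.copy(), 0


def erode_subregions(sub: SubRegionMasks, gm_radius: int = 3,
                     wm_radius: int = 11) -> SubRegionMasks:
    """Erode every quadrant sub-region slice-wise (GM and WM radii differ).

    Defaults are stated in interpolated-grid (0.31 mm) voxels.
    """
    out: dict[str, np.ndarray] = {}
    used = {name: np.zeros(sub.n_slices, dtype=int) for name in ROI_NAMES}
    for name in ROI_NAMES:
        radius = gm_radius if name.endswith("GM") else wm_radius
        eroded = np.zeros_like(sub.masks[name])
        for s in range(sub.n_slices):
            sl = sub.masks[name][:, :, s]
            if not sl.any():
                raise MaskError(f"sub-region {name} empty on slice {s}")
            eroded[:, :, s], used[name][s] = erode_subregion(sl, radius)
        out[name] = eroded
    return SubRegionMasks(out, radius_used=used)
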