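"""Correlation-based connectivity with autocorrelation-corrected Fisher z.

A Pearson correlation r between two time series is converted to an
approximately standard-normal score

    z = atanh(r) * sqrt(dof - 3)

where dof is the sample size discounted for first-order temporal
autocorrelation,

    dof = N * (1 - r1a*r1b) / (1 + r1a*r1b)

with r1a, r1b the lag-1 sample autocorrelations of the two series
(clamped to [4, N]).  Voxel-level seed maps are thresholded (default
|z| > 3.29, the two-tailed 99.9% confidence bound) and filtered by a
minimum cluster extent (default 9 contiguous voxels); ROI-level analysis
produces per-slice 8x8 z matrices over the quadrant sub-regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import Volume4D
from .masks import ROI_NAMES, SubRegionMasks

#: |z| threshold of the two-tailed 99.9% confidence interval.
Z_TWO_TAILED_999 = 3.29
#: z threshold of the one-tailed 95% confidence interval.
Z_ONE_TAILED_95 = 1.65
#: z threshold of the one-tailed 99.9% confidence interval (p < 0.001).
Z_ONE_TAILED_999 = 3.09

#: |r| is clamped below 1 by this margin before atanh (documented ceiling).
R_CLAMP = 1e-7

DOF_MIN = 4.0


class ConnectivityError(ValueError):
    pass


@dataclass
class CorrelationStats:
    r: float
    rho1_a: float
    rho1_b: float
    dof: float
    z: float


def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson product-moment correlation of two equal-length series."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ConnectivityError("series must be 1-D with equal length")
    if a.size < 4:
        raise ConnectivityError("need at least 4 samples")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ConnectivityError("constant series has undefined correlation")
    a = a - a.mean()
    b = b - b.mean()
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


def lag1_autocorr(x: np.ndarray) -> float:
    """Lag-1 sample autocorrelation (biased normalization by lag 0)."""
    x = np.asarray(x, dtype=np.float64)
    x = x - x.mean()
    denom = x @ x
    if denom == 0:
        return 0.0
    return float(x[:-1] @ x[1:] / denom)


def effective_dof(a: np.ndarray, b: np.ndarray,
                  n_effective: int | None = None) -> float:
    """Effective degrees of freedom after first-order autocorrelation
    correction, clamped to [4, N].

    ``n_effective`` replaces the raw sample count when the series are
    residuals of a nuisance regression (standard GLM accounting:
    N minus the number of removed regressor dimensions).
    """
    a = np.asarray(a, dtype=np.float64)
    if a.size < 8:
        raise ConnectivityError("need at least 8 samples for dof estimation")
    n = a.size if n_effective is None else int(n_effective)
    if n < 8:
        raise ConnectivityError("effective sample count too small")
    p = lag1_autocorr(a) * lag1_autocorr(np.asarray(b, dtype=np.float64))
    p = np.clip(p, -0.999999, 0.999999)
    dof = n * (1.0 - p) / (1.0 + p)
    return float(np.clip(dof, DOF_MIN, n))


def fisher_z(r: float, dof: float) -> float:
    """Fisher r-to-z score: atanh(r) * sqrt(dof - 3), with |r| clamped
    to 1 - 1e-7 so degenerate (|r| = 1) inputs stay finite."""
    if dof < DOF_MIN:
        raise ConnectivityError("dof must be >= 4")
    r = float(np.clip(r, -1.0, 1.0))
    r = float(np.clip(r, -(1.0 - R_CLAMP), 1.0 - R_CLAMP))
    return float(np.arctanh(r) * np.sqrt(dof - 3.0))


def correlation_stats(a: np.ndarray, b: np.ndarray,
                      n_effective: int | None = None) -> CorrelationStats:
    """The full r -> effective dof -> z chain for one pair of series."""
    r = pearson_r(a, b)
    dof = effective_dof(a, b, n_effective=n_effective)
    return CorrelationStats(r=r, rho1_a=lag1_autocorr(a),
                            rho1_b=lag1_autocorr(b), dof=dof,
                            z=fisher_z(r, dof))


def zscores_batch(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized z for paired rows of ``a`` and ``b`` (n_pairs, n)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    a = a - a.mean(axis=-1, keepdims=True)
    b = b - b.mean(axis=-1, keepdims=True)
    va = np.einsum("ij,ij->i", a, a)
    vb = np.einsum("ij,ij->i", b, b)
    r = np.einsum("ij,ij->i", a, b) / np.sqrt(va * vb)
    r1a = np.einsum("ij,ij->i", a[:, :-1], a[:, 1:]) / va
    r1b = np.einsum("ij,ij->i", b[:, :-1], b[:, 1:]) / vb
    p = np.clip(r1a * r1b, -0.999999, 0.999999)
    dof = np.clip(a.shape[-1] * (1 - p) / (1 + p), DOF_MIN, a.shape[-1])
    r = np.clip(r, -(1 - R_CLAMP), 1 - R_CLAMP)
    return np.arctanh(r) * np.sqrt(dof - 3.0)


# ---------------------------------------------------------------------------
# seed-based voxel maps


@dataclass
class SeedMap:
    """A single-voxel seed correlation map with cluster-extent filtering."""

    seed: tuple[int, int, int]
    zmap: np.ndarray                   # (nx, ny, n_slices); NaN outside mask
    threshold: float
    min_cluster: int
    two_tailed: bool
    cluster_labels: np.ndarray         # int labels of surviving clusters
    n_clusters: int

    @property
    def surviving(self) -> np.ndarray:
        return self.cluster_labels > 0


def _connectivity_structure(in_plane_only: bool) -> np.ndarray:
    if in_plane_only:
        s = np.zeros((3, 3, 3), dtype=bool)
        s[:, :, 1] = True                  # 8-connectivity within the plane
    else:
        s = ndimage.generate_binary_structure(3, 1)   # faces only
    return s


def label_clusters(binary: np.ndarray, min_cluster: int,
                   in_plane_only: bool = False,
                   ) -> tuple[np.ndarray, int]:
    """Connected components of a 3-D binary map with a minimum extent.

    Components smaller than ``min_cluster`` voxels are removed; surviving
    components are relabeled 1..n.  Default contiguity is 3-D
    face-connectivity; ``in_plane_only`` switches to 8-connectivity
    within each slice with no through-slice links.
    """
    labels, n = ndimage.label(np.asarray(binary, dtype=bool),
                              structure=_connectivity_structure(in_plane_only))
    if n == 0:
        return labels, 0
    counts = np.bincount(labels.ravel())
    keep = np.flatnonzero(counts >= max(min_cluster, 1))
    keep = keep[keep > 0]
    remap = np.zeros(n + 1, dtype=int)
    remap[keep] = np.arange(1, keep.size + 1)
    return remap[labels], int(keep.size)


def seed_correlation_map(series: Volume4D, seed: tuple[int, int, int],
                         mask: np.ndarray, threshold: float = Z_TWO_TAILED_999,
                         min_cluster: int = 9, two_tailed: bool = True,
                         in_plane_only: bool = False) -> SeedMap:
    """z map of every mask voxel against a seed voxel's time series.

    Suprathreshold voxels (|z| > threshold two-tailed, or z > threshold
    one-tailed) are grouped into contiguous clusters and clusters smaller
    than ``min_cluster`` voxels are discarded.
    """
    m = np.asarray(mask, dtype=bool)
    if not m[seed[0], seed[1], seed[2]]:
        raise ConnectivityError(f"seed {seed} lies outside the mask")
    seed_ts = series.data[seed[0], seed[1], seed[2], :]
    vox = series.data[m]
    z = zscores_batch(np.broadcast_to(seed_ts, vox.shape), vox)
    zmap = np.full(series.shape[:3], np.nan)
    zmap[m] = z
    supra = (np.abs(zmap) > threshold) if two_tailed else (zmap > threshold)
    supra &= m
    labels, n = label_clusters(supra, min_cluster, in_plane_only)
    return SeedMap(seed=tuple(seed), zmap=zmap, threshold=threshold,
                   min_cluster=min_cluster, two_tailed=two_tailed,
                   cluster_labels=labels, n_clusters=n)


# ---------------------------------------------------------------------------
# ROI-level 8x8 matrices


@dataclass
class SliceConnectivity:
    """Symmetric 8x8 z matrix over the quadrant sub-regions of one slice
    (diagonal stored as 0)."""

    slice_index: int
    z: np.ndarray
    r: np.ndarray | None = None
    roi_names: tuple = ROI_NAMES

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.z, index=self.roi_names,
                            columns=self.roi_names)


def roi_mean_series(series: Volume4D, sub: SubRegionMasks,
                    s: int) -> np.ndarray:
    """(8, n_volumes) matrix of sub-region mean time courses on slice s."""
    out = np.empty((len(ROI_NAMES), series.n_volumes))
    for i, name in enumerate(ROI_NAMES):
        m = sub.masks[name][:, :, s]
        if not m.any():
            raise ConnectivityError(f"sub-region {name} empty on slice {s}")
        out[i] = series.slice_data(s)[m, :].mean(axis=0)
    return out


def roi_connectivity(series: Volume4D, sub: SubRegionMasks,
                     s: int, dof_penalty: int = 0) -> SliceConnectivity:
    """8x8 z matrix between sub-region mean series on slice ``s``.

    ``dof_penalty`` is the number of nuisance-regressor dimensions
    already removed from the series; it is subtracted from the sample
    count before the autocorrelation correction.
    """
    ts = roi_mean_series(series, sub, s)
    n_eff = series.n_volumes - int(dof_penalty)
    n = ts.shape[0]
    z = np.zeros((n, n))
    r = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            st = correlation_stats(ts[i], ts[j], n_effective=n_eff)
            z[i, j] = z[j, i] = st.z
            r[i, j] = r[j, i] = st.r
    return SliceConnectivity(slice_index=s, z=z, r=r)
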