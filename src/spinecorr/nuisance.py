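"""Data-driven nuisance regression ("regressors of no interest").

Three PCA-based regressor families plus RETROICOR:

* not-spine PCA: principal components of all voxels outside the cord,
  capturing bulk intensity events (swallowing) and scanner-wide noise;
* CSF PCA: components of the CSF compartment, capturing residual
  quasi-periodic physiological noise shared with gray matter;
* white-matter eigenvector: the first principal component of the WM
  mask (optionally of a combined WM+GM mask or of an eroded WM mask);
* RETROICOR: low-order Fourier expansions of cardiac and respiratory
  phase evaluated at each slice's acquisition times.

Component counts follow a cumulative-variance cap with an eigenvalue-gap
stop: up to 80% cumulative variance for not-spine PCA and 50% for CSF
PCA, or until two successive (total-variance-normalized) eigenvalues
differ by less than 0.02.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .core import Volume4D
from .masks import erode_subregion
from .phantom import PhysioRecord


class RegressionError(ValueError):
    pass


@dataclass
class EigSelectionRule:
    """Stopping rule for PCA component selection."""

    cumulative_cap: float = 0.80
    gap_threshold: float = 0.02
    max_components: int = 10
    relative_gap: bool = False     # gap as a fraction of the prior eigenvalue

    def __post_init__(self) -> None:
        if not 0 < self.cumulative_cap <= 1:
            raise ValueError("cumulative cap must be in (0, 1]")
        if not 0 < self.gap_threshold < 1:
            raise ValueError("gap threshold must be in (0, 1)")


NOTSPINE_RULE = EigSelectionRule(cumulative_cap=0.80)
CSF_RULE = EigSelectionRule(cumulative_cap=0.50)


@dataclass
class RegressorSet:
    """Per-slice nuisance design matrix with provenance labels.

    ``matrix`` is (n_volumes, K); ``labels`` has one unique entry per
    column.  An intercept column is always present.
    """

    matrix: np.ndarray
    labels: list[str]
    eigenvalues: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=np.float64))
        if self.matrix.shape[1] != len(self.labels):
            raise RegressionError("label count does not match columns")
        if len(set(self.labels)) != len(self.labels):
            raise RegressionError("regressor labels must be unique")
        if not np.all(np.isfinite(self.matrix)):
            raise RegressionError("regressors contain non-finite values")

    @classmethod
    def intercept_only(cls, n_volumes: int) -> "RegressorSet":
        return cls(np.ones((n_volumes, 1)), ["intercept"])

    def with_columns(self, cols: np.ndarray, labels: list[str],
                     eigenvalues=None) -> "RegressorSet":
        cols = np.atleast_2d(np.asarray(cols, dtype=np.float64))
        if cols.shape[0] != self.matrix.shape[0]:
            cols = cols.T
        ev = self.eigenvalues if eigenvalues is None else eigenvalues
        return RegressorSet(np.column_stack([self.matrix, cols]),
                            self.labels + list(labels), ev)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.matrix, columns=self.labels).to_csv(
            path, sep="\t", index=False)


def _mask_series(series: Volume4D, mask: np.ndarray, s: int) -> np.ndarray:
    """(n_voxels, n_volumes) series of the masked voxels on slice ``s``."""
    m = mask[:, :, s] if mask.ndim == 3 else mask
    return series.slice_data(s)[m, :]


def pca_components(series: Volume4D, mask: np.ndarray, s: int,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Temporal PCA of the voxels of ``mask`` on slice ``s``.

    Voxel series are demeaned (not variance normalized).  Returns
    eigenvalues normalized to the total variance (descending, summing to
    1) and the corresponding unit-norm time-course eigenvectors as
    columns, signs fixed so each vector's first non-negligible element is
    positive.
    """
    x = _mask_series(series, mask, s)
    if x.shape[0] < 2:
        raise RegressionError("mask must contain at least 2 voxels")
    x = x - x.mean(axis=1, keepdims=True)
    total = (x ** 2).sum()
    if total <= 0:
        raise RegressionError("zero total variance within the mask")
    # eigendecomposition of the temporal covariance (Gram) matrix; its
    # eigenvectors are the component time courses
    gram = x.T @ x
    evals, evecs = np.linalg.eigh(gram)
    order = np.argsort(evals)[::-1]
    eig = np.clip(evals[order], 0.0, None) / total
    vecs = evecs[:, order]
    for j in range(vecs.shape[1]):
        col = vecs[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12 * np.abs(col).max())
        if nz.size and col[nz[0]] < 0:
            vecs[:, j] = -col
    return eig, vecs


def select_k(eigenvalues: np.ndarray, rule: EigSelectionRule) -> int:
    """Number of leading components to keep under ``rule``.

    k is the smallest count at which either the cumulative normalized
    variance reaches the cap or the drop to the next eigenvalue falls
    below the gap threshold; always at least 1 and at most
    ``rule.max_components``.
    """
    eig = np.asarray(eigenvalues, dtype=np.float64)
    if eig.size == 0:
        raise RegressionError("empty eigenvalue spectrum")
    cum = np.cumsum(eig)
    k = eig.size
    for i in range(eig.size):
        if cum[i] >= rule.cumulative_cap - 1e-12:
            k = i + 1
            break
        if i + 1 < eig.size:
            gap = eig[i] - eig[i + 1]
            if rule.relative_gap and eig[i] > 0:
                gap = gap / eig[i]
            if gap < rule.gap_threshold:
                k = i + 1
                break
    return max(1, min(k, rule.max_components))


def pca_regressors(series: Volume4D, mask: np.ndarray, s: int,
                   rule: EigSelectionRule, label_prefix: str,
                   ) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Convenience: PCA + selection; returns (columns, labels, spectrum)."""
    eig, vecs = pca_components(series, mask, s)
    k = select_k(eig, rule)
    labels = [f"{label_prefix}-pc{i + 1}" for i in range(k)]
    return vecs[:, :k], labels, eig


# ---------------------------------------------------------------------------
# RETROICOR


def cardiac_phase(times: np.ndarray, peak_times: np.ndarray) -> np.ndarray:
    """Cardiac phase: 2*pi * elapsed fraction of the enclosing R-R interval.

    Times outside the detected peak range use the first/last interval
    length for linear extrapolation of the beat grid.
    """
    peaks = np.asarray(peak_times, dtype=np.float64)
    if peaks.size < 2:
        raise RegressionError("need at least 2 cardiac peaks")
    t = np.asarray(times, dtype=np.float64)
    idx = np.searchsorted(peaks, t, side="right") - 1
    idx = np.clip(idx, 0, peaks.size - 2)
    t_prev = peaks[idx]
    t_next = peaks[idx + 1]
    return 2 * np.pi * (t - t_prev) / (t_next - t_prev)


def respiratory_phase(times: np.ndarray, record: PhysioRecord,
                      nbins: int = 100) -> np.ndarray:
    """Respiratory phase by amplitude-histogram equalization, signed with
    the derivative of the respiratory trace (Glover et al., 2000)."""
    r = record.resp
    if r.size < 2:
        raise RegressionError("respiratory trace too short")
    hist, edges = np.histogram(r, bins=nbins)
    cum = np.cumsum(hist) / hist.sum()
    r_t = np.interp(times, record.times, r)
    dr_t = np.interp(times, record.times, np.gradient(r, record.times))
    b = np.clip(np.searchsorted(edges[1:-1], r_t), 0, nbins - 1)
    phase = np.pi * cum[b]
    return phase * np.sign(np.where(dr_t == 0, 1.0, dr_t))


def detect_cardiac_peaks(record: PhysioRecord,
                         min_interval_s: float = 0.4) -> np.ndarray:
    """Peak times (s) of the cardiac trace."""
    distance = max(1, int(min_interval_s * record.fs))
    peaks, _ = signal.find_peaks(record.cardiac, distance=distance,
                                 prominence=0.1 * np.ptp(record.cardiac))
    if peaks.size < 2:
        raise RegressionError("fewer than 2 cardiac peaks detected")
    return peaks / record.fs


def retroicor_regressors(record: PhysioRecord, s: int, order: int = 2,
                         ) -> tuple[np.ndarray, list[str]]:
    """RETROICOR columns for slice ``s``: cos(m*phi), sin(m*phi) of the
    cardiac and respiratory phases at the slice's acquisition times,
    m = 1..order (8 columns at order 2)."""
    times = record.acq_times[s]
    peaks = detect_cardiac_peaks(record)
    phi_c = cardiac_phase(times, peaks)
    phi_r = respiratory_phase(times, record)
    cols, labels = [], []
    for tag, phi in (("c", phi_c), ("r", phi_r)):
        for m in range(1, order + 1):
            cols.append(np.cos(m * phi))
            labels.append(f"retroicor-{tag}{m}-cos")
            cols.append(np.sin(m * phi))
            labels.append(f"retroicor-{tag}{m}-sin")
    return np.column_stack(cols), labels


# ---------------------------------------------------------------------------
# white-matter eigenvector


def wm_eigenvector(series: Volume4D, wm_mask: np.ndarray, s: int,
                   variant: str = "wm", gm_mask: np.ndarray | None = None,
                   erode_radius: int = 1,
                   ) -> tuple[np.ndarray, float]:
    """First principal time course of the white-matter compartment.

    ``variant``: ``wm`` (default), ``wm+gm`` (combined WM and GM mask) or
    ``wm-eroded`` (WM mask eroded by ``erode_radius`` with fallback).
    Returns the unit-norm eigenvector and its explained-variance
    fraction.
    """
    if variant not in ("wm", "wm+gm", "wm-eroded"):
        raise ValueError(f"unknown variant {variant!r}")
    mask = np.asarray(wm_mask, dtype=bool)
    m2 = mask[:, :, s] if mask.ndim == 3 else mask
    if variant == "wm+gm":
        if gm_mask is None:
            raise RegressionError("variant 'wm+gm' needs the GM mask")
        g2 = gm_mask[:, :, s] if np.asarray(gm_mask).ndim == 3 else gm_mask
        m2 = m2 | np.asarray(g2, dtype=bool)
    elif variant == "wm-eroded":
        m2, _ = erode_subregion(m2, erode_radius)
    eig, vecs = pca_components(series, m2, s)
    return vecs[:, 0], float(eig[0])


# ---------------------------------------------------------------------------
# regression


def regress_out(series: Volume4D, regressors: RegressorSet,
                scope_mask: np.ndarray, s: int | None = None,
                copy: bool = True) -> Volume4D:
    """OLS residuals of every scope voxel on the regressor columns, with
    the voxel mean re-added.

    If ``s`` is given only that slice is touched; otherwise the same
    design is applied to the scope voxels of every slice.  Residuals are
    orthogonal to every regressor column (exact OLS property).  With
    ``copy=False`` the input volume is modified in place (used by the
    pipeline to avoid re-copying the 4-D array at every stage).
    """
    d = regressors.matrix
    if "intercept" not in regressors.labels:
        raise RegressionError("design must include an intercept")
    rank = np.linalg.matrix_rank(d)
    if rank < d.shape[1]:
        # name the offending columns via QR pivoting
        _, r = np.linalg.qr(d)
        bad = [regressors.labels[j] for j in range(d.shape[1])
               if abs(r[j, j]) < 1e-10 * abs(r[0, 0])]
        raise RegressionError(f"rank-deficient design; collinear columns: "
                              f"{bad or regressors.labels}")
    out = series.copy() if copy else series
    slices = range(series.n_slices) if s is None else [s]
    pinv = np.linalg.pinv(d)
    for sl in slices:
        m = scope_mask[:, :, sl] if scope_mask.ndim == 3 else scope_mask
        view = out.data[:, :, sl, :]
        if m.all() and np.shares_memory(
                view.reshape(-1, series.n_volumes), out.data):
            x = view.reshape(-1, series.n_volumes)       # view, no copy
            mean = x.mean(axis=1, keepdims=True)
            x -= (d @ (pinv @ x.T)).T
            x += mean
        else:
            x = view[m, :]                               # (n_vox, n_vol)
            mean = x.mean(axis=1, keepdims=True)
            beta = pinv @ x.T                            # (K, n_vox)
            view[m, :] = x - (d @ beta).T + mean
    return out
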