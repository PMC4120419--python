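"""Group-level nonparametric inference over ROI-pair z scores.

Per ROI pair the median z across slices is taken per subject; a
two-tailed Wilcoxon signed-rank test across subjects (exact by default)
asks whether the group distribution differs from zero, Bonferroni
corrected for the C(8,2) = 28 ROI pairs; box-whisker summaries describe
the significant distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .masks import ROI_NAMES

#: Number of pairwise comparisons among the 8 sub-regions.
N_COMPARISONS = len(ROI_NAMES) * (len(ROI_NAMES) - 1) // 2   # 28

#: Largest sample size at which the exact signed-rank null is enumerated.
EXACT_MAX_N = 25


class GroupError(ValueError):
    pass


@dataclass
class GroupMatrix:
    """Per-subject 8x8 median-z matrices."""

    matrices: np.ndarray                     # (n_subjects, 8, 8)
    slice_counts: np.ndarray | None = None   # (n_subjects,)
    roi_names: tuple = ROI_NAMES

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, dtype=np.float64)
        if self.matrices.ndim != 3 or self.matrices.shape[1:] != (8, 8):
            raise GroupError("expected an (n_subjects, 8, 8) array")
        if not np.allclose(self.matrices,
                           np.swapaxes(self.matrices, 1, 2), atol=1e-10):
            raise GroupError("subject matrices must be symmetric")
        if self.slice_counts is None:
            self.slice_counts = np.zeros(self.matrices.shape[0], dtype=int)

    @property
    def n_subjects(self) -> int:
        return self.matrices.shape[0]

    def pair_values(self, i: int, j: int) -> np.ndarray:
        return self.matrices[:, i, j]


def subject_median(slice_matrices: np.ndarray) -> np.ndarray:
    """Elementwise median over the slice axis of an (n_slices, 8, 8)
    stack (the per-subject unthresholded median z)."""
    m = np.asarray(slice_matrices, dtype=np.float64)
    if m.ndim != 3:
        raise GroupError("expected an (n_slices, 8, 8) stack")
    if m.shape[0] < 1:
        raise GroupError("need at least one slice")
    return np.median(m, axis=0)


def group_matrix_from_slices(per_subject_slices) -> GroupMatrix:
    """Build the GroupMatrix from per-subject (n_slices, 8, 8) stacks."""
    meds = np.stack([subject_median(s) for s in per_subject_slices])
    counts = np.array([np.asarray(s).shape[0] for s in per_subject_slices])
    return GroupMatrix(matrices=meds, slice_counts=counts)


# ---------------------------------------------------------------------------
# exact Wilcoxon signed-rank test


def _signed_rank_distribution(double_ranks: np.ndarray) -> np.ndarray:
    """Counts of the doubled positive-rank sum over all sign patterns.

    Midranks are multiples of 1/2, so doubling makes them integers; the
    returned array c satisfies c[w] = #{sign patterns with 2*W+ = w}.
    """
    total = int(double_ranks.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in double_ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:counts.size - r]
        counts = counts + shifted
    return counts


def signed_rank_test(values, tails: str = "two") -> tuple[float, float]:
    """Wilcoxon signed-rank test of median zero.

    Zeros are dropped; ties receive midranks.  For n <= 25 the p-value is
    exact (full enumeration of the 2^n sign assignments, computed by
    convolution); above that a normal approximation with continuity
    correction and midrank variance is used.

    Returns (W+ statistic, p-value).  ``tails`` is ``"two"``,
    ``"greater"`` (positive shift) or ``"less"``.
    """
    v = np.asarray(values, dtype=np.float64)
    v = v[v != 0]
    n = v.size
    if n < 1:
        raise GroupError("all values are zero: signed-rank test undefined")
    ranks = stats.rankdata(np.abs(v))
    w_pos = float(ranks[v > 0].sum())
    s = float(ranks.sum())
    if n <= EXACT_MAX_N:
        dr = np.rint(2 * ranks).astype(int)
        counts = _signed_rank_distribution(dr)
        total = counts.sum()
        w2 = int(round(2 * w_pos))
        p_le = counts[: w2 + 1].sum() / total
        p_ge = counts[w2:].sum() / total
    else:
        mean = s / 2.0
        sd = np.sqrt((ranks ** 2).sum() / 4.0)
        p_le = stats.norm.cdf((w_pos - mean + 0.5) / sd)
        p_ge = stats.norm.sf((w_pos - mean - 0.5) / sd)
    if tails == "two":
        p = min(1.0, 2.0 * min(p_le, p_ge))
    elif tails == "greater":
        p = p_ge
    elif tails == "less":
        p = p_le
    else:
        raise ValueError(f"unknown tails {tails!r}")
    return w_pos, float(p)


def bonferroni_tier(p: float, n_comparisons: int = N_COMPARISONS) -> str:
    """Significance tier after Bonferroni correction: ``"p<0.01"``,
    ``"p<0.05"`` or ``"ns"``."""
    if not 0 <= p <= 1:
        raise GroupError("p must be in [0, 1]")
    if n_comparisons < 1:
        raise GroupError("n_comparisons must be >= 1")
    if p < 0.01 / n_comparisons:
        return "p<0.01"
    if p < 0.05 / n_comparisons:
        return "p<0.05"
    return "ns"


def slice_significance_fraction(z_values,
                                threshold: float = 1.65,
                                ) -> tuple[int, int, int]:
    """Count and integer percentage of slices with z above ``threshold``
    (positive correlations at the one-tailed 95% confidence level).

    Percentages are rounded half-up to match integer reporting.
    """
    z = np.asarray(z_values, dtype=np.float64)
    total = z.size
    if total == 0:
        raise GroupError("no slice values supplied")
    count = int((z > threshold).sum())
    percent = int(np.floor(100.0 * count / total + 0.5))
    return count, total, percent


@dataclass
class BoxStats:
    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    outliers: np.ndarray


def box_stats(values) -> BoxStats:
    """Box-whisker summary: quartiles by linear interpolation, whiskers at
    the most extreme data within 1.5 IQR of the quartiles, points beyond
    flagged as outliers."""
    v = np.sort(np.asarray(values, dtype=np.float64))
    if v.size < 3:
        raise GroupError("need at least 3 values for box statistics")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return BoxStats(median=float(med), q1=float(q1), q3=float(q3),
                    whisker_lo=float(inside.min()),
                    whisker_hi=float(inside.max()),
                    outliers=v[(v < lo_fence) | (v > hi_fence)])


@dataclass
class PairResult:
    pair: tuple[str, str]
    statistic: float
    p: float
    tier: str
    box: BoxStats


@dataclass
class GroupResult:
    """Per-ROI-pair group statistics."""

    pairs: dict[tuple[str, str], PairResult]
    n_subjects: int
    n_comparisons: int = N_COMPARISONS

    def tier(self, name_a: str, name_b: str) -> str:
        key = (name_a, name_b) if (name_a, name_b) in self.pairs \
            else (name_b, name_a)
        return self.pairs[key].tier

    def significant_pairs(self) -> list[tuple[str, str]]:
        return [k for k, v in self.pairs.items() if v.tier != "ns"]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (a, b), res in self.pairs.items():
            rows.append({
                "roi_a": a, "roi_b": b, "statistic": res.statistic,
                "p": res.p, "tier": res.tier, "median": res.box.median,
                "q1": res.box.q1, "q3": res.box.q3,
                "whisker_lo": res.box.whisker_lo,
                "whisker_hi": res.box.whisker_hi,
                "n_outliers": res.box.outliers.size,
            })
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def group_pipeline(gm: GroupMatrix, tails: str = "two",
                   n_comparisons: int = N_COMPARISONS) -> GroupResult:
    """Signed-rank + Bonferroni + box statistics for all 28 ROI pairs."""
    if gm.n_subjects < 6:
        raise GroupError("need at least 6 subjects for the exact test to "
                         "reach corrected significance")
    pairs = {}
    for i, j in combinations(range(len(gm.roi_names)), 2):
        vals = gm.pair_values(i, j)
        if np.all(vals == 0):
            res = PairResult(pair=(gm.roi_names[i], gm.roi_names[j]),
                             statistic=0.0, p=1.0, tier="ns",
                             box=box_stats(vals))
        else:
            stat, p = signed_rank_test(vals, tails=tails)
            res = PairResult(pair=(gm.roi_names[i], gm.roi_names[j]),
                             statistic=stat, p=p,
                             tier=bonferroni_tier(p, n_comparisons),
                             box=box_stats(vals))
        pairs[res.pair] = res
    return GroupResult(pairs=pairs, n_subjects=gm.n_subjects,
                       n_comparisons=n_comparisons)


def read_group_matrix(path) -> GroupMatrix:
    """Read an externally supplied 8 x 8 x n matrix from a plain text
    export: whitespace- or tab-separated, 8*n rows of 8 values (subject
    blocks stacked vertically)."""
    arr = np.loadtxt(path)
    if arr.ndim != 2 or arr.shape[1] != 8 or arr.shape[0] % 8:
        raise GroupError("expected 8*n rows of 8 columns")
    n = arr.shape[0] // 8
    return GroupMatrix(matrices=arr.reshape(n, 8, 8))
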