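"""Shared statistical primitives for the proteomics pipelines.

Conventions used throughout the package:

* missing measurements are NaN; column-minimum imputation replaces each
  missing cell with the smallest observed value of its sample column (the
  usual left-censoring assumption for label-free MS intensities);
* intensities are log2-transformed after imputation and all fold changes
  are differences of log2 means;
* two-sample comparisons use Student's t by default (pooled variance,
  two-sided), with Welch as an option;
* the adaptive fold-change threshold is ``multiplier x average SD`` of the
  replicate-wise log2 ratios, where the per-replicate dispersion is by
  default a normal-consistent MAD (robust to the regulated minority, which
  is the point of estimating null dispersion from mostly-null data); the
  plain sample SD is available via ``estimator="sample"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AdaptiveThreshold",
    "impute_column_min",
    "log2_transform",
    "two_sample_t",
    "two_sample_t_matrix",
    "bh_adjust",
    "adaptive_sd_threshold",
]

_MAD_SCALE = 1.4826022185056018  # 1 / Phi^{-1}(3/4): MAD -> SD under normality


@dataclass
class AdaptiveThreshold:
    """A data-driven |log2FC| cutoff: ``threshold = multiplier * average_sd``."""

    average_sd: float
    multiplier: float
    per_replicate_sd: np.ndarray

    @property
    def threshold(self) -> float:
        return self.multiplier * self.average_sd


def _as_frame(matrix):
    if isinstance(matrix, pd.DataFrame):
        return matrix, True
    return pd.DataFrame(np.asarray(matrix, dtype=float)), False


def impute_column_min(matrix):
    """Replace each missing (NaN) cell with the minimum present value of its
    column.  Present values are never changed.  A fully missing column is an
    error (there is nothing to impute from)."""
    frame, was_frame = _as_frame(matrix)
    out = frame.astype(float).copy()
    for col in out.columns:
        vals = out[col]
        if vals.isna().all():
            raise ValueError(f"column {col!r} has no present values to impute from")
        out[col] = vals.fillna(vals.min())
    return out if was_frame else out.to_numpy()


def log2_transform(matrix):
    """Elementwise log2; zero or negative entries raise with coordinates
    (they signal that imputation was skipped)."""
    frame, was_frame = _as_frame(matrix)
    arr = frame.to_numpy(dtype=float)
    bad = ~(arr > 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-positive value {arr[i, j]!r} at row {frame.index[i]!r}, "
            f"column {frame.columns[j]!r}; impute before log2 transform"
        )
    out = pd.DataFrame(np.log2(arr), index=frame.index, columns=frame.columns)
    return out if was_frame else out.to_numpy()


def two_sample_t(a, b, variant: str = "student") -> tuple[float, float]:
    """Two-sided two-sample t test.

    ``student`` pools the variance; ``welch`` does not.  Both groups constant
    and equal returns (0, 1) by convention; zero pooled variance with unequal
    means returns (+-inf, 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if variant not in {"student", "welch"}:
        raise ValueError("variant must be 'student' or 'welch'")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return (np.inf if a.mean() > b.mean() else -np.inf), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=(variant == "student"))
    return float(t), float(p)


def two_sample_t_matrix(a, b, variant: str = "student") -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sample t over 2-D arrays (features x replicates)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs at least 2 replicate columns")
    t, p = sps.ttest_ind(a, b, axis=1, equal_var=(variant == "student"))
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    # degenerate rows: zero variance in both groups
    degen = np.isnan(t)
    if degen.any():
        equal = degen & np.isclose(a.mean(axis=1), b.mean(axis=1))
        t[equal], p[equal] = 0.0, 1.0
        unequal = degen & ~equal
        t[unequal] = np.where(a.mean(axis=1)[unequal] > b.mean(axis=1)[unequal], np.inf, -np.inf)
        p[unequal] = 0.0
    return t, p


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (with monotonicity)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _column_scale(values: np.ndarray, estimator: str) -> float:
    if estimator == "sample":
        return float(np.std(values, ddof=1))
    if estimator == "mad":
        med = np.median(values)
        return float(_MAD_SCALE * np.median(np.abs(values - med)))
    raise ValueError("estimator must be 'sample' or 'mad'")


def adaptive_sd_threshold(
    log2fc_matrix,
    multiplier: float = 2.0,
    mode: str = "per_replicate",
    estimator: str = "mad",
) -> AdaptiveThreshold:
    """Compute the adaptive ``multiplier x average SD`` fold-change cutoff.

    ``log2fc_matrix`` holds replicate-wise log2 fold changes
    (features x replicates).  In the default ``per_replicate`` mode the
    dispersion of each replicate column across features is estimated and
    averaged over replicates; ``per_feature`` averages the per-feature SD
    across replicates instead.
    """
    frame, _ = _as_frame(log2fc_matrix)
    arr = frame.to_numpy(dtype=float)
    if arr.shape[1] < 2:
        raise ValueError("need at least 2 replicate columns")
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    if mode == "per_replicate":
        sds = np.array([_column_scale(arr[:, j][~np.isnan(arr[:, j])], estimator) for j in range(arr.shape[1])])
    elif mode == "per_feature":
        if estimator == "sample":
            sds = np.nanstd(arr, axis=1, ddof=1)
        else:
            med = np.nanmedian(arr, axis=1, keepdims=True)
            sds = _MAD_SCALE * np.nanmedian(np.abs(arr - med), axis=1)
    else:
        raise ValueError("mode must be 'per_replicate' or 'per_feature'")
    return AdaptiveThreshold(average_sd=float(np.mean(sds)), multiplier=float(multiplier), per_replicate_sd=sds)
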