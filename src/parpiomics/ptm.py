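"""Differential post-translational-modification analysis.

Two workflows share this module:

* **TMT phosphoproteomics** — reporter-ion intensities for six channels
  (three treated / three vehicle pairs).  Channels are brought onto a common
  scale by iterative rank-order normalization (a rank-invariant-set method:
  features whose rank agrees between a column and the reference are used to
  fit a monotone per-column scaling), then replicate-wise log2 ratios
  (treated - vehicle) are computed.  A site is called regulated when
  |log2FC| exceeds the adaptive ``2 x average SD`` threshold, Student p is
  below 0.05, and the precursor mass error lies within +-3 ppm.

* **Label-free ADP-ribosylome** — drug vs vehicle protein intensities after
  click-chemistry enrichment of ADP-ribosylated proteins.  Missing values
  are imputed with the column minimum, intensities are log2 transformed,
  and a protein is called modulated at raw fold change >= 2 (|log2FC| >= 1,
  inclusive at the cutoff) with p < 0.05.  Negative log2FC means decreased
  ADP-ribosylation under drug.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.isotonic import IsotonicRegression

from .stats import (
    adaptive_sd_threshold,
    impute_column_min,
    log2_transform,
    two_sample_t_matrix,
)
from .tables import QuantTable, SampleDesign

logger = logging.getLogger(__name__)

__all__ = [
    "TmtPhosphoExperiment",
    "AdprExperiment",
    "IronNormalizer",
    "iron_normalize",
    "ppm_gate",
    "regulation_gate",
    "PhosphoDifferential",
    "AdprDifferential",
    "phospho_differential",
    "adpr_differential",
]


@dataclass
class TmtPhosphoExperiment:
    """Reporter-ion quantification plus the design mapping channels to
    treated/vehicle replicates for one cell line."""

    quant: QuantTable
    design: SampleDesign
    isolation_purity_min: float = 0.75  # informational; enforced upstream by the search engine

    def arm_columns(self, cell_line: Optional[str] = None) -> tuple[list[str], list[str]]:
        treated = self.design.select(role="treated", **({"cell_line": cell_line} if cell_line else {}))
        vehicle = self.design.select(role="vehicle", **({"cell_line": cell_line} if cell_line else {}))
        if len(treated) < 2 or len(vehicle) < 2:
            raise ValueError("need at least 2 treated and 2 vehicle channels")
        if len(treated) != len(vehicle):
            raise ValueError("treated and vehicle replicate counts must match for pairing")
        return list(treated["sample_id"]), list(vehicle["sample_id"])


@dataclass
class AdprExperiment:
    """Label-free drug-vs-vehicle protein intensities with design."""

    quant: QuantTable
    design: SampleDesign

    def arm_columns(self, cell_line: Optional[str] = None) -> tuple[list[str], list[str]]:
        treated = self.design.select(role="treated", **({"cell_line": cell_line} if cell_line else {}))
        vehicle = self.design.select(role="vehicle", **({"cell_line": cell_line} if cell_line else {}))
        if len(treated) < 2 or len(vehicle) < 2:
            raise ValueError("need at least 2 replicates in each arm")
        return list(treated["sample_id"]), list(vehicle["sample_id"])


class IronNormalizer(BaseEstimator, TransformerMixin):
    """Iterative rank-order normalization (rank-invariant-set scaling).

    The procedure, in log2 space:

    1. choose a reference column (``reference="auto"`` picks the column with
       minimal summed absolute rank displacement against the element-wise
       median pseudo-column);
    2. start with all features in the invariant set;
    3. iterate: rank the invariant features within each column, compute each
       feature's largest rank displacement against the reference, and drop
       the most-displaced ``trim`` fraction (only features actually
       displaced); stop when the set stabilizes or after ``max_iter``;
    4. fit, per column, a monotone (isotonic, piecewise-linear) map onto the
       reference over the invariant set, extended by a constant log-offset
       beyond its range, and shift so the median column-to-reference log
       ratio over the invariant set is exactly zero.

    The reference column is left unchanged.  ``scale_factors_`` reports the
    per-column median multiplicative change (the fitted scale), so a column
    that is an exact 2x inflation of the reference gets scale ~0.5.
    """

    def __init__(self, reference: str | int = "auto", trim: float = 0.05, max_iter: int = 10):
        self.reference = reference
        self.trim = trim
        self.max_iter = max_iter

    def fit(self, X: pd.DataFrame, y=None) -> "IronNormalizer":
        X = self._validate(X)
        L = np.log2(X.to_numpy(dtype=float))
        n, m = L.shape
        cols = list(X.columns)

        if self.reference == "auto":
            pseudo = np.median(L, axis=1)
            pseudo_rank = rankdata(pseudo)
            disp = [np.abs(rankdata(L[:, j]) - pseudo_rank).sum() for j in range(m)]
            ref_idx = int(np.argmin(disp))
        else:
            ref_idx = cols.index(self.reference) if isinstance(self.reference, str) else int(self.reference)

        invariant = np.ones(n, dtype=bool)
        self.n_iter_ = 0
        for _ in range(self.max_iter):
            self.n_iter_ += 1
            idx = np.flatnonzero(invariant)
            ref_rank = rankdata(L[idx, ref_idx])
            disp = np.zeros(len(idx))
            for j in range(m):
                if j == ref_idx:
                    continue
                disp = np.maximum(disp, np.abs(rankdata(L[idx, j]) - ref_rank))
            n_drop = int(np.ceil(self.trim * len(idx)))
            displaced = np.flatnonzero(disp > 0)
            if len(displaced) == 0 or n_drop == 0:
                break  # invariant set has stabilized
            order = displaced[np.argsort(disp[displaced])[::-1]]
            invariant[idx[order[:n_drop]]] = False

        # monotone per-column maps fitted on the invariant set
        inv_idx = np.flatnonzero(invariant)
        self._maps = {}
        scales = {}
        for j, col in enumerate(cols):
            if j == ref_idx:
                self._maps[col] = None
                scales[col] = 1.0
                continue
            x = L[inv_idx, j]
            y_ref = L[inv_idx, ref_idx]
            order = np.argsort(x, kind="mergesort")
            iso = IsotonicRegression(increasing=True)
            yhat = iso.fit_transform(x[order], y_ref[order])
            knots_x, start = np.unique(x[order], return_index=True)
            counts = np.diff(np.append(start, len(yhat)))
            knots_y = np.add.reduceat(yhat, start) / counts
            mapped_inv = self._apply_map(x, knots_x, knots_y)
            shift = np.median(mapped_inv - y_ref)
            knots_y = knots_y - shift
            self._maps[col] = (knots_x, knots_y)
            scales[col] = float(2.0 ** np.median(self._apply_map(x, knots_x, knots_y) - x))

        self.reference_ = cols[ref_idx]
        self.invariant_mask_ = pd.Series(invariant, index=X.index)
        self.scale_factors_ = pd.Series(scales)[cols]
        self._columns = cols
        return self

    @staticmethod
    def _apply_map(x: np.ndarray, kx: np.ndarray, ky: np.ndarray) -> np.ndarray:
        """Piecewise-linear interpolation through the knots, extended by a
        constant log-offset beyond the fitted range."""
        out = np.interp(x, kx, ky)
        below = x < kx[0]
        above = x > kx[-1]
        out[below] = x[below] + (ky[0] - kx[0])
        out[above] = x[above] + (ky[-1] - kx[-1])
        return out

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = self._validate(X)
        if list(X.columns) != self._columns:
            raise ValueError("columns do not match the fitted matrix")
        L = np.log2(X.to_numpy(dtype=float))
        out = L.copy()
        for j, col in enumerate(self._columns):
            knots = self._maps[col]
            if knots is not None:
                out[:, j] = self._apply_map(L[:, j], *knots)
        return pd.DataFrame(2.0 ** out, index=X.index, columns=X.columns)

    @staticmethod
    def _validate(X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        if X.shape[1] < 2:
            raise ValueError("need at least 2 columns to normalize")
        if not (X.to_numpy(dtype=float) > 0).all():
            raise ValueError("intensities must be strictly positive (impute first)")
        return X


def iron_normalize(matrix, reference: str | int = "auto", trim: float = 0.05,
                   max_iter: int = 10) -> tuple[pd.DataFrame, pd.Series]:
    """Functional wrapper over :class:`IronNormalizer`; returns the
    normalized matrix and the per-column scale report."""
    norm = IronNormalizer(reference=reference, trim=trim, max_iter=max_iter)
    out = norm.fit(matrix).transform(matrix)
    return out, norm.scale_factors_


def ppm_gate(mass_error_ppm, tol: float = 3.0) -> np.ndarray:
    """True where the signed precursor mass error is within the closed
    interval [-tol, +tol] ppm.  A missing mass-error field passes everything
    (with a logged warning)."""
    if mass_error_ppm is None:
        logger.warning("no mass-error column available; ppm gate is a no-op")
        return np.array([], dtype=bool)
    err = np.asarray(mass_error_ppm, dtype=float)
    return np.abs(err) <= tol


def regulation_gate(log2fc, p, threshold: float, p_cutoff: float, ppm_ok=None,
                    inclusive_fc: bool = False) -> np.ndarray:
    """Combined pass flag: |log2FC| against the threshold (strict by
    default, inclusive for the fixed ADPr cutoff), p-value, and optional
    ppm gate."""
    log2fc = np.asarray(log2fc, dtype=float)
    p = np.asarray(p, dtype=float)
    fc_ok = np.abs(log2fc) >= threshold if inclusive_fc else np.abs(log2fc) > threshold
    ok = fc_ok & (p < p_cutoff)
    if ppm_ok is not None and len(np.asarray(ppm_ok)):
        ok = ok & np.asarray(ppm_ok, dtype=bool)
    return ok


class PhosphoDifferential(BaseEstimator):
    """TMT phosphoproteomics differential analysis for one contrast.

    Pipeline: column-minimum imputation -> IRON normalization -> log2 ->
    replicate-wise log2 ratios (treated - vehicle, paired by replicate
    number) -> mean log2FC with Student t across channels -> adaptive
    ``sd_multiplier x average SD`` threshold -> pass flag combining the
    fold-change, p-value and +-``ppm_tol`` mass-error gates.

    Attributes
    ----------
    results_ : DataFrame (feature-indexed) with log2fc, p_value, q_value,
        ppm_ok, passes, mean_treated, mean_vehicle.
    threshold_ : AdaptiveThreshold
    ratio_matrix_ : DataFrame of replicate-wise log2 ratios.
    """

    def __init__(self, p_cutoff: float = 0.05, sd_multiplier: float = 2.0, ppm_tol: float = 3.0,
                 sd_mode: str = "per_replicate", sd_estimator: str = "mad",
                 t_variant: str = "student", impute_first: bool = True,
                 normalize: bool = True):
        self.p_cutoff = p_cutoff
        self.sd_multiplier = sd_multiplier
        self.ppm_tol = ppm_tol
        self.sd_mode = sd_mode
        self.sd_estimator = sd_estimator
        self.t_variant = t_variant
        self.impute_first = impute_first
        self.normalize = normalize

    def fit(self, experiment: TmtPhosphoExperiment, cell_line: Optional[str] = None) -> "PhosphoDifferential":
        treated_cols, vehicle_cols = experiment.arm_columns(cell_line)
        mat = experiment.quant.intensity_matrix()[treated_cols + vehicle_cols]
        if self.impute_first:
            mat = impute_column_min(mat)
        if self.normalize:
            norm = IronNormalizer()
            mat = norm.fit(mat).transform(mat)
            self.normalizer_ = norm
        if not self.impute_first:
            mat = impute_column_min(mat)
        log_mat = log2_transform(mat)

        treated = log_mat[treated_cols].to_numpy()
        vehicle = log_mat[vehicle_cols].to_numpy()
        ratios = treated - vehicle  # paired by replicate order from the design
        self.ratio_matrix_ = pd.DataFrame(
            ratios, index=log_mat.index,
            columns=[f"rep{i + 1}" for i in range(ratios.shape[1])],
        )
        self.threshold_ = adaptive_sd_threshold(
            self.ratio_matrix_, multiplier=self.sd_multiplier,
            mode=self.sd_mode, estimator=self.sd_estimator,
        )
        log2fc = ratios.mean(axis=1)
        _, p = two_sample_t_matrix(treated, vehicle, variant=self.t_variant)

        err = experiment.quant.column("mass_error_ppm")
        if err is not None:
            ppm_ok = ppm_gate(err.to_numpy(), tol=self.ppm_tol)
        else:
            ppm_gate(None, tol=self.ppm_tol)
            ppm_ok = np.ones(len(log_mat), dtype=bool)

        from .stats import bh_adjust

        passes = regulation_gate(log2fc, p, self.threshold_.threshold, self.p_cutoff, ppm_ok)
        self.results_ = pd.DataFrame(
            {
                "log2fc": log2fc,
                "p_value": p,
                "q_value": bh_adjust(p),
                "ppm_ok": ppm_ok,
                "passes": passes,
                "mean_treated": treated.mean(axis=1),
                "mean_vehicle": vehicle.mean(axis=1),
            },
            index=log_mat.index,
        )
        return self


class AdprDifferential(BaseEstimator):
    """Label-free ADP-ribosylome differential analysis (drug vs vehicle).

    Pipeline: column-minimum imputation -> log2 -> per-protein mean log2FC
    (treated - vehicle) with Student t -> pass at raw fold change >=
    ``fc_cutoff_raw`` (inclusive) and p < ``p_cutoff`` (the p gate can be
    disabled).  Negative log2FC = decreased modification under drug.
    """

    def __init__(self, fc_cutoff_raw: float = 2.0, p_cutoff: float = 0.05,
                 use_p_gate: bool = True, t_variant: str = "student"):
        self.fc_cutoff_raw = fc_cutoff_raw
        self.p_cutoff = p_cutoff
        self.use_p_gate = use_p_gate
        self.t_variant = t_variant

    def fit(self, experiment: AdprExperiment, cell_line: Optional[str] = None) -> "AdprDifferential":
        treated_cols, vehicle_cols = experiment.arm_columns(cell_line)
        mat = experiment.quant.intensity_matrix()[treated_cols + vehicle_cols]
        log_mat = log2_transform(impute_column_min(mat))
        treated = log_mat[treated_cols].to_numpy()
        vehicle = log_mat[vehicle_cols].to_numpy()
        log2fc = treated.mean(axis=1) - vehicle.mean(axis=1)
        _, p = two_sample_t_matrix(treated, vehicle, variant=self.t_variant)

        from .stats import bh_adjust

        passes = regulation_gate(
            log2fc, p, np.log2(self.fc_cutoff_raw),
            self.p_cutoff if self.use_p_gate else 1.0 + 1e-9,
            inclusive_fc=True,
        )
        self.results_ = pd.DataFrame(
            {
                "log2fc": log2fc,
                "p_value": p,
                "q_value": bh_adjust(p),
                "passes": passes,
                "direction": np.where(log2fc < 0, "down", "up"),
                "mean_treated": treated.mean(axis=1),
                "mean_vehicle": vehicle.mean(axis=1),
            },
            index=log_mat.index,
        )
        return self


def phospho_differential(experiment: TmtPhosphoExperiment, p_cutoff: float = 0.05,
                         sd_multiplier: float = 2.0, ppm_tol: float = 3.0,
                         cell_line: Optional[str] = None, **kwargs) -> pd.DataFrame:
    """Functional wrapper over :class:`PhosphoDifferential`."""
    est = PhosphoDifferential(p_cutoff=p_cutoff, sd_multiplier=sd_multiplier, ppm_tol=ppm_tol, **kwargs)
    return est.fit(experiment, cell_line=cell_line).results_


def adpr_differential(experiment: AdprExperiment, fc_cutoff_raw: float = 2.0,
                      p_cutoff: float = 0.05, cell_line: Optional[str] = None,
                      **kwargs) -> pd.DataFrame:
    """Functional wrapper over :class:`AdprDifferential`."""
    est = AdprDifferential(fc_cutoff_raw=fc_cutoff_raw, p_cutoff=p_cutoff, **kwargs)
    return est.fit(experiment, cell_line=cell_line).results_
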