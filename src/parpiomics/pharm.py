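"""Dose-response fitting and Bliss-independence drug-synergy analysis.

Viability readouts (e.g. crystal violet absorbance) are normalized to the
mean of vehicle wells; fraction affected is fa = 1 - normalized viability,
clipped to [0, 1].  Single agents are fit with the four-parameter logistic

    y = bottom + (top - bottom) / (1 + (x / IC50)^hill)

(relative IC50 at the inflection, Hill slope > 0 for a decreasing viability
curve).  Combinations are scored against the Bliss independence null

    fa_expected = fa_A + fa_B - fa_A * fa_B,
    delta_Bliss = fa_observed - fa_expected,

so positive delta indicates synergy and negative delta antagonism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

logger = logging.getLogger(__name__)

__all__ = [
    "DoseResponse",
    "SynergyGrid",
    "normalize_to_vehicle",
    "fraction_affected",
    "FourParamLogistic",
    "fit_4pl",
    "bliss_delta",
    "synergy_grid",
    "read_single_agent_csv",
    "read_combo_csv",
]


@dataclass
class DoseResponse:
    """Single-agent viability data: concentrations (uM, strictly increasing)
    by replicates, as fraction of vehicle control."""

    drug: str
    concentrations: np.ndarray
    response: np.ndarray  # shape (n_conc, n_reps), viability fractions
    fitted: Optional[dict] = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.response = np.atleast_2d(np.asarray(self.response, dtype=float))
        if self.response.shape[0] != len(self.concentrations):
            raise ValueError("response must have one row per concentration")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be positive (vehicle is the normalizer, not a dose)")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")

    def mean_response(self) -> np.ndarray:
        return self.response.mean(axis=1)

    def fraction_affected(self) -> np.ndarray:
        return fraction_affected(self.mean_response())


@dataclass
class SynergyGrid:
    """Observed, Bliss-expected and delta fraction-affected over a
    concentration x concentration combination grid."""

    drug_a: str
    drug_b: str
    conc_a: np.ndarray
    conc_b: np.ndarray
    fa_obs: pd.DataFrame
    fa_expected: pd.DataFrame
    delta_bliss: pd.DataFrame

    def mean_delta(self, max_expected: Optional[float] = None) -> float:
        """Mean delta over the grid; ``max_expected`` restricts to cells
        whose Bliss expectation leaves headroom (fa_expected <= value),
        where an added synergy offset is identifiable."""
        delta = self.delta_bliss.to_numpy()
        if max_expected is not None:
            mask = self.fa_expected.to_numpy() <= max_expected
            if not mask.any():
                return float("nan")
            return float(delta[mask].mean())
        return float(delta.mean())

    def max_cell(self) -> tuple[float, float, float]:
        """(conc_a, conc_b, delta) of the maximal-delta cell."""
        arr = self.delta_bliss.to_numpy()
        i, j = np.unravel_index(np.argmax(arr), arr.shape)
        return float(self.conc_a[i]), float(self.conc_b[j]), float(arr[i, j])


def normalize_to_vehicle(raw, vehicle_values) -> np.ndarray:
    """Divide raw signals by the mean of vehicle replicates."""
    vehicle = np.asarray(vehicle_values, dtype=float)
    mean_vehicle = vehicle.mean()
    if not mean_vehicle > 0:
        raise ValueError("vehicle mean must be positive")
    return np.asarray(raw, dtype=float) / mean_vehicle


def fraction_affected(viability) -> np.ndarray:
    """fa = 1 - normalized viability, clipped into [0, 1] for Bliss use."""
    v = np.asarray(viability, dtype=float)
    fa = 1.0 - v
    n_clipped = int(np.sum((fa < 0) | (fa > 1)))
    if n_clipped:
        logger.info("clipped %d fraction-affected values into [0, 1]", n_clipped)
    return np.clip(fa, 0.0, 1.0)


def _4pl(x, bottom, top, ic50, hill):
    return bottom + (top - bottom) / (1.0 + (x / ic50) ** hill)


class FourParamLogistic(BaseEstimator, RegressorMixin):
    """Least-squares four-parameter logistic fit with multi-start
    initialization.

    Parameters are constrained to 0 <= bottom <= top <= 1.2, IC50 > 0,
    hill in [0.1, 10]; starts are taken on a grid of IC50 over the observed
    concentration range crossed with hill in {0.5, 1, 2}.  A fit whose
    dynamic range (top - bottom) is below ``min_span`` is flagged
    non-convergent with undefined IC50 (a flat curve has no inflection).

    Attributes: ``bottom_``, ``top_``, ``ic50_``, ``hill_``,
    ``converged_``, ``residuals_``.
    """

    def __init__(self, min_span: float = 0.1, max_top: float = 1.2):
        self.min_span = min_span
        self.max_top = max_top

    def fit(self, x, y) -> "FourParamLogistic":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(np.unique(x)) < 4:
            raise ValueError("need at least 4 distinct positive concentrations")
        if np.any(x <= 0):
            raise ValueError("concentrations must be positive")

        # theta = (bottom, span, log10 ic50, hill); top = bottom + span
        def resid(theta):
            bottom, span, logc, hill = theta
            return _4pl(x, bottom, bottom + span, 10.0 ** logc, hill) - y

        lo = np.array([0.0, 0.0, np.log10(x.min()) - 2.0, 0.1])
        hi = np.array([self.max_top, self.max_top, np.log10(x.max()) + 2.0, 10.0])
        best = None
        for logc0 in np.linspace(np.log10(x.min()), np.log10(x.max()), 5):
            for hill0 in (0.5, 1.0, 2.0):
                theta0 = np.clip(
                    np.array([max(y.min(), 0.0), max(y.max() - y.min(), 0.05), logc0, hill0]), lo, hi
                )
                try:
                    sol = least_squares(resid, theta0, bounds=(lo, hi))
                except ValueError:
                    continue
                if best is None or sol.cost < best.cost:
                    best = sol
        if best is None:
            raise RuntimeError("no 4PL start converged")

        bottom, span, logc, hill = best.x
        self.bottom_ = float(bottom)
        self.top_ = float(min(bottom + span, self.max_top))
        self.hill_ = float(hill)
        self.residuals_ = resid(best.x)
        self.converged_ = bool(best.success and span >= self.min_span)
        self.ic50_ = float(10.0 ** logc) if self.converged_ else float("nan")
        if not self.converged_:
            logger.warning("4PL fit non-convergent (span %.3g); IC50 undefined", span)
        return self

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        ic50 = self.ic50_ if np.isfinite(self.ic50_) else 10.0 ** 0
        return _4pl(x, self.bottom_, self.top_, ic50, self.hill_)


def fit_4pl(dr: DoseResponse) -> tuple[dict, np.ndarray]:
    """Fit a 4PL to the mean responses of a DoseResponse; returns the fitted
    parameter dict (also stored on ``dr.fitted``) and per-point residuals."""
    est = FourParamLogistic().fit(dr.concentrations, dr.mean_response())
    params = {
        "bottom": est.bottom_,
        "top": est.top_,
        "ic50": est.ic50_,
        "hill": est.hill_,
        "converged": est.converged_,
    }
    dr.fitted = params
    return params, est.residuals_


def bliss_delta(fa_a, fa_b, fa_ab):
    """delta = fa_ab - (fa_a + fa_b - fa_a * fa_b); positive = synergy."""
    fa_a = np.asarray(fa_a, dtype=float)
    fa_b = np.asarray(fa_b, dtype=float)
    fa_ab = np.asarray(fa_ab, dtype=float)
    for name, v in (("fa_a", fa_a), ("fa_b", fa_b), ("fa_ab", fa_ab)):
        if np.any((v < 0) | (v > 1)):
            raise ValueError(f"{name} must lie in [0, 1]")
    expected = fa_a + fa_b - fa_a * fa_b
    out = fa_ab - expected
    return float(out) if out.ndim == 0 else out


def synergy_grid(single_a: DoseResponse, single_b: DoseResponse,
                 combo: dict[tuple[float, float], np.ndarray]) -> SynergyGrid:
    """Build the delta-Bliss matrix for a combination experiment.

    ``combo`` maps (conc_a, conc_b) to replicate *fraction-affected* values;
    marginal fa comes from the mean single-agent responses at each
    concentration.  Every combo concentration must be present in the
    corresponding single-agent dose series.
    """
    fa_a = dict(zip(single_a.concentrations, single_a.fraction_affected()))
    fa_b = dict(zip(single_b.concentrations, single_b.fraction_affected()))
    conc_a = sorted({ca for ca, _ in combo})
    conc_b = sorted({cb for _, cb in combo})
    for ca, cb in combo:
        if ca not in fa_a:
            raise ValueError(f"combo cell ({ca}, {cb}): concentration {ca} missing from {single_a.drug} marginals")
        if cb not in fa_b:
            raise ValueError(f"combo cell ({ca}, {cb}): concentration {cb} missing from {single_b.drug} marginals")

    obs = np.full((len(conc_a), len(conc_b)), np.nan)
    exp = np.full_like(obs, np.nan)
    for (ca, cb), reps in combo.items():
        reps = np.asarray(reps, dtype=float)
        if reps.size < 2:
            raise ValueError(f"combo cell ({ca}, {cb}): need at least 2 replicates")
        i, j = conc_a.index(ca), conc_b.index(cb)
        obs[i, j] = np.clip(reps.mean(), 0.0, 1.0)
        exp[i, j] = fa_a[ca] + fa_b[cb] - fa_a[ca] * fa_b[cb]

    idx_a = pd.Index(conc_a, name=f"{single_a.drug} (uM)")
    idx_b = pd.Index(conc_b, name=f"{single_b.drug} (uM)")
    return SynergyGrid(
        drug_a=single_a.drug,
        drug_b=single_b.drug,
        conc_a=np.asarray(conc_a),
        conc_b=np.asarray(conc_b),
        fa_obs=pd.DataFrame(obs, index=idx_a, columns=idx_b),
        fa_expected=pd.DataFrame(exp, index=idx_a, columns=idx_b),
        delta_bliss=pd.DataFrame(obs - exp, index=idx_a, columns=idx_b),
    )


def read_single_agent_csv(path, drug: Optional[str] = None) -> DoseResponse:
    """Read a long-format single-agent table (columns drug, conc_um,
    replicate, raw_signal).  Rows with conc_um == 0 are the vehicle wells
    used for normalization."""
    df = pd.read_csv(path)
    if drug is not None:
        df = df[df["drug"] == drug]
    if df.empty:
        raise ValueError(f"{path}: no rows{' for drug ' + drug if drug else ''}")
    drug_name = str(df["drug"].iloc[0])
    vehicle = df[df["conc_um"] == 0]["raw_signal"].to_numpy()
    if vehicle.size == 0:
        raise ValueError(f"{path}: no vehicle (conc_um == 0) wells")
    dosed = df[df["conc_um"] > 0]
    wide = dosed.pivot_table(index="conc_um", columns="replicate", values="raw_signal")
    response = normalize_to_vehicle(wide.to_numpy(), vehicle)
    return DoseResponse(drug=drug_name, concentrations=wide.index.to_numpy(), response=response)


def read_combo_csv(path) -> dict[tuple[float, float], np.ndarray]:
    """Read a long-format combination table (columns conc_a_um, conc_b_um,
    replicate, raw_signal); rows with both concentrations zero are the
    vehicle wells.  Returns fraction-affected replicate arrays per cell."""
    df = pd.read_csv(path)
    vehicle = df[(df["conc_a_um"] == 0) & (df["conc_b_um"] == 0)]["raw_signal"].to_numpy()
    if vehicle.size == 0:
        raise ValueError(f"{path}: no vehicle (0, 0) wells")
    out: dict[tuple[float, float], np.ndarray] = {}
    dosed = df[(df["conc_a_um"] > 0) & (df["conc_b_um"] > 0)]
    for (ca, cb), group in dosed.groupby(["conc_a_um", "conc_b_um"]):
        viability = normalize_to_vehicle(group["raw_signal"].to_numpy(), vehicle)
        out[(float(ca), float(cb))] = fraction_affected(viability)
    return out
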