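"""Competitive chemical-proteomics interactor scoring.

In a competition pulldown experiment, a drug analog immobilized on beads
(here, clickable olaparib or rucaparib) enriches its targets and their
complex partners from lysate ("pulldown", PD).  Pre-incubating the lysate
with free drug scavenges true targets, so they drop out of a parallel
pulldown ("competition control", CT).  A *specific* interactor is therefore
a protein enriched in PD over CT:

    specific  <=>  log2(PD/CT) > fc_cutoff  and  Student p < p_cutoff

with the conventional cutoff of 1.5 on the *log2* ratio (about 2.8-fold on
the raw scale).

To compare interactomes between two cell lines, each pulldown sample is
first normalized to relative iBAQ (riBAQ = iBAQ / sum iBAQ, a within-sample
fractional abundance); a protein is called line-enriched when the ratio of
mean riBAQ between the lines exceeds 1.5 (raw scale, per figure-legend
convention) with Student p < 0.1 across replicates.  The joint interactor
call used for reporting applies both gates, which is how the original
analysis selects complex partners that differ between lines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .stats import impute_column_min, log2_transform, two_sample_t_matrix

__all__ = [
    "PulldownSet",
    "compute_ribaq",
    "CompetitionScorer",
    "CrossLineScorer",
    "score_competition",
    "cross_line_differential",
    "call_interactors",
    "merge_probes",
]


@dataclass
class PulldownSet:
    """Pulldown (PD) and competition-control (CT) replicate intensity
    matrices for one probe in one cell line, on the iBAQ scale."""

    probe: str
    cell_line: str
    pd_intensities: pd.DataFrame
    ct_intensities: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.pd_intensities.index.equals(self.ct_intensities.index):
            raise ValueError("PD and CT matrices must share the same feature index")
        if self.pd_intensities.shape[1] < 2 or self.ct_intensities.shape[1] < 2:
            raise ValueError("need at least 2 replicates in PD and CT")


def compute_ribaq(sample_intensities) -> np.ndarray:
    """Relative iBAQ: each entry divided by the sample total.

    Missing entries (NaN) are excluded from the total and stay missing.
    The present entries of the result sum to 1.
    """
    vals = np.asarray(sample_intensities, dtype=float)
    total = np.nansum(vals)
    if not total > 0:
        raise ValueError("cannot compute riBAQ: no positive intensities in sample")
    return vals / total


class CompetitionScorer(BaseEstimator):
    """Score pulldown-vs-competition specificity for one probe.

    Pipeline: column-minimum imputation -> log2 transform -> per-feature
    mean log2(PD) - mean log2(CT) with a Student t test across replicates.

    Parameters
    ----------
    fc_cutoff : float
        Cutoff on the log2 PD/CT ratio (default 1.5).
    p_cutoff : float
        Two-sided p-value cutoff (default 0.05).
    t_variant : {"student", "welch"}

    Attributes
    ----------
    results_ : DataFrame with columns log2fc_pd_ct, p_pd_ct, specific,
        mean_pd, mean_ct (log2 scale), indexed by feature_id.
    """

    def __init__(self, fc_cutoff: float = 1.5, p_cutoff: float = 0.05, t_variant: str = "student"):
        self.fc_cutoff = fc_cutoff
        self.p_cutoff = p_cutoff
        self.t_variant = t_variant

    def fit(self, pulldown_set: PulldownSet) -> "CompetitionScorer":
        pd_log = log2_transform(impute_column_min(pulldown_set.pd_intensities))
        ct_log = log2_transform(impute_column_min(pulldown_set.ct_intensities))
        t, p = two_sample_t_matrix(pd_log.to_numpy(), ct_log.to_numpy(), variant=self.t_variant)
        mean_pd = pd_log.mean(axis=1)
        mean_ct = ct_log.mean(axis=1)
        log2fc = mean_pd - mean_ct
        self.results_ = pd.DataFrame(
            {
                "probe": pulldown_set.probe,
                "log2fc_pd_ct": log2fc,
                "p_pd_ct": p,
                "specific": (log2fc > self.fc_cutoff) & (p < self.p_cutoff),
                "mean_pd": mean_pd,
                "mean_ct": mean_ct,
            },
            index=pd_log.index,
        )
        return self


class CrossLineScorer(BaseEstimator):
    """Call interactors differentially captured between two cell lines.

    riBAQ is computed per pulldown replicate; features absent in one line
    are imputed with the minimum present riBAQ of that replicate before the
    ratio (the usual left-censoring convention).  The enrichment gate is on
    the *raw* ratio of mean riBAQ (A/B), with a Student t test on the
    replicate riBAQ values (on the raw scale by default; set
    ``on_log2=True`` to test log2 riBAQ).

    Attributes
    ----------
    results_ : DataFrame with ribaq_a, ribaq_b, ribaq_ratio, p_lines,
        line_enriched in {"A", "B", "none"}.
    """

    def __init__(self, ratio_cutoff: float = 1.5, p_cutoff: float = 0.1,
                 t_variant: str = "student", on_log2: bool = False):
        self.ratio_cutoff = ratio_cutoff
        self.p_cutoff = p_cutoff
        self.t_variant = t_variant
        self.on_log2 = on_log2

    @staticmethod
    def _ribaq_matrix(pd_intensities: pd.DataFrame, index: pd.Index) -> pd.DataFrame:
        aligned = pd_intensities.reindex(index)
        out = {}
        for col in aligned.columns:
            rib = compute_ribaq(aligned[col].to_numpy())
            rib = np.where(np.isnan(rib), np.nanmin(rib), rib)
            out[col] = rib
        return pd.DataFrame(out, index=index)

    def fit(self, line_a: PulldownSet, line_b: PulldownSet) -> "CrossLineScorer":
        if line_a.probe != line_b.probe:
            raise ValueError(f"probe mismatch: {line_a.probe!r} vs {line_b.probe!r}")
        index = line_a.pd_intensities.index.union(line_b.pd_intensities.index)
        rib_a = self._ribaq_matrix(line_a.pd_intensities, index)
        rib_b = self._ribaq_matrix(line_b.pd_intensities, index)
        mean_a = rib_a.mean(axis=1)
        mean_b = rib_b.mean(axis=1)
        ratio = mean_a / mean_b
        if self.on_log2:
            _, p = two_sample_t_matrix(np.log2(rib_a.to_numpy()), np.log2(rib_b.to_numpy()),
                                       variant=self.t_variant)
        else:
            _, p = two_sample_t_matrix(rib_a.to_numpy(), rib_b.to_numpy(), variant=self.t_variant)
        enriched = np.where(
            (ratio > self.ratio_cutoff) & (p < self.p_cutoff), "A",
            np.where((ratio < 1 / self.ratio_cutoff) & (p < self.p_cutoff), "B", "none"),
        )
        self.results_ = pd.DataFrame(
            {
                "probe": line_a.probe,
                "ribaq_a": mean_a,
                "ribaq_b": mean_b,
                "ribaq_ratio": ratio,
                "p_lines": p,
                "line_enriched": enriched,
            },
            index=index,
        )
        return self


def score_competition(pd_set: PulldownSet, fc_cutoff: float = 1.5, p_cutoff: float = 0.05,
                      t_variant: str = "student") -> pd.DataFrame:
    """Functional wrapper over :class:`CompetitionScorer`."""
    return CompetitionScorer(fc_cutoff, p_cutoff, t_variant).fit(pd_set).results_


def cross_line_differential(line_a: PulldownSet, line_b: PulldownSet, ratio_cutoff: float = 1.5,
                            p_cutoff: float = 0.1, t_variant: str = "student",
                            on_log2: bool = False) -> pd.DataFrame:
    """Functional wrapper over :class:`CrossLineScorer`."""
    return CrossLineScorer(ratio_cutoff, p_cutoff, t_variant, on_log2).fit(line_a, line_b).results_


def call_interactors(
    line_a: PulldownSet,
    line_b: PulldownSet,
    fc_cutoff: float = 1.5,
    p_cutoff: float = 0.05,
    ratio_cutoff: float = 1.5,
    p_lines_cutoff: float = 0.1,
) -> pd.DataFrame:
    """Joint interactor table combining both gates, per the reporting
    convention: a feature is ``selected`` for a line when it is a specific
    interactor (PD/CT gate) in that line *and* line-enriched there
    (riBAQ-ratio gate)."""
    spec_a = score_competition(line_a, fc_cutoff, p_cutoff)
    spec_b = score_competition(line_b, fc_cutoff, p_cutoff)
    cross = cross_line_differential(line_a, line_b, ratio_cutoff, p_lines_cutoff)
    out = cross.copy()
    out["specific_a"] = spec_a["specific"].reindex(out.index, fill_value=False)
    out["specific_b"] = spec_b["specific"].reindex(out.index, fill_value=False)
    out["log2fc_pd_ct_a"] = spec_a["log2fc_pd_ct"].reindex(out.index)
    out["log2fc_pd_ct_b"] = spec_b["log2fc_pd_ct"].reindex(out.index)
    out["selected"] = np.where(
        (out["line_enriched"] == "A") & out["specific_a"], "A",
        np.where((out["line_enriched"] == "B") & out["specific_b"], "B", "none"),
    )
    return out


def merge_probes(calls_probe1: pd.DataFrame, calls_probe2: pd.DataFrame,
                 names: tuple[str, str] = ("probe1", "probe2")) -> pd.DataFrame:
    """Outer-join two per-probe call tables on feature_id, labeling each
    feature by provenance: probe1 only / probe2 only / both.  No calls are
    altered."""
    merged = calls_probe1.add_suffix(f"_{names[0]}").join(
        calls_probe2.add_suffix(f"_{names[1]}"), how="outer"
    )
    in1 = merged.index.isin(calls_probe1.index)
    in2 = merged.index.isin(calls_probe2.index)
    merged["probes"] = np.where(in1 & in2, "both", np.where(in1, f"{names[0]} only", f"{names[1]} only"))
    return merged
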