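"""Seeded synthetic-data generators with planted ground truth.

Each generator emulates one input the pipeline consumes, at the study's
stated conditions (three biological replicates for pulldowns and label-free
runs, TMT six-plex with three treated/vehicle pairs, four viability
replicates), with log-normal intensity noise and abundance-dependent
(left-censored) missingness — the dominant missingness mechanism of
label-free MS, and the regime the column-minimum imputation is designed
for.  Planted features are drawn from the detectable (upper-half) abundance
range so that recovery rates measure the scoring method rather than the
detection floor.

All generators are pure functions of their arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd

from .chemprot import PulldownSet
from .pharm import DoseResponse, _4pl
from .ptm import AdprExperiment, TmtPhosphoExperiment
from .tables import QuantTable, SampleDesign

__all__ = [
    "GroundTruth",
    "gen_chemprot",
    "gen_phospho_tmt",
    "gen_adpr",
    "gen_viability",
]


@dataclass
class GroundTruth:
    """Planted truth emitted alongside each synthetic dataset."""

    planted_specific_binders: list[str] = field(default_factory=list)
    planted_line_enriched: dict[str, str] = field(default_factory=dict)
    planted_regulated_sites: dict[str, float] = field(default_factory=dict)
    planted_ppm_outliers: list[str] = field(default_factory=list)
    planted_adpr_hits: dict[str, float] = field(default_factory=dict)
    planted_ic50s: dict[str, float] = field(default_factory=dict)
    planted_bliss_offset: float = 0.0
    offset_cells: list[tuple[float, float]] = field(default_factory=list)

    def to_json(self, path) -> None:
        data = {k: v for k, v in self.__dict__.items()}
        data["offset_cells"] = [list(c) for c in self.offset_cells]
        Path(path).write_text(json.dumps(data, indent=2) + "\n")


def _feature_ids(n: int, prefix: str = "P") -> list[str]:
    return [f"{prefix}{i:05d}" for i in range(1, n + 1)]


def _censor(rng: np.random.Generator, log2_values: np.ndarray, rate: float) -> np.ndarray:
    """Abundance-dependent missingness: per column, a smooth logistic of
    log2 intensity centered at the column's `rate` quantile, so the overall
    missing fraction is about `rate` and concentrated at low abundance."""
    out = log2_values.copy()
    if rate <= 0:
        return out
    for j in range(out.shape[1]):
        col = out[:, j]
        c = np.quantile(col, rate)
        p_miss = 1.0 / (1.0 + np.exp((col - c) / 0.5))
        miss = rng.random(len(col)) < p_miss
        if miss.all():  # never censor an entire column
            miss[np.argmax(col)] = False
        out[miss, j] = np.nan
    return out


def _pow2(log2_values: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        return 2.0 ** log2_values


def gen_chemprot(
    n_features: int = 2000,
    n_specific: int = 20,
    n_line_diff: int = 10,
    log2_effect: float = 3.0,
    line_ratio: float = 4.0,
    noise_sd_log2: float = 0.25,
    n_reps: int = 3,
    missing_rate: float = 0.05,
    seed: int = 0,
) -> tuple[dict[str, PulldownSet], GroundTruth]:
    """Competitive chemical-proteomics inputs for two cell lines (A, B).

    Baseline log2 iBAQs are N(20, 3); planted features sit in the upper
    half of that range.  Specific binders have their competition-control
    (CT) intensity attenuated by ``2**log2_effect`` in both lines.
    Line-enriched features are *additional* specific binders whose pulldown
    abundance is scaled by ``line_ratio`` in their enriched line (half in A,
    half in B), mirroring complex partners that are captured by the probe
    in one line only.
    """
    if n_specific + n_line_diff > n_features:
        raise ValueError("n_specific + n_line_diff must not exceed n_features")
    rng = np.random.default_rng(seed)
    ids = _feature_ids(n_features)
    base = rng.normal(20.0, 3.0, n_features)
    planted_idx = rng.choice(n_features, n_specific + n_line_diff, replace=False)
    base[planted_idx] = 20.0 + np.abs(rng.normal(0.0, 2.0, len(planted_idx)))
    spec_idx = planted_idx[:n_specific]
    line_idx = planted_idx[n_specific:]
    line_of = {}
    for pos, i in enumerate(line_idx):
        line_of[ids[i]] = "A" if pos % 2 == 0 else "B"

    attenuated = np.zeros(n_features, dtype=bool)
    attenuated[planted_idx] = True  # line-enriched partners are also competed away

    sets = {}
    for line in ("A", "B"):
        shift = np.zeros(n_features)
        for fid, ln in line_of.items():
            if ln == line:
                shift[ids.index(fid)] = np.log2(line_ratio)
        pd_log = (base + shift)[:, None] + rng.normal(0.0, noise_sd_log2, (n_features, n_reps))
        ct_log = (base + shift - np.where(attenuated, log2_effect, 0.0))[:, None] + rng.normal(
            0.0, noise_sd_log2, (n_features, n_reps)
        )
        pd_log = _censor(rng, pd_log, missing_rate)
        ct_log = _censor(rng, ct_log, missing_rate)
        index = pd.Index(ids, name="feature_id")
        sets[line] = PulldownSet(
            probe="c-olaparib",
            cell_line=line,
            pd_intensities=pd.DataFrame(
                _pow2(pd_log), index=index, columns=[f"PD_{line}_{r + 1}" for r in range(n_reps)]
            ),
            ct_intensities=pd.DataFrame(
                _pow2(ct_log), index=index, columns=[f"CT_{line}_{r + 1}" for r in range(n_reps)]
            ),
        )

    truth = GroundTruth(
        planted_specific_binders=sorted(ids[i] for i in planted_idx),
        planted_line_enriched=line_of,
    )
    return sets, truth


def gen_phospho_tmt(
    n_sites: int = 5000,
    n_up: int = 50,
    n_down: int = 50,
    log2_effect: float = 1.5,
    noise_sd: float = 0.25,
    n_rep_pairs: int = 3,
    channel_bias_sd: float = 0.25,
    ppm_outlier_rate: float = 0.02,
    cell_line: str = "UWB",
    seed: int = 0,
) -> tuple[TmtPhosphoExperiment, GroundTruth]:
    """TMT six-plex phosphoproteomics experiment with planted regulation.

    ``noise_sd`` is the SD of the replicate-wise log2 ratios of null sites
    (per-channel noise is ``noise_sd / sqrt(2)``).  Channels carry global
    log-normal loading biases (removed by IRON normalization).  Mass errors
    are uniform on +-2 ppm, with a fraction of *null* sites planted beyond
    +-3 ppm to exercise the mass-error gate.
    """
    if n_up + n_down > n_sites:
        raise ValueError("n_up + n_down must not exceed n_sites")
    rng = np.random.default_rng(seed)
    ids = _feature_ids(n_sites, prefix="SITE")
    base = rng.normal(16.0, 2.0, n_sites)
    reg_idx = rng.choice(n_sites, n_up + n_down, replace=False)
    base[reg_idx] = 16.0 + np.abs(rng.normal(0.0, 1.5, len(reg_idx)))
    effect = np.zeros(n_sites)
    effect[reg_idx[:n_up]] = log2_effect
    effect[reg_idx[n_up:]] = -log2_effect

    ch_noise = noise_sd / np.sqrt(2.0)
    bias = rng.normal(0.0, channel_bias_sd, 2 * n_rep_pairs)
    treated = np.empty((n_sites, n_rep_pairs))
    vehicle = np.empty((n_sites, n_rep_pairs))
    for r in range(n_rep_pairs):
        treated[:, r] = base + effect + bias[r] + rng.normal(0.0, ch_noise, n_sites)
        vehicle[:, r] = base + bias[n_rep_pairs + r] + rng.normal(0.0, ch_noise, n_sites)

    mass_err = rng.uniform(-2.0, 2.0, n_sites)
    null_idx = np.setdiff1d(np.arange(n_sites), reg_idx)
    n_out = int(round(ppm_outlier_rate * n_sites))
    out_idx = rng.choice(null_idx, n_out, replace=False)
    mass_err[out_idx] = rng.uniform(3.5, 8.0, n_out) * rng.choice([-1.0, 1.0], n_out)

    treated_cols = [f"treated_{r + 1}" for r in range(n_rep_pairs)]
    vehicle_cols = [f"vehicle_{r + 1}" for r in range(n_rep_pairs)]
    index = pd.Index(ids, name="feature_id")
    intens = pd.DataFrame(
        np.hstack([_pow2(treated), _pow2(vehicle)]), index=index, columns=treated_cols + vehicle_cols
    )
    feats = pd.DataFrame(
        {
            "gene_symbol": [f"GENE{i + 1}" for i in range(n_sites)],
            "pep": rng.uniform(0.0, 0.04, n_sites),
            "mass_error_ppm": mass_err,
            "localization_prob": rng.uniform(0.75, 1.0, n_sites),
            "reverse": False,
            "contaminant": False,
        },
        index=index,
    )
    channels = ["126", "127", "128", "129", "130", "131"]
    design = SampleDesign(
        pd.DataFrame(
            {
                "sample_id": treated_cols + vehicle_cols,
                "cell_line": cell_line,
                "treatment": ["rucaparib"] * n_rep_pairs + ["DMSO"] * n_rep_pairs,
                "role": ["treated"] * n_rep_pairs + ["vehicle"] * n_rep_pairs,
                "replicate": list(range(1, n_rep_pairs + 1)) * 2,
                "channel": channels[: 2 * n_rep_pairs],
            }
        )
    )
    truth = GroundTruth(
        planted_regulated_sites={ids[i]: float(effect[i]) for i in reg_idx},
        planted_ppm_outliers=sorted(ids[i] for i in out_idx),
    )
    return TmtPhosphoExperiment(quant=QuantTable(intens, feats), design=design), truth


def gen_adpr(
    n_proteins: int = 3000,
    n_hits: int = 60,
    raw_fc: float = 4.0,
    noise_sd: float = 0.3,
    n_reps: int = 3,
    direction: str = "down",
    missing_rate: float = 0.05,
    cell_line: str = "UWB",
    seed: int = 0,
) -> tuple[AdprExperiment, GroundTruth]:
    """Label-free ADP-ribosylome experiment (drug vs DMSO) with planted
    hits at ``raw_fc``-fold (decreased modification under drug by
    default)."""
    if n_hits > n_proteins:
        raise ValueError("n_hits must not exceed n_proteins")
    if direction not in {"down", "up"}:
        raise ValueError("direction must be 'down' or 'up'")
    rng = np.random.default_rng(seed)
    ids = _feature_ids(n_proteins)
    base = rng.normal(20.0, 3.0, n_proteins)
    hit_idx = rng.choice(n_proteins, n_hits, replace=False)
    base[hit_idx] = 20.0 + np.abs(rng.normal(0.0, 2.0, n_hits))
    sign = -1.0 if direction == "down" else 1.0
    effect = np.zeros(n_proteins)
    effect[hit_idx] = sign * np.log2(raw_fc)

    treated = (base + effect)[:, None] + rng.normal(0.0, noise_sd, (n_proteins, n_reps))
    vehicle = base[:, None] + rng.normal(0.0, noise_sd, (n_proteins, n_reps))
    treated = _censor(rng, treated, missing_rate)
    vehicle = _censor(rng, vehicle, missing_rate)

    treated_cols = [f"ruca_{r + 1}" for r in range(n_reps)]
    vehicle_cols = [f"dmso_{r + 1}" for r in range(n_reps)]
    index = pd.Index(ids, name="feature_id")
    intens = pd.DataFrame(
        np.hstack([_pow2(treated), _pow2(vehicle)]), index=index, columns=treated_cols + vehicle_cols
    )
    feats = pd.DataFrame(
        {
            "gene_symbol": [f"GENE{i + 1}" for i in range(n_proteins)],
            "pep": rng.uniform(0.0, 0.04, n_proteins),
            "reverse": False,
            "contaminant": False,
        },
        index=index,
    )
    design = SampleDesign(
        pd.DataFrame(
            {
                "sample_id": treated_cols + vehicle_cols,
                "cell_line": cell_line,
                "treatment": ["rucaparib"] * n_reps + ["DMSO"] * n_reps,
                "role": ["treated"] * n_reps + ["vehicle"] * n_reps,
                "replicate": list(range(1, n_reps + 1)) * 2,
            }
        )
    )
    truth = GroundTruth(planted_adpr_hits={ids[i]: float(sign * raw_fc) for i in hit_idx})
    return AdprExperiment(quant=QuantTable(intens, feats), design=design), truth


def gen_viability(
    ic50_a: float = 0.4,
    ic50_b: float = 2.0,
    hill_a: float = 1.0,
    hill_b: float = 1.0,
    bliss_offset: float = 0.0,
    noise_sd: float = 0.05,
    concentrations=(0.016, 0.08, 0.4, 2.0, 10.0),
    n_reps: int = 4,
    seed: int = 0,
) -> tuple[DoseResponse, DoseResponse, dict[tuple[float, float], np.ndarray], GroundTruth]:
    """Viability grids with known IC50s and a planted Bliss offset.

    Single-agent viability follows a 4PL (bottom 0, top 1) plus Gaussian
    noise.  Combination fraction-affected equals the Bliss-independent
    expectation of the *noiseless* marginals, plus ``bliss_offset`` on every
    cell with headroom (expected fa + offset <= 1; at saturated corners a
    clipped offset is unidentifiable), plus noise.  The offset cells are
    recorded in the ground truth.
    """
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= 0) or np.any(np.diff(conc) <= 0):
        raise ValueError("concentrations must be positive and increasing")
    rng = np.random.default_rng(seed)

    def viability(c, ic50, hill):
        return _4pl(c, 0.0, 1.0, ic50, hill)

    singles = {}
    for drug, ic50, hill in (("rucaparib", ic50_a, hill_a), ("AZD5363", ic50_b, hill_b)):
        v = viability(conc, ic50, hill)[:, None] + rng.normal(0.0, noise_sd, (len(conc), n_reps))
        singles[drug] = DoseResponse(drug=drug, concentrations=conc, response=np.clip(v, 0.0, 1.2))

    fa_a = 1.0 - viability(conc, ic50_a, hill_a)
    fa_b = 1.0 - viability(conc, ic50_b, hill_b)
    combo: dict[tuple[float, float], np.ndarray] = {}
    offset_cells = []
    any_room = False
    for i, ca in enumerate(conc):
        for j, cb in enumerate(conc):
            expected = fa_a[i] + fa_b[j] - fa_a[i] * fa_b[j]
            fa = expected
            if bliss_offset and expected + bliss_offset <= 1.0:
                fa = expected + bliss_offset
                offset_cells.append((float(ca), float(cb)))
            if expected + abs(bliss_offset) <= 1.0:
                any_room = True
            combo[(float(ca), float(cb))] = np.clip(fa + rng.normal(0.0, noise_sd, n_reps), 0.0, 1.0)
    if bliss_offset and not any_room:
        raise ValueError("bliss_offset pushes fraction affected outside [0, 1] on every cell")

    truth = GroundTruth(
        planted_ic50s={"rucaparib": float(ic50_a), "AZD5363": float(ic50_b)},
        planted_bliss_offset=float(bliss_offset),
        offset_cells=offset_cells,
    )
    return singles["rucaparib"], singles["AZD5363"], combo, truth
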