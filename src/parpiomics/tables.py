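"""Readers and quality-control filters for MaxQuant-style quantification tables.

The pipeline consumes two kinds of tab-separated tables produced by common
search engines: protein-group tables carrying iBAQ columns, and PTM-site
tables carrying reporter-ion intensity columns.  Sample annotation comes from
a separate CSV design table mapping intensity columns to cell line,
treatment, role (pulldown / competition / treated / vehicle) and replicate.

Quality control follows the standard label-free conventions: features marked
as reverse-database hits or common contaminants are dropped, peptide-level
identifications with posterior error probability (PEP) >= 0.05 are dropped,
and features without any positive intensity are dropped.  Zero intensities
are preserved on parse and treated as missing downstream (column-minimum
imputation happens in :mod:`parpiomics.stats`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "QuantTable",
    "SampleDesign",
    "FilterReport",
    "parse_quant_table",
    "write_quant_table",
    "qc_filter",
    "read_sample_design",
    "DIALECTS",
]

ROLES = {"pulldown", "competition", "treated", "vehicle"}

#: Per-dialect defaults: candidate feature-ID columns and intensity-column prefix.
DIALECTS = {
    "protein_groups": {
        "id_columns": ["Majority protein IDs", "Protein IDs"],
        "intensity_prefix": "iBAQ ",
    },
    "phospho_sites": {
        "id_columns": ["Unique identifier", "id"],
        "intensity_prefix": "Reporter intensity corrected ",
    },
    "generic": {
        "id_columns": ["Feature ID"],
        "intensity_prefix": "Intensity ",
    },
}

_META_COLUMNS = {
    "gene_symbol": "Gene names",
    "pep": "PEP",
    "mass_error_ppm": "Mass error [ppm]",
    "localization_prob": "Localization prob",
}


@dataclass
class QuantTable:
    """A features x samples intensity matrix with per-feature metadata.

    ``intensities`` is a DataFrame indexed by feature_id with one column per
    sample; NaN marks a missing measurement, zeros are preserved as parsed.
    ``features`` is a DataFrame (same index) holding gene_symbol, pep,
    reverse, contaminant, mass_error_ppm, localization_prob where available.
    """

    intensities: pd.DataFrame
    features: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.intensities.index.equals(self.features.index):
            raise ValueError("intensities and features must share the same feature index")
        if self.intensities.index.has_duplicates:
            dups = self.intensities.index[self.intensities.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature IDs: {dups}")
        with np.errstate(invalid="ignore"):
            if (self.intensities.to_numpy(dtype=float) < 0).any():
                raise ValueError("intensities must be non-negative")

    @property
    def feature_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_features(self) -> int:
        return len(self.intensities)

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    def intensity_matrix(self, zero_as_missing: bool = True) -> pd.DataFrame:
        """Return the intensity matrix, with zeros mapped to NaN by default."""
        mat = self.intensities.astype(float)
        if zero_as_missing:
            mat = mat.mask(mat == 0)
        return mat

    def column(self, name: str, default=None) -> Optional[pd.Series]:
        if name in self.features.columns:
            return self.features[name]
        return default

    def subset(self, index: pd.Index) -> "QuantTable":
        return QuantTable(self.intensities.loc[index], self.features.loc[index])


@dataclass
class SampleDesign:
    """Mapping from sample column to experimental annotation.

    Columns: sample_id, cell_line, treatment, role, replicate and optionally
    channel (TMT label).  (cell_line, treatment, role, replicate) tuples are
    unique and every sample_id must match one intensity column.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["sample_id", "cell_line", "treatment", "role", "replicate"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"sample design is missing columns: {missing}")
        bad_roles = set(self.table["role"]) - ROLES
        if bad_roles:
            raise ValueError(f"unknown roles in design: {sorted(bad_roles)}; expected one of {sorted(ROLES)}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("sample_id values must be unique")
        key = self.table[["cell_line", "treatment", "role", "replicate"]]
        if key.duplicated().any():
            raise ValueError("(cell_line, treatment, role, replicate) tuples must be unique")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def select(self, **conditions) -> pd.DataFrame:
        """Rows matching all given column == value conditions, ordered by replicate."""
        sub = self.table
        for col, val in conditions.items():
            sub = sub[sub[col] == val]
        return sub.sort_values("replicate")

    def validate_against(self, table: QuantTable) -> None:
        extra = set(self.sample_ids) - set(table.sample_ids)
        if extra:
            raise ValueError(f"design samples not found in quant table: {sorted(extra)}")
        missing = set(table.sample_ids) - set(self.sample_ids)
        if missing:
            raise ValueError(f"quant table columns not described by design: {sorted(missing)}")


@dataclass
class FilterReport:
    """Bookkeeping for qc_filter; each removed feature is counted once,
    at the first rule it violates (reverse -> contaminant -> PEP -> zero)."""

    n_input: int = 0
    n_removed_reverse: int = 0
    n_removed_contaminant: int = 0
    n_removed_pep: int = 0
    n_removed_zero_intensity: int = 0
    n_output: int = 0

    def balances(self) -> bool:
        removed = (
            self.n_removed_reverse
            + self.n_removed_contaminant
            + self.n_removed_pep
            + self.n_removed_zero_intensity
        )
        return self.n_input == self.n_output + removed

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def _find_id_column(columns, candidates, dialect):
    for cand in candidates:
        if cand in columns:
            return cand
    raise ValueError(
        f"missing header: no feature-ID column for dialect {dialect!r}; "
        f"expected one of {candidates}, first absent: {candidates[0]!r}"
    )


def parse_quant_table(
    path,
    dialect: str = "generic",
    intensity_prefix: Optional[str] = None,
    id_column: Optional[str] = None,
) -> QuantTable:
    """Read a MaxQuant-dialect tab-separated quantification table.

    Parameters
    ----------
    path : str or Path
        Tab-separated file with a header row.
    dialect : {"protein_groups", "phospho_sites", "generic"}
        Chooses the default feature-ID column and intensity-column prefix
        (``iBAQ `` for protein groups, ``Reporter intensity corrected `` for
        phospho sites, ``Intensity `` otherwise).
    intensity_prefix, id_column : str, optional
        Overrides for non-standard exports.

    '+' marks in the ``Reverse`` / ``Potential contaminant`` columns map to
    boolean flags; absent optional columns yield absent metadata fields.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(DIALECTS)}")
    conf = DIALECTS[dialect]
    prefix = intensity_prefix if intensity_prefix is not None else conf["intensity_prefix"]

    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.empty and raw.columns.empty:
        raise ValueError(f"{path}: empty file or missing header row")

    id_col = id_column or _find_id_column(raw.columns, conf["id_columns"], dialect)
    intensity_cols = [c for c in raw.columns if c.startswith(prefix) and c != prefix.strip()]
    if not intensity_cols:
        raise ValueError(
            f"missing header: no intensity columns with prefix {prefix!r} "
            f"(first absent required column: {prefix!r}...)"
        )

    ids = raw[id_col].astype(str)
    if ids.duplicated().any():
        dups = sorted(ids[ids.duplicated()].unique().tolist())
        raise ValueError(f"duplicate feature IDs: {dups}")

    intens = pd.DataFrame(index=pd.Index(ids, name="feature_id"))
    for col in intensity_cols:
        cells = raw[col].str.strip()
        numeric = pd.to_numeric(cells.replace({"": None, "NaN": None, "NA": None}), errors="coerce")
        bad = numeric.isna() & ~cells.isin(["", "NaN", "NA", "nan"])
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-numeric intensity value {cells.iloc[row]!r} at row {row + 2}, column {col!r}"
            )
        intens[col.removeprefix(prefix)] = numeric.to_numpy()

    feats = pd.DataFrame(index=intens.index)
    for field_name, header in _META_COLUMNS.items():
        if header in raw.columns:
            if field_name == "gene_symbol":
                feats[field_name] = raw[header].to_numpy()
            else:
                feats[field_name] = pd.to_numeric(raw[header].replace("", np.nan), errors="coerce").to_numpy()
    for field_name, header in [("reverse", "Reverse"), ("contaminant", "Potential contaminant")]:
        if header in raw.columns:
            feats[field_name] = (raw[header].str.strip() == "+").to_numpy()
        else:
            feats[field_name] = False

    return QuantTable(intens, feats)


def write_quant_table(table: QuantTable, path) -> None:
    """Write a QuantTable in the generic dialect (round-trips through
    :func:`parse_quant_table` with ``dialect='generic'``)."""
    out = pd.DataFrame({"Feature ID": table.feature_ids})
    if "gene_symbol" in table.features.columns:
        out["Gene names"] = table.features["gene_symbol"].to_numpy()
    for sample in table.sample_ids:
        out[f"Intensity {sample}"] = table.intensities[sample].to_numpy()
    for field_name, header in _META_COLUMNS.items():
        if field_name == "gene_symbol":
            continue
        if field_name in table.features.columns:
            out[header] = table.features[field_name].to_numpy()
    for field_name, header in [("reverse", "Reverse"), ("contaminant", "Potential contaminant")]:
        if field_name in table.features.columns:
            out[header] = np.where(table.features[field_name].to_numpy(), "+", "")
    out.to_csv(path, sep="\t", index=False)


def qc_filter(
    table: QuantTable,
    pep_max: float = 0.05,
    drop_reverse: bool = True,
    drop_contaminant: bool = True,
    drop_all_missing: bool = True,
) -> tuple[QuantTable, FilterReport]:
    """Apply the standard identification-quality filters.

    Keeps features with (PEP absent or PEP < ``pep_max``), not reverse, not
    contaminant, and at least one present positive intensity.  The report
    counts each removed feature once, under the precedence
    reverse -> contaminant -> PEP -> zero-intensity; the surviving set is
    precedence-independent.
    """
    if not (0 < pep_max <= 1):
        raise ValueError("pep_max must be in (0, 1]")
    n = table.n_features
    reverse = table.features["reverse"].to_numpy(dtype=bool) if drop_reverse else np.zeros(n, bool)
    contam = table.features["contaminant"].to_numpy(dtype=bool) if drop_contaminant else np.zeros(n, bool)
    pep = table.column("pep")
    if pep is not None:
        pep_bad = (pep.to_numpy(dtype=float) >= pep_max) & ~np.isnan(pep.to_numpy(dtype=float))
    else:
        pep_bad = np.zeros(n, bool)
    present = table.intensity_matrix(zero_as_missing=True).notna().to_numpy()
    all_missing = ~present.any(axis=1) if drop_all_missing else np.zeros(n, bool)

    removed_reverse = reverse
    removed_contam = contam & ~removed_reverse
    removed_pep = pep_bad & ~reverse & ~contam
    removed_zero = all_missing & ~reverse & ~contam & ~pep_bad
    keep = ~(reverse | contam | pep_bad | all_missing)

    report = FilterReport(
        n_input=n,
        n_removed_reverse=int(removed_reverse.sum()),
        n_removed_contaminant=int(removed_contam.sum()),
        n_removed_pep=int(removed_pep.sum()),
        n_removed_zero_intensity=int(removed_zero.sum()),
        n_output=int(keep.sum()),
    )
    return table.subset(table.feature_ids[keep]), report


def read_sample_design(path) -> SampleDesign:
    """Read the sample design CSV (columns sample_id, cell_line, treatment,
    role, replicate[, channel])."""
    df = pd.read_csv(path, dtype={"sample_id": str, "cell_line": str, "treatment": str, "role": str})
    df["replicate"] = df["replicate"].astype(int)
    return SampleDesign(df)
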