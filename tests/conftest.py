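import numpy as np
import pandas as pd
import pytest

from parpiomics.tables import QuantTable


def make_quant(intensities: dict, **feature_cols) -> QuantTable:
    """Build a small QuantTable from dicts; feature index from the first
    intensity column's keys order."""
    intens = pd.DataFrame(intensities)
    intens.index.name = "feature_id"
    feats = pd.DataFrame(index=intens.index)
    n = len(intens)
    feats["reverse"] = feature_cols.pop("reverse", [False] * n)
    feats["contaminant"] = feature_cols.pop("contaminant", [False] * n)
    for name, values in feature_cols.items():
        feats[name] = values
    return QuantTable(intens, feats)


@pytest.fixture
def toy_tsv(tmp_path):
    """Hand-written 3-row protein-groups table with one reverse and one
    contaminant mark."""
    path = tmp_path / "toy.tsv"
    path.write_text(
        "Majority protein IDs\tGene names\tiBAQ A\tiBAQ B\tReverse\tPotential contaminant\tPEP\n"
        "P09874\tPARP1\t100.5\t200\t\t\t0.001\n"
        "REV_P1\tX\t50\t60\t+\t\t0.002\n"
        "CON_K1\tKRT1\t10\t0\t\t+\t0.003\n"
    )
    return path
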