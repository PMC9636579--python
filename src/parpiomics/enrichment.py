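"""Local gene-set over-representation analysis (ORA) and multi-omic list
integration.

ORA asks whether a query gene list overlaps a curated gene set more than
expected by chance when drawing from a background "universe".  With universe
size N, set size K, query size n and overlap k, the one-sided p-value is the
upper hypergeometric tail P(X >= k), and the enrichment factor is
(k/n)/(K/N).  Terms are reported when overlap >= 3, p < 0.01 and enrichment
factor >= 1.5 (the conventional reporting gates), with Benjamini-Hochberg
q-values across each collection.

The default universe is the set of genes actually quantified in the
experiment, not the whole genome: testing against the detected proteome
avoids enrichment artifacts from detection bias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .stats import bh_adjust

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "ora_test",
    "filter_terms",
    "integrate_omics_lists",
]


@dataclass
class GeneSetCollection:
    """Named gene sets (symbols uppercased, de-duplicated, no empty sets)."""

    name: str
    sets: dict[str, list[str]]
    universe: Optional[set[str]] = None

    def __post_init__(self) -> None:
        clean = {}
        for set_name, genes in self.sets.items():
            seen: dict[str, None] = {}
            for g in genes:
                g = str(g).strip().upper()
                if g:
                    seen.setdefault(g)
            if not seen:
                raise ValueError(f"gene set {set_name!r} is empty")
            clean[set_name] = list(seen)
        self.sets = clean
        if self.universe is not None:
            self.universe = {str(g).strip().upper() for g in self.universe}

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.sets.values():
            out.update(genes)
        return out


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: one set per line, tab-separated as
    ``name<TAB>description<TAB>gene1<TAB>gene2...``.  The description column
    is discarded."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    lines = path.read_text().splitlines()
    if not any(line.strip() for line in lines):
        raise ValueError(f"{path}: empty GMT file")
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}: line {lineno} has fewer than 3 tab-separated fields")
        sets[fields[0]] = [g for g in fields[2:] if g.strip()]
    return GeneSetCollection(name=path.stem, sets=sets)


def _normalize(genes: Iterable[str]) -> list[str]:
    seen: dict[str, None] = {}
    for g in genes:
        g = str(g).strip().upper()
        if g:
            seen.setdefault(g)
    return list(seen)


def ora_test(query: Iterable[str], collection: GeneSetCollection,
             universe: Optional[Iterable[str]] = None) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test of ``query``
    against every set in ``collection``.

    Query genes outside the universe are dropped with a warning; set members
    outside the universe do not count toward the set size.  Returns one row
    per set with overlap k, sizes, enrichment factor, p and BH q.
    """
    if universe is None:
        universe = collection.universe if collection.universe is not None else collection.all_genes()
    uni = set(_normalize(universe))
    query_set = set(_normalize(query))
    outside = query_set - uni
    if outside:
        warnings.warn(f"{len(outside)} query genes outside the universe were dropped")
    query_set &= uni
    if not query_set:
        raise ValueError("query is empty after intersecting with the universe")

    N, n = len(uni), len(query_set)
    rows = []
    for set_name, genes in collection.sets.items():
        members = set(genes) & uni
        K = len(members)
        overlap = sorted(query_set & members)
        k = len(overlap)
        p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        ef = (k / n) / (K / N) if K else 0.0
        rows.append(
            {
                "set_name": set_name,
                "overlap": k,
                "query_size": n,
                "set_size": K,
                "universe_size": N,
                "enrichment_factor": ef,
                "p_value": min(p, 1.0),
                "overlap_genes": overlap,
            }
        )
    out = pd.DataFrame(rows)
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    return out


def filter_terms(results: pd.DataFrame, min_overlap: int = 3, p_cutoff: float = 0.01,
                 min_enrichment: float = 1.5) -> pd.DataFrame:
    """Keep terms with overlap >= min_overlap, p < p_cutoff and enrichment
    factor >= min_enrichment, sorted by p-value."""
    if results.empty:
        return results.copy()
    passes = (
        (results["overlap"] >= min_overlap)
        & (results["p_value"] < p_cutoff)
        & (results["enrichment_factor"] >= min_enrichment)
    )
    out = results[passes].sort_values("p_value", kind="mergesort").reset_index(drop=True)
    out["passes"] = True
    return out


def integrate_omics_lists(phospho_hits: Iterable[str], adpr_hits: Iterable[str]) -> pd.DataFrame:
    """Union of the phosphoproteomics and ADP-ribosylome hit lists with a
    source flag per gene ({phospho, adpr, both}); the union is the query for
    the integrated pathway analysis."""
    phos = set(_normalize(phospho_hits))
    adpr = set(_normalize(adpr_hits))
    genes = sorted(phos | adpr)
    source = ["both" if g in phos and g in adpr else "phospho" if g in phos else "adpr" for g in genes]
    return pd.DataFrame({"gene": genes, "source": source})
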