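# parpiomics

Integrated proteomics analysis of PARP-inhibitor (PARPi) response in
*BRCA1*-isogenic ovarian cancer models. The package implements, as a tested
and reusable pipeline, the four quantitative analyses that together profile
how PARPi-sensitive and PARPi-insensitive cells differ:

1. **Competitive chemical proteomics** (`parpiomics.chemprot`) — scoring of
   drug-bead pulldowns (PD) against free-drug competition controls (CT).
   A protein is a *specific* interactor when
   `log2(PD/CT) > 1.5` and Student *p* < 0.05. Interactomes of two cell
   lines are compared on the riBAQ scale (riBAQ = iBAQ / ΣiBAQ, a
   within-sample relative abundance); a protein is line-enriched when the
   raw riBAQ ratio exceeds 1.5 with *p* < 0.1.
2. **TMT phosphoproteomics** (`parpiomics.ptm`) — six-plex reporter-ion
   quantification, iterative rank-order (rank-invariant-set) normalization,
   and an adaptive significance gate: |log2FC| > 2 × average SD of the
   replicate log2 ratios, *p* < 0.05, precursor mass error within ±3 ppm.
3. **Label-free ADP-ribosylome** (`parpiomics.ptm`) — column-minimum
   imputation, log2 transform, and a fixed twofold gate
   (|log2FC| ≥ 1, *p* < 0.05) for drug-modulated ADP-ribosylation.
4. **Pathway integration and pharmacology** (`parpiomics.enrichment`,
   `parpiomics.pharm`) — local GMT-driven hypergeometric
   over-representation analysis (overlap ≥ 3, *p* < 0.01, enrichment factor
   ≥ 1.5) over the union of phospho and ADPr hits, four-parameter-logistic
   IC50 fitting, and ΔBliss synergy grids
   (`Δ = fa_obs − (fa_A + fa_B − fa_A·fa_B)`, positive = synergy).

`parpiomics.tables` reads MaxQuant-style tab-separated tables (iBAQ /
reporter-intensity columns, Reverse / Potential contaminant / PEP fields)
and applies the standard QC filters; `parpiomics.synth` provides seeded
generators for every input with planted ground truth, so the whole pipeline
runs at desk scale without downloads.

The analysis cores are scikit-learn-style estimators
(`CompetitionScorer`, `CrossLineScorer`, `IronNormalizer`,
`PhosphoDifferential`, `AdprDifferential`, `FourParamLogistic`) with plain
functional wrappers, so they compose with sklearn tooling where useful.

## Worked example

```python
from parpiomics import synth, chemprot, ptm, pharm

# chemical proteomics: two cell lines, planted specific binders
sets, truth = synth.gen_chemprot(seed=1)
calls = chemprot.score_competition(sets["A"])
print(int(calls["specific"].sum()), "specific interactors")   # -> 30 specific interactors

joint = chemprot.call_interactors(sets["A"], sets["B"])
print((joint["selected"] != "none").sum(), "line-differential")  # -> 10 line-differential

# TMT phosphoproteomics
exp, _ = synth.gen_phospho_tmt(seed=1)
est = ptm.PhosphoDifferential().fit(exp)
print(round(est.threshold_.threshold, 3))                     # -> 0.487
print(int(est.results_["passes"].sum()), "regulated sites")   # -> 103 regulated sites

# dose-response and synergy
dr_a, dr_b, combo, t = synth.gen_viability(bliss_offset=0.2, noise_sd=0.02, seed=1)
params, _ = pharm.fit_4pl(dr_a)
print(round(params["ic50"], 3), "uM IC50")                    # -> 0.413 uM IC50
grid = pharm.synergy_grid(dr_a, dr_b, combo)
print(round(grid.mean_delta(max_expected=0.8), 3))            # -> 0.203
```

The chemical-proteomics run recovers all 30 planted competitive binders and
the 10 planted line-enriched complex partners; the phospho analysis lands
its adaptive cutoff at 0.487 (2 × the planted null ratio SD of 0.25) and
recovers the 100 planted regulated sites plus 3 borderline nulls; the 4PL
fit recovers the planted IC50 of 0.4 μM from noisy viability data, and the
mean ΔBliss over the non-saturated grid cells recovers the planted +0.2
synergy offset.

## Command line

```sh
parpiomics synth phospho --seed 1 --out data/
parpiomics phospho --quant data/phospho_sites.tsv --design data/design.csv --out diff.tsv
parpiomics ora --query hits.txt --gmt pathways.gmt --out terms.tsv
parpiomics synergy --single-a a.csv --single-b b.csv --combo grid.csv --out delta.tsv
```

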