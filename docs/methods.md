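# Methods

This note documents the statistical procedures implemented in `parpiomics`,
the choices made where the conventions of the field leave room, and what
the synthetic-data generators do and do not emulate.

## Table handling and quality control

MaxQuant-dialect tables are read by intensity-column prefix (`iBAQ ` for
protein groups, `Reporter intensity corrected ` for PTM-site tables,
`Intensity ` otherwise), with `+` marks in *Reverse* / *Potential
contaminant* mapping to boolean flags. QC keeps features with PEP < 0.05
(when a PEP column exists), no reverse or contaminant flag, and at least
one positive intensity. The filter report charges each removed feature to
the first rule it violates, in the fixed order reverse → contaminant → PEP
→ zero-intensity; this precedence only affects the bookkeeping, never the
surviving set. Zero intensities are preserved on parse and treated as
missing downstream, which matches the pairing of a "no intensity" exclusion
rule with column-minimum imputation: features with *no* measurements are
dropped, partially observed ones are kept and imputed.

## Shared statistics

* **Imputation.** Missing cells take the minimum observed value of their
  sample column — the standard left-censoring assumption for label-free MS,
  where values are missing mostly because they fall below detection.
  Imputation always precedes the log2 transform, which precedes testing.
* **Tests.** Two-sided Student's *t* (pooled variance) on log2 intensities
  is the default everywhere; Welch is available. Degenerate rows (both
  groups constant and equal) return *p* = 1 by convention.
* **Multiple testing.** Benjamini–Hochberg step-up (via statsmodels);
  q-values are reported alongside raw p-values, but the pass/fail gates use
  the raw-p cutoffs of the original reporting conventions.
* **Adaptive threshold.** The phospho fold-change cutoff is
  `multiplier × average SD` of the replicate-wise log2 ratios. Two choices
  are open in that phrase and both are configurable:
  * the averaging axis — default is the mean over replicates of the
    per-replicate dispersion across features (`per_replicate`); the mean
    over features of per-feature SD is available (`per_feature`);
  * the scale estimator — default is the normal-consistent MAD
    (1.4826 × median absolute deviation). The threshold is meant to
    estimate *null* dispersion from a matrix that is mostly null but
    contains the very regulated sites one is trying to find; the sample SD
    is inflated by that minority (by ~30% at 2% regulated sites with
    |log2FC| = 1.5 and null SD 0.25), while the MAD is essentially immune
    to it and converges to σ on pure-null data exactly as the sample SD
    does. `estimator="sample"` restores the plain SD.

## Competitive chemical proteomics

Specificity is scored per probe and cell line: impute → log2 → per-feature
mean log2(PD) − mean log2(CT) with Student *t* across replicates; specific
⇔ log2FC > 1.5 (note: a cutoff on the *log2* ratio, ≈2.8-fold raw) and
*p* < 0.05.

Cross-line comparison happens on the riBAQ scale. riBAQ is computed per
pulldown replicate (each sample column normalized to its own total), so the
replicate structure survives into the *t* test; features absent from one
line are imputed with the minimum present riBAQ of that replicate. The
enrichment gate is on the **raw** ratio of mean riBAQ (> 1.5 or < 1/1.5),
with *p* < 0.1 on the raw riBAQ replicate values (a log2-scale test is a
switch). The asymmetry — log2-scale cutoff for PD/CT, raw-scale cutoff for
the riBAQ ratio — follows the two stated reporting conventions and is
intentional.

The joint interactor call (`call_interactors`) requires both gates: a
protein must be a specific interactor in a line *and* riBAQ-enriched there.
This is the operative selection: the cross-line gate alone, at *p* < 0.1
over a whole proteome, has an irreducible false-positive floor (~0.4% per
feature at triplicate noise SD 0.25), and it is only meaningful applied to
the specific-interactor set.

## TMT phosphoproteomics

Channels are normalized by iterative rank-order normalization, specified
here at the contract level: (1) auto-reference = the column with minimal
summed rank displacement against the element-wise median pseudo-column;
(2) the invariant set starts as all features and each iteration drops the
most rank-displaced 5% (only features actually displaced; max 10
iterations, both configurable); (3) each column is mapped onto the
reference by an isotonic (monotone piecewise-linear) fit over the invariant
set, extended beyond its range by a constant log-offset, and shifted so the
median column-to-reference log ratio over the invariant set is exactly
zero. The reference column is never altered. Because rank displacement is
invariant under monotone scalings, the trimming loop is a pure
outlier-rejection schedule; its point is to keep strongly regulated or
artifact features from bending the calibration curve.

Differential analysis: impute → normalize → log2 → replicate-wise ratios
(treated − vehicle, paired by replicate number from the design table) →
mean log2FC, Student *t* across channels → pass ⇔ |log2FC| strictly above
the adaptive threshold, *p* < 0.05, and |mass error| ≤ 3 ppm (closed
interval; a missing mass-error column makes the gate a no-op with a logged
warning). The channel-to-condition assignment is never guessed: the design
table is a required input and the generator emits one. Technical replicates
are expected to be averaged upstream; biological replicates are the unit of
analysis.

## Label-free ADP-ribosylome

Impute → log2 → mean log2FC (drug − vehicle) with Student *t*. The fold
change gate is fixed at raw 2-fold and **inclusive** (|log2FC| ≥ 1), and a
*p* < 0.05 gate is applied by default (volcano-style reporting shows
p-values even though the stated filter is the fold change; the p gate can
be disabled). Negative log2FC means decreased ADP-ribosylation under drug.

## Over-representation analysis

One-sided hypergeometric upper tail, P(X ≥ k) with universe N, set size K,
query n, overlap k; enrichment factor (k/n)/(K/N); BH q across each
collection. Reporting gates: overlap ≥ 3, *p* < 0.01, enrichment ≥ 1.5.
The default universe is the detected proteome of the corresponding
experiment rather than the genome — testing against what could have been
observed avoids detection-bias enrichment. The integrated query is the
union of phospho and ADPr hit genes with per-gene source flags. Term-level
reproduction of any specific public pathway release is out of scope; the
collection is a user-supplied GMT.

## Pharmacology

Viability is raw signal divided by the mean of vehicle wells; fraction
affected fa = 1 − viability clipped to [0, 1] (clipping logged). The 4PL
`y = bottom + (top − bottom)/(1 + (x/IC50)^hill)` is fit by bounded
least squares on mean responses with multi-start initialization (IC50 grid
over the observed concentration range × hill ∈ {0.5, 1, 2}); constraints
0 ≤ bottom ≤ top ≤ 1.2, hill ∈ [0.1, 10]. A fitted span below 0.1 flags the
curve non-convergent with undefined IC50 (a flat curve has no inflection).
IC50 is relative (the inflection point).

Bliss independence is evaluated on fraction affected:
`Δ = fa_obs − (fa_A + fa_B − fa_A·fa_B)`. Marginals are means over
single-agent replicates, observations are means over combination replicates
(mean-then-Δ; Δ-then-mean is a switch at the data-preparation level).
`SynergyGrid.mean_delta(max_expected=...)` restricts the summary to cells
whose Bliss expectation leaves headroom — at saturating dose combinations
fa → 1 and any synergy offset is clipped away, so only non-saturated cells
are informative about its size.

## Synthetic data

The generators emulate the table shapes and the study conditions: three
biological replicates for pulldowns and label-free runs, TMT six-plex as
three treated/vehicle pairs, four viability replicates at the
concentration series 0.016–10 μM. Intensities are log-normal (log2 means
20/16, SD 3/2 for protein-level/reporter data), noise is multiplicative
log-normal, and ~5% of label-free cells are censored with
abundance-dependent (logistic-in-log2) missingness — the mechanism
column-minimum imputation is designed for. Two deliberate design choices:

* **Planted features are detectable.** Planted binders/sites draw their
  baselines from the upper half of the abundance distribution. A planted
  effect below the detection floor is unrecoverable by any scoring method,
  so leaving plants in the censored tail would make recovery measure the
  detection limit rather than the method.
* **Line-enriched partners are also specific binders**, as in the real
  experiment (a complex partner appears in the competitive pulldown), so
  the joint call is the recovery target.
* In the TMT generator, `noise_sd` is the SD of null replicate log2
  *ratios* (per-channel noise is `noise_sd/√2`), which is the scale on
  which the adaptive threshold operates; channels additionally carry global
  loading biases that normalization must remove. Planted ppm outliers are
  drawn from null sites so the mass-error gate check is independent of the
  recovery check.
* The viability generator adds its planted Bliss offset only on grid cells
  with headroom (expected fa + offset ≤ 1) and records which, since a
  clipped offset at a saturated corner is unidentifiable.

What the generators do **not** emulate: peptide-to-protein inference,
ratio compression in TMT, correlated (batch) noise, intensity-dependent
variance, and real interactome structure. Recovery rates on these data
therefore validate the scoring logic and its statistical calibration, not
performance on any specific biological matrix.

## Problem sizes and numerics

Default simulation sizes (2000 proteins for pulldowns, 5000 phosphosites,
3000 ADPr proteins, 5×5 dose grids) keep every stage within seconds on one
core while leaving ≥100 planted features per recovery estimate. Isotonic
fits use scikit-learn; hypergeometric tails, t tests and bounded least
squares use scipy. Ties in the rank-displacement trim are broken by the
sort order of the displacement values; features with zero displacement are
never trimmed, which is what lets the invariant set stabilize on clean
data. The IRON median-ratio postcondition is enforced exactly (to float
precision) by a final per-column shift.

## Known limitations

* Student's *t* with n = 3 per arm has limited power and unstable variance
  estimates; no moderated (empirical-Bayes) variance shrinkage is applied,
  matching the original analysis conventions rather than best current
  practice.
* The riBAQ cross-line test on raw (not log) values inherits mild
  right-skew; the raw-scale default mirrors the stated convention and a
  log-scale switch is provided.
* ORA treats genes as exchangeable; no gene-length or abundance weighting.
* The 4PL fit reports no confidence intervals; multi-start least squares
  finds the global optimum on well-behaved curves but is not a profile
  likelihood.
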