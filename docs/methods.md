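# Methods

This note documents the statistical model behind `proteoalloc`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions in corner cases.

## Input model

The pipeline consumes protein-level abundances: chromatographic peak areas
summed per protein, one column per sample. Non-detections are *missing*,
not zero — label-free instruments censor low-abundance proteins at a
detection limit rather than measuring zero. The loader therefore treats
blanks and NA tokens as missing but keeps a literal `0` as a recorded
value; the log2 stage later converts zeros to missing explicitly, because
they cannot be log-transformed and are operationally indistinguishable
from censoring. Sample columns match design rows by exact, case-sensitive
string equality so that design errors fail loudly instead of being
silently case-folded away.

## Differential-expression branch

1. **Valid-value filter.** A protein is retained when every condition
   group has ≥ `min_valid_frac` (default 0.70) valid values. The
   every-group reading is deliberate; with 3 replicates the threshold
   removes proteins observed in only 2/3 = 66.7% of a group. A `mode="any"`
   flag exposes the at-least-one-group alternative.
2. **log2 transform**, zeros → missing.
3. **Downshifted-normal imputation.** Per sample column with observed
   mean μ and sample sd σ (ddof = 1), missing cells are drawn from
   Normal(μ − 1.8 σ, (0.3 σ)²). The downshift (1.8) and width (0.3) are
   the conventional defaults of mainstream label-free post-processing and
   model values censored at the detection limit; both are configurable and
   recorded in the run log. Columns with fewer than 2 valid values cannot
   be parameterized and are a hard error. Valid cells are never altered;
   complete matrices pass through unchanged, so the step is idempotent.
4. **Tests.** Two-sided pooled-variance Student t for two groups;
   one-way fixed-effects ANOVA for ≥ 3. Welch's variant is deliberately
   not used: with 3–5 replicates per group and a shared platform the
   equal-variance assumption is standard, and the pooled test is what the
   surrounding toolchain applies by default.
5. **FDR.** Benjamini–Hochberg step-up, applied within each pairwise
   comparison separately (comparisons answer separate questions and are
   reported separately). Permutation-based FDR is out of scope.
6. **Regulation calls.** UP iff log2FC > 1 and p < 0.05, DOWN mirrored,
   strict inequalities on both thresholds. Calls use the raw p-value, with
   q-values reported alongside.
7. **Presence calls** run on the *unfiltered, unimputed* matrix: a protein
   is detected in a condition when its valid fraction there is ≥ 0.70 (the
   same threshold as the DE filter, for symmetry; configurable), and
   labelled unique/shared/absent across conditions.

Degenerate proteins follow fixed conventions rather than propagating NaN:
identical groups give p = 1 (no evidence), zero within-group variance with
differing means gives p = 0 plus a warning (this almost always indicates a
constant fixture, not data). Constant groups are detected by range
(max = min), not by comparing values to their mean, since the mean of n
identical floats need not be bitwise equal to them.

## Allocation branch

Mass fractions are computed on raw abundances with missing = 0 mass —
filtering and imputation are deliberately *not* applied, so the allocation
view reflects the measured proteome as-is. The amino-acid statistic weights
residue **counts** by protein fractions; molecular-mass weighting of
residues is not applied (the count reading is the only one consistent with
an abundance-weighted usage interpretation, and relative comparisons
between conditions are insensitive to a fixed per-residue weight).

Condition summaries average the per-sample fraction vectors
(fractions first, then mean), never fractions of pooled raw abundance: the
former is invariant to per-sample rescaling (normalization differences
between runs), the latter is not. Pathway comparisons test replicate-level
pathway fractions (n = replicates per condition) with the pooled t-test;
percent changes are relative, 100·Δ/ref. A protein annotated to several
KOG classes contributes full mass to each class, so class fractions may
sum above 1 across classes; partition additivity holds exactly for
single-class annotations. Formatted outputs print p < 1e-15 as 0; the
floating value is kept internally.

## Curation

The built-in KOG table has 23 classes. The original KOG scheme defines 25
functional categories; fungal annotations routinely lack N (cell motility)
and W (extracellular structures), and those two are omitted here. The
built-in hydrocarbon-degradation route (alkane → fatty alcohol → fatty
aldehyde → fatty acyl-CoA → beta-oxidation) ships only the
literature-named member proteins; fuller rosters can be supplied as a TSV
(`step`, `protein_id`, `note`). One curated id, `YALI0D04422`, lacks the
`p` suffix of the standard identifier pattern and is stored verbatim as a
documented exception.

## Ordination

PCA treats samples as observations over protein variables of the imputed
log2 matrix (ordination cannot handle missing cells). Variables are
centered; unit-variance scaling is off by default, the abundance-proteomics
convention, with a flag to enable it. Component signs are fixed by making
the largest-magnitude loading positive, so results are deterministic.
When all samples are identical the explained-variance ratios and scores
are defined as 0. Hierarchical clustering uses Euclidean distance with
average linkage by default and scipy's deterministic lowest-index
tie-break; trees serialize to Newick.

## Synthetic data

The generator draws, per protein, a KOG class (top seven classes C, J, G,
I, E, O, P jointly 72% of proteins) and a log2 baseline ~ Normal(20, 2.5)
— about five orders of magnitude of linear-scale abundance. Per condition
and replicate, the log2 signal is baseline + class effect + Normal(0,
0.25) replicate noise; the raw value 2^log2 is censored to missing with
probability `expit(−(log2 − 16))`, a soft detection limit producing ~10%
missing cells overall, concentrated in low-abundance proteins (MNAR).
Sequences are residue-i.i.d. draws from per-class 20-simplex compositions
(default: average proteome frequencies) with Poisson(450) lengths.

Scenario effects are log2 shifts chosen to match observed per-class
allocation changes of hydrocarbon growth: `hexadecane` raises class I by
1.163 (≈ ×2.24) and class C by 0.163 (≈ ×1.12) in the alkane condition;
`dp_oil` additionally lowers J, O and E (−0.578, −0.396, −0.120);
`null` has no effects.

The expected class allocation has closed form: share ∝ p_class ·
2^effect, because the log-normal baseline and noise expectation factors
are common to all classes and cancel. Note that an injected ×2.24 class
effect yields an expected allocation fold of only ×1.98 — fractions
renormalize against the whole proteome. The expectation ignores
missingness distortion (censored proteins carry little mass); empirically
this bias is a few percent, and recovery tolerances are set at 10%.

What the generator does **not** emulate: peptide-level roll-up noise,
shared/razor peptides, batch and chromatographic drift, correlated
protein co-regulation within pathways, realistic sequence composition
structure beyond class-level residue frequencies, or
technical-vs-biological replicate hierarchy. Passing recovery tests
therefore validates the statistical machinery, not instrument-specific
behaviour on real spectra.

## Reproducibility

One integer seed drives every stochastic stage through independent
`SeedSequence`-derived substreams (simulation, imputation), so adding a
stage never perturbs another stage's draws, and an identical config
reproduces every output table byte for byte. The run log records the
package version, seed, thresholds and all convention choices in force.

## Problem sizes

Validation uses 2,000-protein proteomes with 3 replicates per condition —
the scale of a typical quantified yeast LC-MS/MS experiment — and
50-protein instances for brute-force formula equivalence. The injected
fold-change recovery scenario uses 5 replicates per group: an a-priori
power analysis of the pooled t-test at log2FC = 2 and sd = 0.5 gives
recovery probability 0.948/0.996/0.9998 for 3/4/5 replicates and an
expected 8.1/3.7/1.4 spurious UP calls among 1,900 null proteins, so 5
replicates is the smallest size at which ≥ 95% recovery with ≤ 5 false
calls holds with margin. The amino-acid shift recovery uses a sign test
over 20 simulation seeds.

## Known limitations

* No moderated (empirical-Bayes) test statistics; with very few replicates
  a limma-style approach would be more powerful.
* No permutation FDR, no batch correction, no peptide-level modelling.
* The allocation view treats censored proteins as zero mass, slightly
  undercounting low-abundance pathways.
* The curated pathway covers only literature-named members; step-level
  fractions on other organisms require user curation.
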