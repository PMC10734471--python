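# proteoalloc

Proteome mass-fraction reallocation analysis for label-free quantitative
proteomics.

## The problem

When a microbe switches carbon source — say, an oleaginous yeast moving from
glucose to hydrocarbons — it does not just switch a few genes on and off: it
*reallocates* a finite proteome budget between functional programs (energy
metabolism, translation, lipid transport, ...). Label-free LC-MS/MS
quantification yields a protein × sample abundance matrix from which both
views can be computed: the classical differential-expression view (which
proteins changed?) and the resource-allocation view (what share of total
proteome mass does each pathway or amino acid receive, and how does that
share shift between conditions?).

`proteoalloc` implements both views as a tested, reproducible pipeline for
protein-level abundance tables, together with a synthetic-data generator
with known ground truth so every stage can be validated without access to
raw mass-spectrometry data.

## The statistics

For a sample with protein abundances PA_i (i = 1..N):

* **protein mass fraction** — f_Pi = PA_i / Σ_k PA_k, with undetected
  proteins contributing zero mass; Σ_i f_Pi = 1;
* **pathway mass fraction** — f_Path = Σ_{i ∈ pathway} f_Pi for a pathway
  with M member proteins (a KOG class, a KEGG pathway, or a hand-curated
  route);
* **amino-acid mass fraction** —
  f_Aj = Σ_i AA_ij · f_Pi / Σ_j Σ_i AA_ij · f_Pi, where AA_ij is the count
  of residue j in protein i's sequence; Σ_j f_Aj = 1.

All three are computed on raw abundances, without filtering or imputation.
Condition-level comparisons report alternate-over-reference fold changes of
replicate-mean fractions, relative percent changes 100·(fold − 1), and
two-sided pooled-variance Student t-tests over replicate-level values.

The differential-expression branch filters proteins to ≥ 70% valid values
per condition group, log2-transforms, imputes missing values from a
downshifted normal (per sample column: mean − 1.8 σ, width 0.3 σ —
modelling censoring at the detection limit), tests with a pooled-variance
Student t (or one-way ANOVA for ≥ 3 groups), adjusts by Benjamini–Hochberg,
and calls a protein UP when log2FC > 1 and p < 0.05 (DOWN symmetric; strict
inequalities). PCA and hierarchical clustering of the imputed matrix
summarize sample-level structure.

## Worked example

Simulate a glucose-vs-alkane experiment (2,000 proteins, 3 replicates per
condition, the lipid class I shifted up by 1.163 log2 units and the energy
class C by 0.163) and measure the lipid-class allocation shift:

```python
from proteoalloc import default_truth, simulate_dataset
from proteoalloc.allocation import compare_pathway_allocation
from proteoalloc.curation import map_to_pathways

sim = simulate_dataset(default_truth("hexadecane", seed=17))
lipid = map_to_pathways(sim.annotations, "I")
res = compare_pathway_allocation(sim.matrix, sim.design, lipid, "GP24", "HP24")
print(f"f_Path(I) GP24 = {res.mean_ref:.4f}")
print(f"f_Path(I) HP24 = {res.mean_alt:.4f}")
print(f"fold change    = {res.fold_change:.2f}  ({res.percent_change:+.1f}%)")
print(f"p-value        = {res.p_value:.2e}")
```

prints

```
f_Path(I) GP24 = 0.0565
f_Path(I) HP24 = 0.1163
fold change    = 2.06  (+105.9%)
p-value        = 2.31e-05
```

i.e. the lipid-transport-and-metabolism class holds 5.7% of proteome mass on
glucose and 11.6% on hexadecane — a 2.06-fold reallocation, close to the
closed-form expectation of 1.98 under the generative model (the injected
2.24-fold class effect, deflated because fractions renormalize against the
whole proteome).

The same pipeline runs from the shell on files or synthetic scenarios:

```sh
proteoalloc simulate --scenario hexadecane --out data/ --seed 17
proteoalloc analyze --config run.yaml
```

`analyze` writes differential-expression tables, per-class and per-pathway
allocation tables, amino-acid percent-change tables, presence calls, PCA
scores and a Newick sample tree, plus a run log sufficient to reproduce the
run byte for byte.

## Layout

| module | contents |
| --- | --- |
| `proteoalloc.io` | strict TSV/FASTA readers and writers |
| `proteoalloc.preprocess` | min-valid filter, log2, downshifted-normal imputer (sklearn transformers) |
| `proteoalloc.de` | pooled t-test, ANOVA, BH-FDR, regulation/presence/overlap calls |
| `proteoalloc.allocation` | f_Pi / f_Path / f_Aj statistics and comparisons |
| `proteoalloc.curation` | 23-class KOG table, curated hydrocarbon-degradation route |
| `proteoalloc.ordination` | PCA and hierarchical clustering of samples |
| `proteoalloc.simulate` | ground-truth synthetic proteome generator |
| `proteoalloc.pipeline` | end-to-end orchestration and report bundle |
| `proteoalloc.cli` | `proteoalloc analyze / simulate / version` |
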