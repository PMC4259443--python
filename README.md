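# lncscape

Long non-coding RNAs (lncRNAs) are poorly captured by classic microarray
studies, yet their expression stratifies tumors into clinically distinct
groups. `lncscape` is a Python package for the full analysis arc of a
lncRNA-centric bulk RNA-seq cohort study — the kind of workflow used to
profile lncRNAs across hundreds of breast carcinomas: quantify lncRNAs
without double-counting bases they share with mRNAs, find expression
subtypes by resampled consensus clustering, call subtype markers with a
negative-binomial exact test, relate lncRNAs to neighboring and distant
coding genes, integrate promoter histone marks from two cell contexts, and
screen every lncRNA against overall survival. It is aimed at computational
biologists who want each of those stages as a tested, seedable library
function rather than a one-off script.

A first-class synthetic-cohort generator plants every structure the
analysis assumes (clusters, markers, cis pairs, chromatin states, hazards)
with known ground truth, so the whole pipeline runs and is validated
end-to-end with no downloads.

## Core methods

* **Overlap-masked FPKM.** Gene lengths exclude exonic bases shared between
  mRNAs and lncRNAs (strand-blind, matching non-strand-specific libraries),
  mirroring union-mode counting where cross-class fragments are discarded:
  `FPKM(g,s) = counts(g,s)·10⁹ / (masked_length(g)·total(s))`. Expressed
  genes: FPKM ≥ 1 in ≥ 10 % of samples.
* **Consensus clustering.** 500 resampled runs (80 % samples × 80 %
  features), Ward linkage on Pearson distance `1 − r`; consensus
  `M(i,j) = co-clustered / co-sampled`; classes from Ward/Euclidean on the
  consensus rows; `k` chosen by BIC of a hard-assignment spherical Gaussian
  mixture.
* **Differential expression.** Median-of-ratios size factors; per-gene
  method-of-moments dispersion with a parametric trend `v(μ) = μ + αμ²`;
  conditional NB exact test on the split of each gene's total `K = K_A+K_B`;
  Benjamini–Hochberg FDR; one-vs-rest markers at FC ≥ 2, FDR < 0.05.
* **Association & GSEA.** Pearson lncRNA×mRNA matrices on
  variance-stabilized expression; ternarization of the global 1 % tails to
  {−1, 0, +1}; per-lncRNA weighted-KS enrichment over correlation-ranked
  mRNAs with permutation NES/FDR and ternary calls; biclustering of the
  ternary NES matrix.
* **Chromatin.** A gene is marked when a peak overlaps the closed ±5 kb TSS
  window; bivalent (H3K4me3 ∧ H3K27me3), enhancer (H3K27ac, optionally
  + H3K4me2), and mark gain/loss between two cell contexts.
* **Survival.** Kaplan–Meier / k-group log-rank between clusters; per-gene
  univariate Cox screen (continuous VST covariate, Wald p, BH FDR).

Full model descriptions, parameter tables and limitations are in
[docs/methods.md](docs/methods.md).

## Worked example

Simulate an 80-sample cohort with 4 planted clusters, 10 cis pairs and
8 markers per cluster, then run every stage:

```python
from lncscape.synthetic_data import CohortConfig, simulate
from lncscape.pipeline import PipelineConfig, run

simulate(CohortConfig(n_samples=80, n_mrna=120, n_lnc=60, n_cis_pairs=10,
                      n_marker_lnc=8, n_prognostic=4, seed=7), "demo")
out = run(PipelineConfig(gtf="demo/annotation.gtf", counts="demo/counts.tsv",
                         clinical="demo/clinical.tsv", outdir="demo_out",
                         seed=7, n_runs=100, k_fixed=4))
```

Cross-tabulating `demo_out/cluster_labels.tsv` against the generator truth
shows the four planted clusters recovered exactly (rows = found classes,
columns = planted clusters; class labels are arbitrary):

```
planted   0   1   2  3
found
1        37   0   0  0
2         0  20   0  0
3         0   0   0  8
4         0   0  15  0
```

The cis report ranks lncRNA–neighbor pairs by |r|; the top entries are the
planted pairs, whose sample correlation scatters around the generated
latent correlation ρ = 0.8:

```
lnc_gene_id coding_gene_id        r
    LNC0001       MRNA0042 0.858295
    LNC0003       MRNA0020 0.809250
    LNC0004       MRNA0074 0.797932
    LNC0002       MRNA0051 0.796545
```

The planted cluster hazard ratios (1, 3, 1.5, 0.7) separate the survival
curves — `demo_out/km_logrank.json` reports `chi2 = 18.54, p = 3.4e-04` —
and the one-vs-rest marker caller returns exactly the 8 planted cluster-1
markers at FC ≥ 2, FDR < 0.05.

The same pipeline runs from the shell:

```bash
lncscape simulate --outdir demo --seed 7
lncscape run-all --config pipeline.json      # or: quantify / cluster / ... / survive
```

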