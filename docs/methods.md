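# Methods

`lncscape` re-implements, as a tested pipeline, a lncRNA-centric analysis of
bulk RNA-seq tumor cohorts: overlap-masked quantification and filtering of
lncRNAs, consensus-clustering subtype discovery, negative-binomial
differential expression, lncRNA–mRNA association, per-lncRNA gene-set
enrichment, histone-mark integration, and survival association. This note
records the models, the parameters that matter, the numerical choices, and
what the synthetic cohorts do and do not establish.

## Gene model and overlap masking

Genes are modelled at gene level as the union of their transcript exons
(quantification is per gene, not per transcript). Coordinates are 0-based
half-open internally; GTF is read as 1-based inclusive and BED as 0-based
half-open. Because a non-strand-specific library cannot attribute a read
that falls where an mRNA exon and a lncRNA exon overlap, such bases are
removed from both genes' effective lengths, strand-blind: a gene's *masked
length* is its exonic bases not covered by exons of any gene of the other
class (coding vs non-coding). Genes with masked length 0 have no defined
FPKM and are dropped from all downstream steps.

The toy fragment counter follows union-mode semantics: a fragment is
credited to a gene only when that gene is the *sole* gene whose exons it
touches; ambiguous fragments — including every fragment spanning an
mRNA/lncRNA overlap — are discarded, which is what makes the masked length
the correct FPKM denominator:

FPKM(g, s) = counts(g, s) · 10⁹ / (masked_length(g) · total_fragments(s)),

with `total_fragments(s)` the column total of counted fragments (upstream
mapping totals are not available at this scale, so the counted total stands
in; the convention is recorded here and fixed in code).

A gene is "expressed" when FPKM ≥ 1 in at least 10 % of samples; the sample
threshold is `ceil(0.10 · n)` and both comparisons are inclusive.

## Neighbor (cis) assignment

Regulatory-domain assignment uses the basal-plus-extension rule: every
coding gene owns a strand-aware basal domain (5 kb upstream, 1 kb
downstream of the TSS), extended in both directions to the nearest other
gene's basal domain, capped at 1 Mb from the TSS and never shrinking below
the basal domain. A lncRNA is assigned to every coding gene whose domain
contains its TSS. All three distances are configurable; the defaults are
the rule's published defaults. Ontology annotation of the neighbors is out
of scope; set-level enrichment of neighbor genes is provided as a one-sided
hypergeometric test with BH adjustment.

## Normalization, dispersion and the exact test

Size factors are median-of-ratios: factor(s) = median over genes with a
positive geometric mean of counts(g, s)/geomean(g). Normalized counts are
counts divided by the sample's factor.

Dispersion: per gene, a method-of-moments estimate
α_g = (w − z·μ)/μ², where μ is the mean normalized count, w the
within-group pooled variance of normalized counts and z = mean(1/s_j)
(the shot-noise inflation from dividing by size factors). A single trend
coefficient α̂ (v(μ) = μ + α̂·μ²) is the median of the positive per-gene
estimates. The working dispersion is max(α_g, α̂), floored at 10⁻⁸ —
deliberately conservative for genes whose estimate fluctuates high.

The two-group test is a conditional NB exact test. With group count sums
K_A, K_B (K = K_A + K_B), pooled per-unit mean q = K/Σs, the group sums are
modelled as independent NB with means q·Σ_A s and variances
m + α·q²·Σ_A s² (the overdispersion of a sum of independent NB counts
scales with Σs², not (Σs)²). The p-value is the total probability of all
K + 1 splits no more likely than the observed one, normalized over the
splits; K = 0 gives p = 1. Benjamini–Hochberg adjustment is applied across
genes. Marker calling is one-vs-rest per cluster with
fold change = (mean_norm_target + 1)/(mean_norm_rest + 1) (pseudocount 1
keeps the ratio defined at zero means) at FC ≥ 2 and FDR < 0.05.

Calibration: null simulations at 30 samples per group land inside the
binomial 95 % band around the nominal 5 %. At markedly smaller groups the
max(α_g, α̂) rule makes the test conservative (estimation noise only ever
inflates the working dispersion); this is inherited from the estimator
design, not a bug, and is the reason the calibration study uses
cohort-scale groups.

## Variance-stabilizing transform

u(x) = ∫₀ˣ dμ/√(μ + α̂ μ²), computed by trapezoidal quadrature on a grid
quadratic near zero (substituting μ = t² removes the integrable √μ
singularity; 4096 nodes), then affine-calibrated to agree with log₂ of
normalized counts at the 99th and 90th percentiles of the normalized
counts (two anchors fix the two affine constants at the high-count end).
α̂ ≤ 0 falls back to the Poisson limit 2√x. The closed form
(2/√α)·asinh(√(αx)) is used as an oracle in tests, never in the pipeline
path, so the quadrature is independently checked.

## Consensus clustering

Each of `n_runs` (default 500) runs draws 80 % of samples and 80 % of
lncRNA features without replacement (run r seeds its own RNG as
`seed + r`), clusters samples by agglomerative Ward linkage on Pearson
distance (1 − r over feature vectors), and cuts at the k under evaluation.
The consensus entry M(i, j) is co-clustered runs divided by co-sampled runs
(so rarely co-sampled pairs are not biased low); never co-sampled pairs get
0 with a logged count, and the diagonal is forced to 1. Sample classes come
from clustering the consensus rows as feature vectors (Euclidean, Ward).
Ward on the non-Euclidean 1 − r distances uses the classical
Lance–Williams update on squared distances.

`select_k` scores each candidate k by the BIC of a hard-assignment
spherical Gaussian mixture (k·d means + one shared variance) on the
labels produced by the full pipeline at that k. The default scores all k in
the common expression space; scoring each k on its own consensus-matrix
rows is available (`bic_space="consensus"`) but compares likelihoods across
spaces that change with k, which under-selects in simulations. Known
limitation: when the expression contains strong *continuous* latent
programs (co-expression factors, a prognostic program), a mixture model can
legitimately prefer one extra component to cover the largest class, so on
such cohorts the BIC table should be read alongside the decisive-gap
structure (on the default synthetic cohort the 3→4 BIC drop is an order of
magnitude larger than the 4→5 drop). On well-separated mixtures matching
the model's assumptions, k = 4 is recovered in ≥ 18/20 seeds.

## Association and per-lncRNA GSEA

Correlation matrices are Pearson r across samples on VST expression
(constant rows dropped with a warning). Ternarization flags the globally
largest floor(0.01·N) entries +1 and the smallest floor(0.01·N) entries −1
(N = all entries); ties at a cutoff break by (row, column) ascending; the
per-row variant is a config option. Two-way ordering of the ternary matrix
uses complete linkage on Euclidean distance.

GSEA treats each lncRNA profile as a continuous phenotype: mRNAs are ranked
by Pearson r (ties by gene id), and the weighted Kolmogorov–Smirnov running
sum scores each set: hits add |r|^p (p = 1 by default) normalized over
in-set hits, misses subtract 1/(N − N_hit); the enrichment score is the
extremum of largest magnitude, sign kept. Because the phenotype is
continuous, sample-label permutation is unavailable; the null is gene-label
permutation (random same-size sets), cached per set size per lncRNA.
NES = es / mean(|null es| of the matching sign); the permutation p is the
sign-matched add-one tail; BH runs across all (lncRNA, set) pairs; the
ternary call is 0 when FDR > 0.05 and sign(NES) otherwise. Biclustering
reports maximal contiguous constant-sign blocks (minimum size
configurable) on the two-way-ordered matrix.

## Chromatin

A gene is marked by a histone mark in a context when any peak overlaps the
closed ±5 kb window around its TSS ([tss − w, tss + w], i.e. half-open
[tss − w, tss + w + 1); any ≥ 1 bp overlap qualifies — the center-vs-any
question is settled as any-overlap and the window is configurable). Calls:
bivalent = H3K4me3 ∧ H3K27me3 in one context; enhancer lncRNAs =
H3K27ac in any given context (lax) or H3K27ac ∧ H3K4me2 within a single
context (stringent); mark change between contexts partitions the marked
union into lost/gained/retained. Peaks are used as released, without score
filtering.

## Survival

Cluster comparisons: per-group Kaplan–Meier product-limit curves and the
k-group log-rank test. The per-gene screen fits a univariate Cox
proportional-hazards model with VST expression as a continuous covariate
(Breslow tie handling), takes the Wald p, and BH-adjusts across the
screened list; genes with fdr < 0.05 are flagged. Constant covariates get
coefficient 0 and p = 1; non-convergent fits are flagged with p = 1.
Single-gene KM figures dichotomize at the median (ties to "low") — the
cutpoint is a reporting convention, not part of the screen.

## Synthetic cohorts: what they emulate and what they do not

The generator lays genes out in loci ≥ 30 kb apart on two synthetic
chromosomes; genes sharing a locus (cis pairs, exon-overlapping lncRNAs)
share histone-mark status, so TSS-window annotation recovers the planted
status exactly. Defaults (the study conditions for every end-to-end test):
200 samples in 4 clusters at proportions (0.46, 0.25, 0.19, 0.10) echoing
the luminal-A/B, basal, HER2 mix of a breast cohort; 800 coding genes and
300 lncRNAs (lncRNAs ~e^1.4-fold lower expressed); NB dispersion α = 0.2;
25 marker lncRNAs per cluster at log₂ effect 2.0 (the FC = 4 regime the
marker caller must detect at FC ≥ 2); 40 cis pairs sharing a per-pair
latent factor scaled so the log-scale correlation is 0.8 (coefficient
c_g = √(ρ/(1−ρ)·v_g) with v_g = α + 1/μ_g the log-scale noise of gene g);
15 % of lncRNAs with a coding-overlapping exon; 10 % essentially silent
(below the FPKM filter); 10 % bivalent; either-context H3K27ac fraction
0.6; 30 % of lncRNAs H3K27me3-marked with half losing the mark in the
second context and gaining +1.5 log units of tumor expression; library
sizes spanning 4×; exponential survival with cluster hazard ratios
(1, 3, 1.5, 0.7) around a 1/1500 d⁻¹ baseline, ~40 % censoring, and ten
prognostic lncRNAs driven by one shared per-sample program whose log-hazard
coefficient is 0.5 per SD (a shared program keeps each gene's *marginal*
hazard near the planted value; ten independent hazards would attenuate
each other as frailty).

Not emulated: junction reads and transcript structure (counts are drawn at
gene level), batch effects, tumor purity, copy number, subtype-dependent
censoring, realistic genome sequence, and peak-calling noise (peaks are
placed, not called). Passing the end-to-end tests therefore shows the
*methods* recover planted structure under their stated noise model — not
that results from real tumor cohorts are reproduced.

## Problem sizes

Simulation-backed checks use: the 200-sample default cohort (clustering
ARI, markers, cis correlation, chromatin recovery, log-rank); 1 000 null
genes at 30 + 30 samples (exact-test calibration); a 300-sample, 500-lncRNA
cohort with flat cluster hazards (prognostic recovery); 20 seeds of
40-sample Gaussian mixtures (k selection); 1 000 permutations for GSEA
nulls; and a 50-sample cohort run twice through the full pipeline for
byte-identical determinism. These sizes are the package's chosen study
conditions and are fixed in `tests/` and `scripts/acceptance.py`.
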