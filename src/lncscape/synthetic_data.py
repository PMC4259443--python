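"""Synthetic cohort generator with known ground truth.

Emits everything the pipeline consumes — GTF annotation, a gene x sample
raw count matrix, a clinical table, and ChIP-seq peak BEDs for six histone
marks in two cell contexts — with the statistical structures the analysis
assumes planted and recorded:

* four latent expression clusters over negative-binomial counts, with a
  configurable number of marker lncRNAs per cluster (default 4-fold up);
* cis-correlated lncRNA/coding neighbor pairs sharing a latent factor scaled
  to a target log-scale correlation;
* six lncRNA biotype categories, a configurable fraction with exons
  overlapping coding exons (exercising length masking);
* histone-mark status coupled to expression tier (active marks with high
  expression, H3K27me3/H3K9me3 with low), planted bivalent promoters and
  H3K27ac enhancers, and H3K27me3 loss between the two contexts paired with
  raised tumor expression of the de-repressed genes;
* exponential survival with cluster-dependent hazard ratios and planted
  prognostic genes acting through a per-sample latent factor.

All randomness flows from a single integer seed; identical seeds give
byte-identical outputs. Genes are laid out in loci at least 30 kb apart so
TSS mark windows of different loci never interact; genes sharing a locus
(cis pairs, overlapping lncRNAs) share mark status.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .chromatin import ACTIVE_MARKS, MARKS
from .gene_model import GeneRecord, LNC_BIOTYPES, write_gtf

LOCUS_SPACING = 30_000
CONTEXT_A = "HMEC"
CONTEXT_B = "MCF7"
SUBTYPE_NAMES = ("basal-like", "HER2-enriched", "luminal A", "luminal B")


@dataclass
class CohortConfig:
    """Generator parameters; defaults are the study conditions under test."""

    n_samples: int = 200
    n_clusters: int = 4
    cluster_proportions: tuple = (0.46, 0.25, 0.19, 0.10)
    n_mrna: int = 800
    n_lnc: int = 300
    mrna_log_mean: float = 5.3     # natural-log NB mean scale for coding genes
    lnc_log_mean: float = 3.9      # lncRNAs are lower-expressed
    log_mean_sd: float = 1.0
    dispersion: float = 0.2        # NB alpha
    cluster_log2_effect: float = 2.0
    n_marker_lnc: int = 25
    n_cis_pairs: int = 40
    cis_rho: float = 0.8
    frac_lnc_overlap: float = 0.15
    frac_lnc_silent: float = 0.10  # lncRNAs below the FPKM>=1-in-10% filter
    bivalent_fraction: float = 0.1
    enhancer_fraction: float = 0.6
    mark_loss_fraction: float = 0.5
    baseline_hazard: float = 1.0 / 1500.0   # events per day
    cluster_hazard_ratios: tuple = (1.0, 3.0, 1.5, 0.7)
    n_prognostic: int = 10
    prognostic_beta: float = 0.5
    censoring_rate: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.cluster_proportions) - 1.0) > 1e-9:
            raise ValueError("cluster proportions must sum to 1")
        if not 0 < self.cis_rho < 1:
            raise ValueError("cis_rho must be in (0, 1)")
        if len(self.cluster_proportions) != self.n_clusters:
            raise ValueError("one proportion per cluster required")
        if len(self.cluster_hazard_ratios) != self.n_clusters:
            raise ValueError("one hazard ratio per cluster required")


@dataclass
class AnnotationTruth:
    """Geometry ground truth from generate_annotation."""

    cis_pairs: list          # (lnc_id, coding_id)
    overlap_lnc: list        # lnc ids with coding-overlapping exons
    loci: dict               # gene_id -> locus index
    lnc_only_loci: list      # locus indices containing only lncRNAs


@dataclass
class GroundTruth:
    """Everything planted in one simulated cohort."""

    sample_cluster: pd.Series
    markers: dict                       # cluster index -> list of lnc ids
    cis_pairs: list                     # (lnc_id, coding_id, rho)
    prognostic: list                    # lnc ids with planted log-hazard
    derepressed: list                   # genes losing H3K27me3 in context B
    silent: list                        # lncRNAs planted below the filter
    baseline_log_mean: pd.Series
    annotation: AnnotationTruth | None = None
    mark_status: pd.DataFrame | None = None   # gene x (mark, context) booleans


def _make_gene(rng, gene_id, name, biotype, chrom, strand, locus_start) -> GeneRecord:
    exons = []
    pos = locus_start
    for _ in range(int(rng.integers(2, 4))):
        length = int(rng.integers(150, 400))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(500, 2000))
    return GeneRecord(gene_id, name, biotype, chrom, strand, exons)


def generate_annotation(cfg: CohortConfig, seed: int | None = None):
    """Lay out coding and lncRNA genes on two synthetic chromosomes.

    Returns (genes, AnnotationTruth). Cis-pair lncRNAs sit 0.5-4.5 kb
    upstream of their coding partner's TSS (same locus, exons disjoint);
    the configured fraction of the remaining lncRNAs get an exon overlapping
    a coding exon; everything else occupies its own locus.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    genes: list[GeneRecord] = []
    loci: dict[str, int] = {}
    locus = 0

    def place(locus_idx: int) -> tuple[str, int]:
        chrom = f"chrS{1 + locus_idx % 2}"
        start = 10_000 + (locus_idx // 2) * LOCUS_SPACING
        return chrom, start

    coding = []
    for i in range(cfg.n_mrna):
        chrom, start = place(locus)
        g = _make_gene(rng, f"MRNA{i:04d}", f"CG{i:04d}", "protein_coding", chrom,
                       "+" if rng.random() < 0.5 else "-", start)
        genes.append(g)
        coding.append(g)
        loci[g.gene_id] = locus
        locus += 1

    n_cis = min(cfg.n_cis_pairs, cfg.n_mrna, cfg.n_lnc)
    cis_hosts = rng.choice(cfg.n_mrna, size=n_cis, replace=False)
    cis_pairs = []
    lnc_idx = 0
    for host_i in cis_hosts:
        host = coding[host_i]
        gid = f"LNC{lnc_idx:04d}"
        if host.strand == "+":
            s = host.tss - int(rng.integers(2500, 4500))
        else:
            s = host.tss + int(rng.integers(500, 2500))
        exons = [(s, s + int(rng.integers(300, 800)))]
        biotype = "lincRNA" if rng.random() < 0.6 else "antisense"
        g = GeneRecord(gid, gid, biotype, host.chrom, "+" if rng.random() < 0.5 else "-", exons)
        genes.append(g)
        loci[gid] = loci[host.gene_id]
        cis_pairs.append((gid, host.gene_id))
        lnc_idx += 1

    n_overlap = int(np.floor(cfg.frac_lnc_overlap * cfg.n_lnc))
    free_hosts = [i for i in range(cfg.n_mrna) if i not in set(cis_hosts)]
    overlap_hosts = rng.choice(free_hosts, size=n_overlap, replace=False)
    overlap_lnc = []
    for host_i in overlap_hosts:
        host = coding[host_i]
        gid = f"LNC{lnc_idx:04d}"
        es, ee = host.exons[0]
        mid = (es + ee) // 2
        exons = [(mid, mid + (ee - es))]          # half-overlaps exon 1
        far = host.end + int(rng.integers(1000, 3000))
        exons.append((far, far + int(rng.integers(200, 500))))
        biotype = "antisense" if rng.random() < 0.7 else "sense_overlapping"
        g = GeneRecord(gid, gid, biotype, host.chrom, "+" if rng.random() < 0.5 else "-", exons)
        genes.append(g)
        loci[gid] = loci[host.gene_id]
        overlap_lnc.append(gid)
        lnc_idx += 1

    other_biotypes = list(LNC_BIOTYPES)
    weights = np.array([0.34, 0.48, 0.01, 0.05, 0.11, 0.01])
    lnc_only_loci = []
    while lnc_idx < cfg.n_lnc:
        chrom, start = place(locus)
        gid = f"LNC{lnc_idx:04d}"
        biotype = other_biotypes[int(rng.choice(len(other_biotypes), p=weights))]
        g = _make_gene(rng, gid, gid, biotype, chrom, "+" if rng.random() < 0.5 else "-", start)
        genes.append(g)
        loci[gid] = locus
        lnc_only_loci.append(locus)
        locus += 1
        lnc_idx += 1

    return genes, AnnotationTruth(cis_pairs, overlap_lnc, loci, lnc_only_loci)


def generate_cohort(
    cfg: CohortConfig, genes: list[GeneRecord], ann: AnnotationTruth, seed: int | None = None
):
    """Simulate counts and clinical data over the annotated genes.

    Returns (counts DataFrame genes x samples, clinical DataFrame indexed by
    sample, GroundTruth). Counts are NB(mean, alpha) with log-mean = gene
    baseline + cluster marker effect + cis latent factor + prognostic latent
    + library-size offset (4x range). Survival is exponential with cluster-
    and prognostic-gene-dependent hazard and independent censoring.
    """
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 1_000_003)
    lnc_ids = [g.gene_id for g in genes if g.is_lncRNA]
    mrna_ids = [g.gene_id for g in genes if not g.is_lncRNA]
    gene_ids = [g.gene_id for g in genes]
    n_genes, n = len(gene_ids), cfg.n_samples
    samples = [f"S{i:04d}" for i in range(n)]

    # cluster assignment: deterministic counts per proportions, shuffled
    counts_per = np.floor(np.asarray(cfg.cluster_proportions) * n).astype(int)
    counts_per[0] += n - counts_per.sum()
    labels = np.repeat(np.arange(cfg.n_clusters), counts_per)
    labels = labels[rng.permutation(n)]
    sample_cluster = pd.Series(labels, index=samples, name="cluster")

    base = pd.Series(
        np.where(
            [g.is_lncRNA for g in genes],
            cfg.lnc_log_mean + cfg.log_mean_sd * rng.standard_normal(n_genes),
            cfg.mrna_log_mean + cfg.log_mean_sd * rng.standard_normal(n_genes),
        ),
        index=gene_ids,
    )

    cis_lnc = [l for l, _ in ann.cis_pairs]
    for l, c in ann.cis_pairs:  # healthy fixed baseline so the latent dominates
        base[l] = np.log(300.0)
        base[c] = np.log(300.0)

    # markers: lncRNAs not in cis pairs, disjoint across clusters
    free_lnc = [g for g in lnc_ids if g not in set(cis_lnc)]
    markers: dict[int, list[str]] = {}
    pool = list(rng.permutation(free_lnc))
    for c in range(cfg.n_clusters):
        markers[c] = sorted(pool[c * cfg.n_marker_lnc: (c + 1) * cfg.n_marker_lnc])
    used = {g for v in markers.values() for g in v}

    # prognostic lncRNAs among the remainder
    remainder = [g for g in free_lnc if g not in used]
    prognostic = sorted(rng.permutation(remainder)[: cfg.n_prognostic])

    # silent lncRNAs: essentially unexpressed, removed by the FPKM filter
    rest = [g for g in remainder if g not in set(prognostic)]
    n_silent = int(np.floor(cfg.frac_lnc_silent * cfg.n_lnc))
    silent = sorted(rng.permutation(rest)[:n_silent])
    base[silent] = np.log(0.03)

    # de-repressed genes: lncRNA-only loci, low baseline preferred
    n_k27 = int(round(0.3 * cfg.n_lnc))            # H3K27me3-marked pool size
    n_lost = int(round(cfg.mark_loss_fraction * n_k27))
    lnc_solo = [g for g in lnc_ids if ann.loci[g] in set(ann.lnc_only_loci)]
    lnc_solo = [g for g in lnc_solo
                if g not in used and g not in set(prognostic) and g not in set(silent)]
    by_low = sorted(lnc_solo, key=lambda g: base[g])
    derepressed = sorted(by_low[:n_lost])
    base[derepressed] = base[derepressed] + 1.5     # raised tumor expression

    logmu = np.tile(base.to_numpy()[:, None], (1, n))
    eff = cfg.cluster_log2_effect * np.log(2.0)
    gi = {g: i for i, g in enumerate(gene_ids)}
    for c, marks in markers.items():
        cols = np.where(labels == c)[0]
        for g in marks:
            logmu[gi[g], cols] += eff

    cis_rho_list = []
    for l, c in ann.cis_pairs:
        z = rng.standard_normal(n)
        for g in (l, c):
            v = cfg.dispersion + 1.0 / np.exp(base[g])
            coef = np.sqrt(cfg.cis_rho / (1.0 - cfg.cis_rho) * v)
            logmu[gi[g]] += coef * z
        cis_rho_list.append((l, c, cfg.cis_rho))

    # one prognostic program: a shared per-sample factor drives every planted
    # gene's expression and the hazard, so each gene's marginal log-hazard per
    # covariate SD stays near the planted beta
    prog_factor = rng.standard_normal(n)
    for g in prognostic:
        v = cfg.dispersion + 1.0 / np.exp(base[g])
        logmu[gi[g]] += np.sqrt(0.8 * v / 0.2) * prog_factor

    lib = rng.uniform(np.log(0.5), np.log(2.0), size=n)
    mu = np.exp(logmu + lib[None, :])
    r = 1.0 / cfg.dispersion
    counts = rng.negative_binomial(r, r / (r + mu)).astype(int)
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=samples)

    # survival: exponential with cluster HR and prognostic latent effects
    hr = np.asarray(cfg.cluster_hazard_ratios)[labels]
    loghaz = np.log(cfg.baseline_hazard) + np.log(hr) + cfg.prognostic_beta * prog_factor
    t_event = rng.exponential(1.0 / np.exp(loghaz))
    cens_rate = cfg.baseline_hazard * cfg.censoring_rate / max(1e-9, 1.0 - cfg.censoring_rate)
    t_cens = np.minimum(rng.exponential(1.0 / cens_rate, size=n), 3000.0)
    os_time = np.maximum(1, np.minimum(t_event, t_cens).astype(int))
    os_event = (t_event <= t_cens).astype(int)

    er = np.where(labels >= 2, "positive", "negative")          # luminal ER+
    pr = np.where((labels >= 2) & (rng.random(n) < 0.8), "positive", "negative")
    her2 = np.where(labels == 1, "positive", "negative")
    clinical = pd.DataFrame(
        {
            "subtype": [SUBTYPE_NAMES[c] for c in labels],
            "er_status": er,
            "pr_status": pr,
            "her2_status": her2,
            "os_time": os_time,
            "os_event": os_event,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    truth = GroundTruth(
        sample_cluster=sample_cluster,
        markers=markers,
        cis_pairs=cis_rho_list,
        prognostic=list(prognostic),
        derepressed=list(derepressed),
        silent=list(silent),
        baseline_log_mean=base,
        annotation=ann,
    )
    return counts_df, clinical, truth


def generate_peaks(
    cfg: CohortConfig, genes: list[GeneRecord], truth: GroundTruth, seed: int | None = None
):
    """Plant histone-mark status per locus and emit peak intervals.

    Mark status is drawn per locus from the expression tier of the locus
    (active marks favor high tiers, repressive marks low tiers), then copied
    to every gene in the locus so TSS-window annotation recovers it exactly.
    Forced sets: planted bivalent lncRNAs (H3K4me3 + H3K27me3 in context A,
    no other gene bivalent there), H3K27me3 in context A for the repressed
    pool with the derepressed subset losing it in context B. Returns
    (dict (mark, context) -> peak DataFrame, mark-status DataFrame).
    """
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 2_000_003)
    ann = truth.annotation
    gene_ids = [g.gene_id for g in genes]
    lnc_ids = [g.gene_id for g in genes if g.is_lncRNA]
    base = truth.baseline_log_mean

    # per-locus primary gene and expression tier (0 low, 1 mid, 2 high)
    locus_members: dict[int, list[str]] = {}
    for g in genes:
        locus_members.setdefault(ann.loci[g.gene_id], []).append(g.gene_id)
    primaries = {loc: members[0] for loc, members in locus_members.items()}
    prim_base = base[[primaries[loc] for loc in sorted(locus_members)]]
    qs = prim_base.quantile([1 / 3, 2 / 3]).to_numpy()
    tier = {loc: int(np.searchsorted(qs, base[primaries[loc]], side="right"))
            for loc in sorted(locus_members)}

    p_active = {0: 0.15, 1: 0.5, 2: 0.85}
    lo, hi = max(0.0, cfg.enhancer_fraction - 0.25), min(1.0, cfg.enhancer_fraction + 0.25)
    p_k27ac = {0: lo, 1: cfg.enhancer_fraction, 2: hi}
    p_repr = {0: 0.85, 1: 0.5, 2: 0.15}

    cols = pd.MultiIndex.from_tuples(
        sorted((m, c) for m in MARKS for c in (CONTEXT_A, CONTEXT_B)), names=["mark", "context"]
    )
    status = pd.DataFrame(False, index=gene_ids, columns=cols)

    sorted_loci = sorted(locus_members)
    for mark in MARKS:
        if mark == "H3K27me3":
            continue  # handled by the forced repression plan below
        if mark == "H3K27ac":
            # latent enhancer status per locus at the configured rate; the two
            # contexts echo it almost always, so the either-context fraction
            # matches the enhancer fraction rather than its union inflation
            for loc in sorted_loci:
                enh = rng.random() < p_k27ac[tier[loc]]
                for ctx in (CONTEXT_A, CONTEXT_B):
                    if rng.random() < (0.95 if enh else 0.02):
                        for gid in locus_members[loc]:
                            status.loc[gid, (mark, ctx)] = True
            continue
        for ctx in (CONTEXT_A, CONTEXT_B):
            for loc in sorted_loci:
                t = tier[loc]
                p = p_active[t] if mark in ACTIVE_MARKS else p_repr[t]
                if rng.random() < p:
                    for gid in locus_members[loc]:
                        status.loc[gid, (mark, ctx)] = True

    # repression plan: pool of low-tier solo lncRNAs marked in context A;
    # derepressed subset (chosen in generate_cohort) loses the mark in B
    derep = set(truth.derepressed)
    n_k27 = int(round(0.3 * cfg.n_lnc))
    solo = [g for g in lnc_ids if ann.loci[g] in set(ann.lnc_only_loci) and g not in derep]
    solo_low = sorted(solo, key=lambda g: base[g])
    retained = set(solo_low[: max(0, n_k27 - len(derep))])
    k27a = derep | retained
    for gid in k27a:
        for g2 in locus_members[ann.loci[gid]]:
            status.loc[g2, ("H3K27me3", CONTEXT_A)] = True
            if gid not in derep:
                status.loc[g2, ("H3K27me3", CONTEXT_B)] = True

    # planted bivalent lncRNAs: both H3K4me3 and H3K27me3 in context A (the
    # polycomb mark retained in B so the loss plan stays exact); every other
    # gene loses H3K27me3 entirely if it would be bivalent by chance
    n_biv = int(np.floor(cfg.bivalent_fraction * cfg.n_lnc))
    biv_pool = [g for g in lnc_ids
                if ann.loci[g] in set(ann.lnc_only_loci) and g not in derep]
    bivalent = set(rng.permutation(sorted(biv_pool))[:n_biv])
    for gid in bivalent:
        status.loc[gid, ("H3K4me3", CONTEXT_A)] = True
        status.loc[gid, ("H3K27me3", CONTEXT_A)] = True
        status.loc[gid, ("H3K27me3", CONTEXT_B)] = True
    both = status[("H3K4me3", CONTEXT_A)] & status[("H3K27me3", CONTEXT_A)]
    for gid in status.index[both]:
        if gid in bivalent:
            continue
        if gid in k27a:  # forced repression pool keeps H3K27me3; drop H3K4me3
            status.loc[gid, ("H3K4me3", CONTEXT_A)] = False
        else:
            for g2 in locus_members[ann.loci[gid]]:
                status.loc[g2, ("H3K27me3", CONTEXT_A)] = False
                status.loc[g2, ("H3K27me3", CONTEXT_B)] = False

    tss = {g.gene_id: (g.chrom, g.tss) for g in genes}
    peaks: dict[tuple[str, str], pd.DataFrame] = {}
    for mark, ctx in cols:
        rows = []
        for gid in gene_ids:
            if status.loc[gid, (mark, ctx)]:
                chrom, t0 = tss[gid]
                off = int(rng.integers(-4000, 3700))
                rows.append((chrom, max(0, t0 + off), max(0, t0 + off) + 300))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"]).sort_values(
            ["chrom", "start"], kind="stable"
        ).reset_index(drop=True)
        peaks[(mark, ctx)] = df
    truth.mark_status = status
    return peaks, status


def simulate(cfg: CohortConfig, outdir) -> GroundTruth:
    """Run the full generator and write GTF, counts, clinical, BEDs, truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes, ann = generate_annotation(cfg)
    counts, clinical, truth = generate_cohort(cfg, genes, ann)
    peaks, status = generate_peaks(cfg, genes, truth)

    write_gtf(genes, outdir / "annotation.gtf")
    counts.to_csv(outdir / "counts.tsv", sep="\t", index_label="gene_id")
    clinical.to_csv(outdir / "clinical.tsv", sep="\t")
    for (mark, ctx), df in peaks.items():
        df.to_csv(outdir / f"peaks_{mark}_{ctx}.bed", sep="\t", header=False, index=False)
    status_flat = status.copy()
    status_flat.columns = [f"{m}:{c}" for m, c in status.columns]
    status_flat.to_csv(outdir / "mark_status.tsv", sep="\t", index_label="gene_id")
    payload = {
        "config": asdict(cfg),
        "sample_cluster": {k: int(v) for k, v in truth.sample_cluster.items()},
        "markers": {str(k): v for k, v in truth.markers.items()},
        "cis_pairs": truth.cis_pairs,
        "prognostic": truth.prognostic,
        "derepressed": truth.derepressed,
        "silent": truth.silent,
        "overlap_lnc": ann.overlap_lnc,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    return truth
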