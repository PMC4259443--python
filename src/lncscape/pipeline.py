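"""End-to-end pipeline: quantify -> filter -> normalize -> cluster -> markers
-> association -> GSEA -> chromatin -> survival, with a run manifest.

Stage outputs are plain TSV/JSON in the output directory; a manifest records
the package version, the seed, a hash of the configuration and the completed
stages, so a rerun with identical inputs is byte-identical and stages can be
skipped when their outputs already exist under the same configuration hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import association, chromatin, consensus_clustering as cc, gene_model, gsea
from . import expression as expr_mod
from . import normalization_de as nde
from . import survival as surv_mod

logger = logging.getLogger(__name__)

STAGES = (
    "quantify", "filter", "normalize", "cluster", "markers",
    "associate", "gsea", "chromatin", "survive",
)


@dataclass
class PipelineConfig:
    """Paths and stage parameters for one pipeline run."""

    gtf: str
    counts: str
    clinical: str
    peak_beds: dict = field(default_factory=dict)   # "mark:context" -> path
    gmt: str | None = None
    outdir: str = "lncscape_out"
    seed: int = 0
    fpkm_min: float = 1.0
    fpkm_min_fraction: float = 0.10
    n_runs: int = 500
    frac_samples: float = 0.8
    frac_features: float = 0.8
    k_range: tuple = (2, 8)
    k_fixed: int | None = None
    fc_min: float = 2.0
    fdr_max: float = 0.05
    ternary_tail: float = 0.01
    gsea_n_perm: int = 1000
    gsea_weight: float = 1.0
    gsea_max_lnc: int | None = 25
    tss_window: int = 5000
    contexts: tuple = ("HMEC", "MCF7")

    def validate(self) -> None:
        for name in ("gtf", "counts", "clinical"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} input not found: {p}")
        for key, p in self.peak_beds.items():
            if ":" not in key:
                raise ValueError(f"peak key {key!r} must be 'mark:context'")
            if not Path(p).exists():
                raise FileNotFoundError(f"peak bed not found: {p}")
        if not (0 < self.fpkm_min_fraction <= 1):
            raise ValueError("fpkm_min_fraction must be in (0, 1]")

    def digest(self) -> str:
        payload = asdict(self)
        payload.pop("outdir")  # the run is defined by inputs + parameters
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g", **kw)


def run(config: PipelineConfig, stop_after: str | None = None) -> Path:
    """Execute stages in dependency order; returns the output directory.

    stop_after: optional stage name ('quantify' ... 'survive') to end the run
    early. A completed run with the same configuration hash is not repeated
    (delete manifest.json to force a rerun).
    """
    if stop_after is not None and stop_after not in STAGES:
        raise ValueError(f"unknown stage {stop_after!r}")
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "seed": config.seed,
                "config_hash": config.digest(), "stages": []}
    prior = out / "manifest.json"
    if prior.exists():
        old = json.loads(prior.read_text())
        if old.get("config_hash") == manifest["config_hash"] and (
            stop_after or old["stages"][-1]) in old.get("stages", []):
            logger.info("outputs up to date under config %s; skipping", manifest["config_hash"])
            return out

    genes = gene_model.load_annotation(config.gtf)
    lnc = [g for g in genes if g.is_lncRNA]
    coding = [g for g in genes if not g.is_lncRNA]
    counts = pd.read_csv(config.counts, sep="\t", index_col=0)
    clinical = pd.read_csv(config.clinical, sep="\t", index_col=0)

    def stage(name):
        logger.info("stage %s", name)
        manifest["stages"].append(name)

    def finish():
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return out

    # quantify: masked lengths + FPKM
    stage("quantify")
    lengths = gene_model.masked_lengths(genes)
    _write(lengths, out / "masked_lengths.tsv")
    counts = counts.loc[counts.index.intersection(lengths.index[lengths["masked_length"] > 0])]
    fpkm = expr_mod.fpkm(counts, lengths)
    _write(fpkm, out / "fpkm.tsv", index_label="gene_id")

    if stop_after == "quantify":
        return finish()

    # filter: expressed genes
    stage("filter")
    expressed = expr_mod.filter_low_expression(fpkm, config.fpkm_min, config.fpkm_min_fraction)
    lnc_ids = [g.gene_id for g in lnc if g.gene_id in set(expressed)]
    mrna_ids = [g.gene_id for g in coding if g.gene_id in set(expressed)]
    pd.Series(expressed, name="gene_id").to_csv(out / "expressed_genes.tsv", sep="\t", index=False)

    if stop_after == "filter":
        return finish()

    # normalize + VST
    stage("normalize")
    sub = counts.loc[expressed]
    sf = nde.size_factors(sub)
    # dispersion trend for the VST: one pooled group over all samples
    disp = nde.fit_dispersion(sub, sf, pd.Series(np.zeros(sub.shape[1]), index=sub.columns))
    vst = nde.vst(sub, sf, disp.trend_alpha)
    _write(sf.to_frame(), out / "size_factors.tsv", index_label="sample_id")
    _write(vst, out / "vst.tsv", index_label="gene_id")

    if stop_after == "normalize":
        return finish()

    # consensus clustering on expressed lncRNAs
    stage("cluster")
    lnc_vst = vst.loc[lnc_ids].T  # samples x lncRNA features
    if config.k_fixed is not None:
        k_star = config.k_fixed
        bic_table = None
    else:
        k_star, bic_table = cc.select_k(
            lnc_vst, range(config.k_range[0], config.k_range[1] + 1),
            config.n_runs, config.frac_samples, config.frac_features, config.seed,
        )
        _write(bic_table, out / "bic.tsv")
    cons = cc.run_consensus(lnc_vst, k_star, config.n_runs,
                            config.frac_samples, config.frac_features, config.seed)
    cons.validate()
    labels = cc.cluster_consensus(cons, k_star)
    _write(cons.M, out / "consensus_matrix.tsv", index_label="sample_id")
    _write(labels.to_frame(), out / "cluster_labels.tsv", index_label="sample_id")

    if stop_after == "cluster":
        return finish()

    # one-vs-rest subtype markers
    stage("markers")
    for c in sorted(labels.unique()):
        mk = nde.subtype_markers(sub, sf, labels, c, config.fc_min, config.fdr_max)
        _write(mk, out / f"markers_cluster{c}.tsv", index_label="gene_id")

    if stop_after == "markers":
        return finish()

    # lncRNA-mRNA association
    stage("associate")
    r = association.correlation_matrix(vst.loc[lnc_ids], vst.loc[mrna_ids])
    T = association.ternarize(r, config.ternary_tail)
    _write(T, out / "ternary_association.tsv", index_label="lnc_id")
    neighbors = gene_model.assign_neighbors(lnc, coding)
    _write(neighbors, out / "neighbors.tsv", index=False)
    cis = association.cis_report(neighbors, r)
    _write(cis, out / "cis_report.tsv", index=False)

    if stop_after == "associate":
        return finish()

    # per-lncRNA GSEA (optional: needs a GMT)
    if config.gmt:
        stage("gsea")
        sets = gsea.read_gmt(config.gmt)
        chosen = lnc_ids[: config.gsea_max_lnc] if config.gsea_max_lnc else lnc_ids
        ranked = {
            l: gsea.rank_by_phenotype(l, vst.loc[lnc_ids], vst.loc[mrna_ids]) for l in chosen
        }
        res = gsea.nes_fdr(ranked, sets, config.gsea_n_perm, config.gsea_weight,
                           config.seed, config.fdr_max)
        _write(res, out / "gsea_results.tsv", index=False)
        _write(gsea.ternary_nes_matrix(res), out / "gsea_ternary.tsv", index_label="lnc_id")

    if stop_after == "gsea":
        return finish()

    # chromatin annotation (optional: needs peak BEDs)
    if config.peak_beds:
        stage("chromatin")
        peaks = [chromatin.PeakSet.from_bed(path, *key.split(":", 1))
                 for key, path in sorted(config.peak_beds.items())]
        ann = chromatin.annotate_marks(genes, peaks, config.tss_window)
        flat = ann.copy()
        flat.columns = [f"{m}:{c}" for m, c in ann.columns]
        _write(flat, out / "mark_annotation.tsv", index_label="gene_id")
        ctx = config.contexts[0]
        summary = chromatin.expression_by_mark(fpkm.loc[fpkm.index.intersection(lnc_ids)], ann, ctx)
        _write(summary, out / f"expression_by_mark_{ctx}.tsv")

    if stop_after == "chromatin":
        return finish()

    # survival
    stage("survive")
    km = surv_mod.km_logrank(labels, clinical)
    screen = surv_mod.cox_screen(vst.loc[lnc_ids], clinical, config.fdr_max)
    _write(screen, out / "cox_screen.tsv")
    with open(out / "km_logrank.json", "w") as fh:
        json.dump({"statistic": km.statistic, "p_value": km.p_value}, fh, sort_keys=True)

    return finish()
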