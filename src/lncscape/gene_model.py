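"""Gene annotation model: GTF parsing, masked exonic lengths, neighbor genes.

Genes are modelled at gene level as the union of their exons (the analysis
quantifies genes, not transcripts). lncRNA/mRNA overlap masking removes, from
each gene's exonic length, every base shared with exons of the *other* class
(coding vs non-coding), strand-blind, because a non-strand-specific library
cannot attribute such bases to either gene.

Coordinates are internally 0-based half-open; GTF is read/written as 1-based
inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from gffutils.iterators import DataIterator

from .intervals import Interval, merge, subtract, total_length

logger = logging.getLogger(__name__)

#: lncRNA biotype categories recognised alongside protein_coding.
LNC_BIOTYPES = (
    "antisense",
    "lincRNA",
    "sense_overlapping",
    "sense_intronic",
    "processed_transcript",
    "three_prime_overlapping_ncRNA",
)
BIOTYPES = ("protein_coding",) + LNC_BIOTYPES


class AnnotationError(ValueError):
    """Raised for malformed annotation input."""


@dataclass
class GeneRecord:
    """One annotated gene with merged exon structure.

    exons are 0-based half-open, pairwise disjoint, sorted by start.
    The TSS is the strand-aware 5' end of the merged exon span.
    """

    gene_id: str
    gene_name: str
    biotype: str
    chrom: str
    strand: str
    exons: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = merge(self.exons)
        if not self.exons:
            raise AnnotationError(f"gene {self.gene_id} has no exons")
        if self.biotype not in BIOTYPES:
            raise AnnotationError(f"unknown biotype {self.biotype!r} for {self.gene_id}")
        if self.strand not in "+-":
            raise AnnotationError(f"bad strand {self.strand!r} for {self.gene_id}")

    @property
    def tss(self) -> int:
        return self.exons[0][0] if self.strand == "+" else self.exons[-1][1]

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def raw_length(self) -> int:
        return total_length(self.exons)

    @property
    def is_lncRNA(self) -> bool:
        return self.biotype != "protein_coding"


def load_annotation(gtf_path) -> list[GeneRecord]:
    """Parse a GENCODE-dialect GTF into one GeneRecord per gene_id.

    Exon features are pooled per gene and merged; 1-based inclusive GTF
    coordinates become 0-based half-open. Genes with an unrecognised biotype
    are skipped with a warning; a missing gene_id is an error.
    """
    raw: dict[str, dict] = {}
    for n, feat in enumerate(DataIterator(str(gtf_path)), start=1):
        if feat.featuretype != "exon":
            continue
        attrs = feat.attributes
        if "gene_id" not in attrs:
            raise AnnotationError(f"exon feature without gene_id at line {n} of {gtf_path}")
        gid = attrs["gene_id"][0]
        biotype = (attrs.get("gene_type") or attrs.get("gene_biotype") or [None])[0]
        name = (attrs.get("gene_name") or [gid])[0]
        rec = raw.setdefault(
            gid, {"name": name, "biotype": biotype, "chrom": feat.seqid, "strand": feat.strand, "exons": []}
        )
        rec["exons"].append((feat.start - 1, feat.end))  # GTF 1-based inclusive
    genes = []
    for gid, rec in raw.items():
        if rec["biotype"] not in BIOTYPES:
            logger.warning("skipping gene %s with unknown biotype %r", gid, rec["biotype"])
            continue
        genes.append(
            GeneRecord(gid, rec["name"], rec["biotype"], rec["chrom"], rec["strand"], rec["exons"])
        )
    return genes


def write_gtf(genes: list[GeneRecord], path) -> None:
    """Write one exon line per merged exon, GENCODE attribute dialect."""
    with open(path, "w") as fh:
        for g in genes:
            for s, e in g.exons:
                attrs = f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}"; gene_type "{g.biotype}";'
                fh.write(
                    f"{g.chrom}\tlncscape\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )


def masked_lengths(genes: list[GeneRecord]) -> pd.DataFrame:
    """Exonic length of every gene after masking cross-class overlap.

    For each gene, bases shared (strand-blind) with exons of any gene of the
    other class (coding vs lncRNA) are excluded. Returns a DataFrame indexed
    by gene_id with columns raw_length, masked_length. Genes with
    masked_length 0 are flagged with a warning (FPKM is undefined for them).
    """
    by_class_chrom: dict[tuple[bool, str], list[Interval]] = {}
    for g in genes:
        by_class_chrom.setdefault((g.is_lncRNA, g.chrom), []).extend(g.exons)
    rows = []
    for g in genes:
        other = merge(by_class_chrom.get((not g.is_lncRNA, g.chrom), []))
        masked = total_length(subtract(g.exons, other))
        rows.append((g.gene_id, g.raw_length, masked))
        if masked == 0:
            logger.warning("gene %s fully masked by cross-class overlap", g.gene_id)
    df = pd.DataFrame(rows, columns=["gene_id", "raw_length", "masked_length"])
    return df.set_index("gene_id")


def _basal_domain(g: GeneRecord, basal_up: int, basal_down: int) -> Interval:
    if g.strand == "+":
        return (g.tss - basal_up, g.tss + basal_down)
    return (g.tss - basal_down, g.tss + basal_up)


def regulatory_domains(
    coding: list[GeneRecord],
    basal_up: int = 5000,
    basal_down: int = 1000,
    max_extension: int = 1_000_000,
) -> pd.DataFrame:
    """Basal-plus-extension regulatory domains for coding genes.

    Each gene owns a strand-aware basal domain (basal_up upstream, basal_down
    downstream of the TSS). The domain then extends in both directions up to
    the nearest neighboring gene's basal domain, capped at max_extension from
    the TSS, never shrinking below the gene's own basal domain.
    """
    rows = []
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in coding:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, gs in by_chrom.items():
        basals = {g.gene_id: _basal_domain(g, basal_up, basal_down) for g in gs}
        for g in gs:
            bs, be = basals[g.gene_id]
            left_cands = [b[1] for gid, b in basals.items() if gid != g.gene_id and b[1] <= bs]
            right_cands = [b[0] for gid, b in basals.items() if gid != g.gene_id and b[0] >= be]
            ext_start = max([g.tss - max_extension] + left_cands)
            ext_end = min([g.tss + max_extension] + right_cands)
            rows.append((g.gene_id, chrom, ext_start, ext_end, bs, be))
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "basal_start", "basal_end"]
    ).set_index("gene_id")


def assign_neighbors(
    lnc: list[GeneRecord],
    coding: list[GeneRecord],
    basal_up: int = 5000,
    basal_down: int = 1000,
    max_extension: int = 1_000_000,
) -> pd.DataFrame:
    """Assign each lncRNA to coding genes whose regulatory domain holds its TSS.

    Returns columns lnc_gene_id, coding_gene_id, distance (lncRNA TSS minus
    coding TSS, so negative means the lncRNA lies upstream on the forward
    axis), rule ('basal' if the TSS falls inside the basal domain, else
    'extension'). Deterministic: sorted by (lnc_gene_id, coding_gene_id).
    """
    if not lnc or not coding:
        raise AnnotationError("both lncRNA and coding gene sets must be non-empty")
    doms = regulatory_domains(coding, basal_up, basal_down, max_extension)
    coding_by_id = {g.gene_id: g for g in coding}
    lnc_chroms = {g.chrom for g in lnc}
    for chrom in lnc_chroms.symmetric_difference({g.chrom for g in coding}):
        logger.warning("chromosome %s present in only one gene set; no assignments there", chrom)
    rows = []
    for l in lnc:
        sub = doms[doms["chrom"] == l.chrom]
        hit = sub[(sub["start"] <= l.tss) & (l.tss < sub["end"])]
        for gid, row in hit.iterrows():
            in_basal = row["basal_start"] <= l.tss < row["basal_end"]
            rows.append(
                (l.gene_id, gid, l.tss - coding_by_id[gid].tss, "basal" if in_basal else "extension")
            )
    df = pd.DataFrame(rows, columns=["lnc_gene_id", "coding_gene_id", "distance", "rule"])
    return df.sort_values(["lnc_gene_id", "coding_gene_id"], kind="stable").reset_index(drop=True)
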