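"""Fragment counting (union mode), FPKM, and the expressed-gene filter.

FPKM here is fragments per kilobase of *non-overlapped* exon per million
mapped fragments: gene lengths come from the cross-class overlap mask, and
union-mode counting discards any fragment touching exons of more than one
gene (in particular any fragment spanning an mRNA/lncRNA overlap).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .gene_model import GeneRecord

logger = logging.getLogger(__name__)


def union_count(
    fragments: list[tuple[str, int, int]], genes: list[GeneRecord]
) -> pd.Series:
    """Count fragments per gene in union mode.

    A fragment (chrom, start, end) is counted for gene g iff g is the *only*
    gene whose exons it overlaps; fragments hitting exons of two or more
    genes, or none, are discarded. Returns a Series indexed by gene_id in
    input gene order.
    """
    trees: dict[str, IntervalTree] = {}
    for gi, g in enumerate(genes):
        tree = trees.setdefault(g.chrom, IntervalTree())
        for s, e in g.exons:
            tree.addi(s, e, gi)
    counts = np.zeros(len(genes), dtype=int)
    for chrom, s, e in fragments:
        tree = trees.get(chrom)
        if tree is None:
            continue
        hits = {iv.data for iv in tree.overlap(s, e)}
        if len(hits) == 1:
            counts[hits.pop()] += 1
    return pd.Series(counts, index=[g.gene_id for g in genes], name="count")


def fpkm(counts: pd.DataFrame, lengths: pd.DataFrame) -> pd.DataFrame:
    """FPKM(g, s) = counts(g, s) * 1e9 / (masked_length(g) * total(s)).

    ``lengths`` is the masked-length table indexed by gene_id. Genes with
    masked_length 0 are dropped (FPKM undefined), with a warning. The
    per-sample total is the column sum of counted fragments.
    """
    ml = lengths["masked_length"].reindex(counts.index)
    if ml.isna().any():
        missing = list(counts.index[ml.isna()])[:5]
        raise KeyError(f"genes missing from length table, e.g. {missing}")
    keep = ml > 0
    if (~keep).any():
        logger.warning("dropping %d genes with masked_length 0 from FPKM", int((~keep).sum()))
    counts = counts.loc[keep]
    ml = ml.loc[keep]
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total counts: {list(zero.index)}")
    vals = counts.to_numpy(dtype=float) * 1e9 / np.outer(ml.to_numpy(dtype=float), totals.to_numpy(dtype=float))
    return pd.DataFrame(vals, index=counts.index, columns=counts.columns)


def filter_low_expression(
    expr: pd.DataFrame, min_value: float = 1.0, min_fraction: float = 0.10
) -> list[str]:
    """Genes with expression >= min_value in at least min_fraction of samples.

    The sample threshold is ceil(min_fraction * n_samples); both thresholds
    are inclusive. Gene order is preserved.
    """
    if expr.shape[1] == 0 or expr.shape[0] == 0:
        return []
    need = math.ceil(min_fraction * expr.shape[1])
    n_ok = (expr.to_numpy() >= min_value).sum(axis=1)
    return list(expr.index[n_ok >= need])
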