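"""Histone-mark integration: TSS-window annotation, bivalency, enhancers.

A gene is "marked" by a histone mark in a cell context when any ChIP-seq
peak for that mark overlaps the closed +/- 5 kb window around the gene's
TSS (any >= 1 bp overlap qualifies). Downstream calls: bivalent promoters
(H3K4me3 + H3K27me3), enhancer lncRNAs (H3K27ac, optionally + H3K4me2),
mark gain/loss between two contexts, and expression summaries by mark.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gene_model import GeneRecord

logger = logging.getLogger(__name__)

MARKS = ("H3K4me3", "H3K4me2", "H3K36me3", "H3K27ac", "H3K27me3", "H3K9me3")
ACTIVE_MARKS = ("H3K4me3", "H3K4me2", "H3K36me3", "H3K27ac")
REPRESSIVE_MARKS = ("H3K27me3", "H3K9me3")


@dataclass
class PeakSet:
    """ChIP-seq peaks for one mark in one cell context (0-based half-open)."""

    mark: str
    context: str
    intervals: dict[str, np.ndarray]  # chrom -> (n, 2) sorted array

    @classmethod
    def from_bed(cls, path, mark: str, context: str) -> "PeakSet":
        df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2], comment="#",
                         names=["chrom", "start", "end"])
        return cls.from_frame(df, mark, context)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, mark: str, context: str) -> "PeakSet":
        ivs = {
            str(chrom): np.asarray(sub[["start", "end"]].sort_values("start"), dtype=int)
            for chrom, sub in df.groupby("chrom")
        }
        return cls(mark, context, ivs)


def annotate_marks(
    genes: list[GeneRecord], peaks: list[PeakSet], window: int = 5000
) -> pd.DataFrame:
    """Boolean gene x (mark, context) table of TSS-window peak overlap.

    The window is the closed interval [tss - window, tss + window], i.e.
    half-open [tss - window, tss + window + 1). Genes on chromosomes absent
    from a peak set count as unmarked (logged).
    """
    cols = pd.MultiIndex.from_tuples(
        sorted({(p.mark, p.context) for p in peaks}), names=["mark", "context"]
    )
    out = pd.DataFrame(False, index=[g.gene_id for g in genes], columns=cols)
    for p in peaks:
        n_missing = 0
        marked = np.zeros(len(genes), dtype=bool)
        for i, g in enumerate(genes):
            ivs = p.intervals.get(g.chrom)
            if ivs is None:
                n_missing += 1
                continue
            lo, hi = g.tss - window, g.tss + window + 1
            marked[i] = bool(np.any((ivs[:, 0] < hi) & (ivs[:, 1] > lo)))
        if n_missing:
            logger.warning("%d genes on chromosomes absent from %s/%s peaks", n_missing, p.mark, p.context)
        out[(p.mark, p.context)] = marked
    return out


def bivalent(ann: pd.DataFrame, context: str) -> set[str]:
    """Genes carrying both H3K4me3 and H3K27me3 in the given context."""
    both = ann[("H3K4me3", context)] & ann[("H3K27me3", context)]
    return set(ann.index[both])


def enhancer_lncRNAs(
    ann: pd.DataFrame, contexts: list[str], stringent: bool = False
) -> set[str]:
    """Enhancer-associated genes by H3K27ac.

    Lax mode: H3K27ac in any of the given contexts. Stringent mode: both
    H3K27ac and H3K4me2 within a single context (any one of those given).
    """
    hit = pd.Series(False, index=ann.index)
    for ctx in contexts:
        if stringent:
            hit |= ann[("H3K27ac", ctx)] & ann[("H3K4me2", ctx)]
        else:
            hit |= ann[("H3K27ac", ctx)]
    return set(ann.index[hit])


def mark_change(
    ann: pd.DataFrame, mark: str, context_a: str, context_b: str
) -> tuple[set[str], set[str], set[str]]:
    """(lost, gained, retained) gene sets for one mark between two contexts."""
    a = ann[(mark, context_a)]
    b = ann[(mark, context_b)]
    lost = set(ann.index[a & ~b])
    gained = set(ann.index[~a & b])
    retained = set(ann.index[a & b])
    return lost, gained, retained


def expression_by_mark(
    expr: pd.DataFrame, ann: pd.DataFrame, context: str
) -> pd.DataFrame:
    """Distribution of per-gene median expression, grouped by each mark.

    Rows: marks present for the context; columns n, median, q25, q75 of the
    per-gene median expression over samples among marked genes.
    """
    med = expr.median(axis=1)
    rows = []
    for mark in MARKS:
        if (mark, context) not in ann.columns:
            continue
        genes = ann.index[ann[(mark, context)]].intersection(med.index)
        vals = med.loc[genes]
        rows.append(
            (
                mark,
                len(vals),
                float(vals.median()) if len(vals) else np.nan,
                float(vals.quantile(0.25)) if len(vals) else np.nan,
                float(vals.quantile(0.75)) if len(vals) else np.nan,
            )
        )
    return pd.DataFrame(rows, columns=["mark", "n", "median", "q25", "q75"]).set_index("mark")


def mark_group_test(
    expr: pd.DataFrame, ann: pd.DataFrame, context: str, mark_a: str, mark_b: str
) -> float:
    """Two-sided Wilcoxon rank-sum p between two marks' expression groups."""
    med = expr.median(axis=1)
    a = med.loc[ann.index[ann[(mark_a, context)]].intersection(med.index)]
    b = med.loc[ann.index[ann[(mark_b, context)]].intersection(med.index)]
    if len(a) == 0 or len(b) == 0:
        return float("nan")
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
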