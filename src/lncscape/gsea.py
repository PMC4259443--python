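"""Per-lncRNA gene-set enrichment with correlation-ranked phenotypes.

Each lncRNA expression profile serves as a continuous phenotype: mRNAs are
ranked by their Pearson correlation with it, and a weighted Kolmogorov-
Smirnov running statistic scores each gene set on that ranking. Significance
comes from gene-label permutations: null enrichment scores from random sets
of the same size give a sign-matched NES and a permutation p-value, BH-
adjusted across all (lncRNA, set) pairs, and the significant calls are
ternarized by NES sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import cluster_ternary
from .normalization_de import bh_adjust

logger = logging.getLogger(__name__)


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


@dataclass
class RankedList:
    """mRNAs sorted by descending correlation with one lncRNA phenotype."""

    phenotype: str
    genes: list[str]
    scores: np.ndarray


def rank_by_phenotype(
    lnc_id: str, lnc_expr: pd.DataFrame, mrna_expr: pd.DataFrame
) -> RankedList:
    """Rank mRNAs by Pearson r with the lncRNA profile (ties by gene id)."""
    prof = lnc_expr.loc[lnc_id].to_numpy(dtype=float)
    if lnc_expr.shape[1] < 3:
        raise ValueError("need at least 3 shared samples")
    if prof.std() == 0:
        raise ValueError(f"constant lncRNA profile {lnc_id}")
    x = mrna_expr.to_numpy(dtype=float)
    sd = x.std(axis=1)
    pz = (prof - prof.mean()) / prof.std()
    with np.errstate(invalid="ignore"):
        r = ((x - x.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1)[:, None] @ pz) / len(prof)
    r[sd == 0] = 0.0
    order = sorted(range(len(r)), key=lambda i: (-r[i], mrna_expr.index[i]))
    return RankedList(lnc_id, [mrna_expr.index[i] for i in order], np.asarray([r[i] for i in order]))


def enrichment_score(
    ranked: RankedList, gene_set, weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted-KS enrichment score and the full running sum.

    Hits increment by |r|^weight normalized over in-set hits; misses
    decrement by 1/(N - N_hit). The score is the running-sum extremum of
    largest magnitude, sign retained.
    """
    in_set = np.asarray([g in gene_set for g in ranked.genes])
    n_hit = int(in_set.sum())
    N = len(ranked.genes)
    if n_hit == 0:
        raise ValueError("gene set has no overlap with the ranked list")
    w = np.abs(ranked.scores) ** weight
    hit_w = np.where(in_set, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:  # all in-set scores exactly 0: fall back to unweighted hits
        hit_w = in_set.astype(float)
        denom = n_hit
    steps = hit_w / denom - (~in_set) * (1.0 / (N - n_hit) if N > n_hit else 0.0)
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), running


def _null_es(
    ranked: RankedList, set_size: int, n_perm: int, rng: np.random.Generator, weight: float
) -> np.ndarray:
    """Null ES values from random gene sets of the same size."""
    out = np.empty(n_perm)
    genes = ranked.genes
    for p in range(n_perm):
        idx = rng.choice(len(genes), size=set_size, replace=False)
        members = {genes[i] for i in idx}
        out[p], _ = enrichment_score(ranked, members, weight)
    return out


def nes_fdr(
    ranked_lists: dict[str, RankedList],
    gene_sets: dict[str, list[str]],
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """NES, permutation p, BH fdr and ternary call per (lncRNA, gene set).

    NES = es / mean(|null es| of matching sign); p is the sign-matched
    permutation tail (add-one). Pairs whose set does not intersect the
    ranked genes are excluded (logged). Ternary: 0 if fdr > fdr_max, else
    sign(NES).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rows = []
    for li, (lnc_id, ranked) in enumerate(ranked_lists.items()):
        universe = set(ranked.genes)
        rng = np.random.default_rng(seed + li)
        null_cache: dict[int, np.ndarray] = {}
        for set_id, members in gene_sets.items():
            overlap = universe.intersection(members)
            if not overlap:
                logger.warning("set %s has no overlap with ranking for %s; excluded", set_id, lnc_id)
                continue
            es, _ = enrichment_score(ranked, overlap, weight)
            size = len(overlap)
            if size not in null_cache:
                null_cache[size] = _null_es(ranked, size, n_perm, rng, weight)
            null = null_cache[size]
            same = null[np.sign(null) == np.sign(es)] if es != 0 else null
            if len(same) == 0:
                logger.warning("no matching-sign nulls for (%s, %s); NES undefined", lnc_id, set_id)
                rows.append((lnc_id, set_id, es, np.nan, 1.0))
                continue
            nes = es / np.mean(np.abs(same))
            p = (1 + int(np.sum(np.abs(same) >= abs(es)))) / (1 + len(same))
            rows.append((lnc_id, set_id, es, nes, p))
    res = pd.DataFrame(rows, columns=["lnc_id", "set_id", "es", "nes", "p_value"])
    res["fdr"] = bh_adjust(res["p_value"].to_numpy()) if len(res) else []
    res["ternary"] = np.where(res["fdr"] < fdr_max, np.sign(res["nes"]).fillna(0), 0).astype(int)
    return res


def ternary_nes_matrix(results: pd.DataFrame) -> pd.DataFrame:
    """Pivot nes_fdr results into a lncRNA x gene-set {-1,0,1} matrix."""
    return results.pivot(index="lnc_id", columns="set_id", values="ternary").fillna(0).astype(int)


def bicluster(
    T: pd.DataFrame, min_rows: int = 2, min_cols: int = 2
) -> tuple[list, list, list[dict]]:
    """Two-way clustering of a ternary matrix plus constant-sign blocks.

    Rows/columns are ordered by hierarchical clustering (Euclidean,
    complete). Blocks are maximal contiguous row-range x column subsets of
    the reordered matrix in which every entry has the same nonzero sign and
    spans at least min_rows x min_cols; row-dominated sub-blocks are pruned.
    """
    row_order, col_order = cluster_ternary(T)
    R = T.loc[row_order, col_order].to_numpy()
    blocks: list[dict] = []
    nr = len(row_order)
    for sign in (1, -1):
        B = R == sign
        found: list[tuple[int, int, tuple]] = []
        for i in range(nr):
            cols = B[i]
            for j in range(i, nr):
                cols = cols & B[j]
                if cols.sum() < min_cols:
                    break
                if j - i + 1 >= min_rows:
                    found.append((i, j, tuple(np.where(cols)[0])))
        # keep only blocks not strictly contained in another of same sign
        for i, j, cols in found:
            contained = any(
                (i >= i2 and j <= j2 and set(cols) <= set(c2)) and (i, j, cols) != (i2, j2, c2)
                for i2, j2, c2 in found
            )
            if not contained:
                blocks.append(
                    {
                        "sign": sign,
                        "rows": [row_order[r] for r in range(i, j + 1)],
                        "cols": [col_order[c] for c in cols],
                    }
                )
    return row_order, col_order, blocks


def neighbor_set_enrichment(
    neighbor_genes, gene_sets: dict[str, list[str]], universe
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of each set in the neighbor genes.

    p = P(X >= k) with k = |neighbors ∩ set|, drawing |neighbors| genes from
    a universe containing |set ∩ universe| successes. Sets disjoint from the
    universe are skipped; BH across the tested sets.
    """
    universe = set(universe)
    neigh = set(neighbor_genes) & universe
    if not set(neighbor_genes) <= set(universe):
        raise ValueError("universe must contain all neighbor genes")
    rows = []
    for set_id, members in gene_sets.items():
        in_univ = set(members) & universe
        if not in_univ:
            continue
        k = len(neigh & in_univ)
        p = float(stats.hypergeom.sf(k - 1, len(universe), len(in_univ), len(neigh)))
        rows.append((set_id, k, len(in_univ), min(1.0, p)))
    out = pd.DataFrame(rows, columns=["set_id", "n_overlap", "set_size", "p_value"])
    out["fdr"] = bh_adjust(out["p_value"].to_numpy()) if len(out) else []
    return out
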