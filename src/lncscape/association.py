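"""lncRNA-mRNA association: correlation matrix, ternarization, clustering.

Correlations are Pearson across samples on variance-stabilized expression.
Ternarization flags the globally most extreme 1% of entries per sign,
yielding a sparse {-1, 0, +1} association matrix that is then two-way
clustered (Euclidean, complete linkage) for visualization and block finding.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)


def correlation_matrix(lnc_expr: pd.DataFrame, mrna_expr: pd.DataFrame) -> pd.DataFrame:
    """Pearson r between every lncRNA row and every mRNA row.

    Both inputs are genes x samples over identical sample columns. Constant
    rows are dropped with a warning (r undefined).
    """
    if list(lnc_expr.columns) != list(mrna_expr.columns):
        raise ValueError("sample columns must match in identity and order")
    if lnc_expr.shape[1] < 3:
        raise ValueError("need at least 3 shared samples for correlation")
    def _drop_constant(df: pd.DataFrame, what: str) -> pd.DataFrame:
        sd = df.std(axis=1)
        if (sd == 0).any():
            logger.warning("dropping %d constant %s rows", int((sd == 0).sum()), what)
        return df[sd > 0]
    lnc_expr = _drop_constant(lnc_expr, "lncRNA")
    mrna_expr = _drop_constant(mrna_expr, "mRNA")
    a = lnc_expr.to_numpy(dtype=float)
    b = mrna_expr.to_numpy(dtype=float)
    az = (a - a.mean(axis=1, keepdims=True)) / a.std(axis=1, keepdims=True)
    bz = (b - b.mean(axis=1, keepdims=True)) / b.std(axis=1, keepdims=True)
    r = az @ bz.T / a.shape[1]
    return pd.DataFrame(np.clip(r, -1.0, 1.0), index=lnc_expr.index, columns=mrna_expr.index)


def ternarize(r: pd.DataFrame, tail: float = 0.01) -> pd.DataFrame:
    """Assign +1 to the floor(tail*N) largest entries, -1 to the smallest.

    N is the total entry count. Ties at a cutoff are broken by (row, column)
    index ascending. tail*N < 1 yields an all-zero matrix (logged).
    """
    x = r.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("non-finite correlation entries")
    N = x.size
    n_tail = int(np.floor(tail * N))
    T = np.zeros_like(x, dtype=int)
    if n_tail < 1:
        logger.warning("tail fraction %g selects no entries (N=%d); all-zero matrix", tail, N)
        return pd.DataFrame(T, index=r.index, columns=r.columns)
    flat = x.ravel()  # row-major: flat index orders by (row, col)
    desc = np.argsort(-flat, kind="stable")  # ties -> lower flat index first
    asc = np.argsort(flat, kind="stable")
    pos = desc[:n_tail]
    neg = [i for i in asc if i not in set(pos)][:n_tail]
    T.ravel()[pos] = 1
    T.ravel()[np.asarray(neg, dtype=int)] = -1
    return pd.DataFrame(T, index=r.index, columns=r.columns)


def cluster_ternary(T: pd.DataFrame) -> tuple[list, list]:
    """Leaf orders of independent row/column clustering (Euclidean, complete)."""
    def _order(df: pd.DataFrame) -> list:
        if len(df) < 2:
            return list(df.index)
        Z = linkage(pdist(df.to_numpy(dtype=float)), method="complete")
        return [df.index[i] for i in leaves_list(Z)]
    return _order(T), _order(T.T)


def cis_report(neighbors: pd.DataFrame, r: pd.DataFrame) -> pd.DataFrame:
    """Pearson r of every lncRNA-neighbor pair, sorted by |r| descending.

    ``neighbors`` needs lnc_gene_id / coding_gene_id columns; pairs missing
    from the correlation matrix are skipped with a warning.
    """
    rows = []
    n_skip = 0
    for _, row in neighbors.iterrows():
        l, c = row["lnc_gene_id"], row["coding_gene_id"]
        if l in r.index and c in r.columns:
            rows.append((l, c, float(r.at[l, c])))
        else:
            n_skip += 1
    if n_skip:
        logger.warning("skipped %d neighbor pairs absent from expression", n_skip)
    out = pd.DataFrame(rows, columns=["lnc_gene_id", "coding_gene_id", "r"])
    return out.reindex(out["r"].abs().sort_values(ascending=False, kind="stable").index).reset_index(
        drop=True
    )
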