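"""Resampled consensus clustering for subtype discovery.

Repeated hierarchical clustering (Pearson distance, Ward linkage) of
feature/sample-resampled expression; the consensus matrix averages the
co-clustering indicator over the runs in which a sample pair was co-sampled.
The consensus matrix is then itself clustered (rows as features, Euclidean,
Ward), and the number of clusters can be chosen by BIC over a range of k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)


def pearson_distance(matrix: np.ndarray) -> np.ndarray:
    """Condensed 1 - r distances between rows (samples) over columns (features)."""
    sd = matrix.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.where(sd == 0)[0][0])
        raise ValueError(f"constant sample vector at row {bad}; Pearson distance undefined")
    r = np.corrcoef(matrix)
    np.fill_diagonal(r, 1.0)
    return squareform(1.0 - r, checks=False)


def hcluster(
    matrix: pd.DataFrame, distance: str, linkage_method: str, k: int
) -> pd.Series:
    """Cut an agglomerative dendrogram of the samples into exactly k clusters.

    ``matrix`` is samples x features. distance: 'pearson' (1 - r) or
    'euclidean'; linkage: 'ward' or 'complete'. Ward on 1 - r distances uses
    the classical Lance-Williams update on squared distances.
    """
    if distance not in ("pearson", "euclidean"):
        raise ValueError(f"unknown distance {distance!r}")
    if linkage_method not in ("ward", "complete"):
        raise ValueError(f"unknown linkage {linkage_method!r}")
    x = matrix.to_numpy(dtype=float)
    if k < 1 or k > len(x):
        raise ValueError(f"k={k} out of range for {len(x)} samples")
    d = pearson_distance(x) if distance == "pearson" else pdist(x)
    Z = linkage(d, method=linkage_method)
    labels = fcluster(Z, t=k, criterion="maxclust")
    if len(np.unique(labels)) != k:
        # maxclust can return fewer clusters on exact-tie plateaus; force by
        # cutting at the (k-1)-th largest merge height
        heights = np.sort(Z[:, 2])
        labels = fcluster(Z, t=heights[-(k - 1)] - 1e-12, criterion="distance") if k > 1 else np.ones(len(x), int)
    return pd.Series(labels, index=matrix.index, name="cluster")


@dataclass
class ConsensusResult:
    """Consensus matrix M (samples x samples) plus co-sampling counts."""

    M: pd.DataFrame
    co_sampled: pd.DataFrame
    n_runs: int

    def validate(self) -> None:
        m = self.M.to_numpy()
        assert np.allclose(m, m.T), "consensus matrix not symmetric"
        assert np.allclose(np.diag(m), 1.0), "consensus diagonal != 1"
        assert m.min() >= 0 and m.max() <= 1 + 1e-12, "consensus outside [0,1]"


def run_consensus(
    matrix: pd.DataFrame,
    k: int,
    n_runs: int = 500,
    frac_samples: float = 0.8,
    frac_features: float = 0.8,
    seed: int = 0,
) -> ConsensusResult:
    """Consensus matrix from resampled hierarchical clustering runs.

    ``matrix`` is samples x features (variance-stabilized expression). Each
    run draws floor(frac * n) samples and features without replacement (run
    r uses RNG seed ``seed + r``), clusters with Pearson/Ward at the given k,
    and M(i, j) = co-clustered runs / co-sampled runs. Pairs never co-sampled
    get M = 0 (logged); the diagonal is forced to 1.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    n, m = matrix.shape
    ns, nf = int(np.floor(frac_samples * n)), int(np.floor(frac_features * m))
    x = matrix.to_numpy(dtype=float)
    co_clust = np.zeros((n, n))
    co_samp = np.zeros((n, n))
    for r in range(n_runs):
        rng = np.random.default_rng(seed + r)
        si = np.sort(rng.choice(n, size=ns, replace=False))
        fi = np.sort(rng.choice(m, size=nf, replace=False))
        sub = pd.DataFrame(x[np.ix_(si, fi)], index=matrix.index[si])
        labels = hcluster(sub, "pearson", "ward", k).to_numpy()
        same = labels[:, None] == labels[None, :]
        co_samp[np.ix_(si, si)] += 1
        co_clust[np.ix_(si, si)] += same
    never = (co_samp == 0) & ~np.eye(n, dtype=bool)
    if never.any():
        logger.warning("%d sample pairs never co-sampled; consensus set to 0", int(never.sum() // 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        M = np.where(co_samp > 0, co_clust / np.maximum(co_samp, 1), 0.0)
    np.fill_diagonal(M, 1.0)
    idx = matrix.index
    return ConsensusResult(
        pd.DataFrame(M, index=idx, columns=idx),
        pd.DataFrame(co_samp, index=idx, columns=idx),
        n_runs,
    )


def cluster_consensus(consensus: ConsensusResult | pd.DataFrame, k: int) -> pd.Series:
    """Cluster samples using consensus-matrix rows as feature vectors."""
    M = consensus.M if isinstance(consensus, ConsensusResult) else consensus
    return hcluster(M, "euclidean", "ward", k)


def _bic_hard_spherical(X: np.ndarray, labels: np.ndarray) -> tuple[float, bool]:
    """BIC of a hard-assignment spherical Gaussian mixture on rows of X.

    Parameters counted: k * d component means + 1 shared variance. Returns
    (bic, degenerate) where degenerate flags singleton clusters (pooled
    variance is used regardless, so the value stays finite).
    """
    n, d = X.shape
    ks = np.unique(labels)
    rss = 0.0
    degenerate = False
    for c in ks:
        sub = X[labels == c]
        if len(sub) < 2:
            degenerate = True
        rss += ((sub - sub.mean(axis=0)) ** 2).sum()
    sigma2 = max(rss / (n * d), 1e-12)
    loglik = -0.5 * n * d * (np.log(2 * np.pi * sigma2) + 1.0)
    n_par = len(ks) * d + 1
    return -2.0 * loglik + n_par * np.log(n), degenerate


def select_k(
    matrix: pd.DataFrame,
    k_range=range(2, 9),
    n_runs: int = 500,
    frac_samples: float = 0.8,
    frac_features: float = 0.8,
    seed: int = 0,
    bic_space: str = "expression",
) -> tuple[int, pd.DataFrame]:
    """Choose the cluster count by BIC under hard spherical-Gaussian mixtures.

    For each k, the full pipeline (run_consensus at that k, then
    cluster_consensus) yields labels; BIC scores those labels on the sample
    feature vectors. bic_space='expression' (default) scores every k in the
    common expression space, which keeps the per-k fits comparable;
    'consensus' scores each k on its own consensus-matrix rows. Returns
    (argmin-BIC k, table of k / bic / degenerate).
    """
    if bic_space not in ("expression", "consensus"):
        raise ValueError(f"unknown bic_space {bic_space!r}")
    rows = []
    for k in k_range:
        cons = run_consensus(matrix, k, n_runs, frac_samples, frac_features, seed)
        labels = cluster_consensus(cons, k)
        data = matrix.to_numpy(dtype=float) if bic_space == "expression" else cons.M.to_numpy()
        bic, degen = _bic_hard_spherical(data, labels.to_numpy())
        if degen:
            logger.warning("k=%d produced a singleton cluster; pooled-variance BIC", k)
        rows.append((k, bic, degen))
    table = pd.DataFrame(rows, columns=["k", "bic", "degenerate"]).set_index("k")
    return int(table["bic"].idxmin()), table
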