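"""Count normalization, dispersion, NB exact test, BH, subtype markers, VST.

The normalization follows the median-of-ratios scheme: each sample's size
factor is the median, over genes with a positive geometric mean, of that
sample's counts divided by the gene's geometric mean across samples.

Differential expression uses a conditional negative-binomial exact test:
given the total K = K_A + K_B of a gene's counts in two groups, the p-value
sums the probabilities of all splits (a, K - a) no more likely than the
observed one, under independent NB laws for the group sums whose means are
the pooled per-unit expression scaled by each group's size-factor sum and
whose variance uses the gene's working dispersion. Dispersions are per-gene
method-of-moments estimates combined with a parametric trend v(mu) = mu +
alpha * mu^2, taking the more conservative (larger) of the two.

The variance-stabilizing transform integrates 1 / sqrt(v(mu)) numerically
and is affine-calibrated to agree with log2 of normalized counts at the
high-count end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-8


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample.

    Genes with a zero geometric mean (any zero count, in particular) are
    skipped. Raises if no gene has a positive geometric mean.
    """
    x = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        loggm = np.mean(np.log(x), axis=1)  # -inf where any zero
    ok = np.isfinite(loggm)
    if not ok.any():
        raise ValueError("no gene with all-positive counts; size factors undefined")
    ratios = x[ok] / np.exp(loggm[ok])[:, None]
    return pd.Series(np.median(ratios, axis=0), index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame, sf: pd.Series) -> pd.DataFrame:
    """Divide each sample column by its size factor."""
    missing = [s for s in counts.columns if s not in sf.index]
    if missing:
        raise KeyError(f"samples missing from size factors: {missing[:5]}")
    return counts / sf.reindex(counts.columns)


@dataclass
class DispersionFit:
    """Per-gene working dispersions plus the fitted trend coefficient."""

    per_gene: pd.Series       # raw method-of-moments estimate (may be <= 0)
    trend_alpha: float        # alpha in v(mu) = mu + alpha mu^2
    working: pd.Series        # max(per-gene, trend), floored

    def alpha(self, gene: str) -> float:
        return float(self.working.loc[gene])


def fit_dispersion(
    counts: pd.DataFrame, sf: pd.Series, groups: pd.Series
) -> DispersionFit:
    """Method-of-moments dispersions pooled within groups, plus a trend.

    For each gene the within-group variance w of normalized counts is
    combined with the normalized mean mu via alpha_g = (w - z*mu) / mu^2,
    where z = mean(1/s_j) corrects for the shot-noise inflation of dividing
    by size factors. The trend alpha is the median of the positive per-gene
    estimates. Working dispersion = max(per-gene, trend) floored at 1e-8;
    all-zero genes get NaN (excluded from testing with p = 1).
    """
    groups = groups.reindex(counts.columns)
    if groups.isna().any():
        raise KeyError("every sample needs a group label")
    norm = normalize(counts, sf).to_numpy(dtype=float)
    sfv = sf.reindex(counts.columns).to_numpy(dtype=float)
    z = float(np.mean(1.0 / sfv))
    labels = groups.to_numpy()
    mu = norm.mean(axis=1)
    # pooled within-group variance
    ss = np.zeros(norm.shape[0])
    df = 0
    for lab in pd.unique(labels):
        sub = norm[:, labels == lab]
        if sub.shape[1] < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 samples")
        ss += sub.var(axis=1, ddof=1) * (sub.shape[1] - 1)
        df += sub.shape[1] - 1
    w = ss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_g = (w - z * mu) / mu**2
    alpha_g[mu == 0] = np.nan
    per_gene = pd.Series(alpha_g, index=counts.index, name="dispersion")
    pos = per_gene[per_gene > 0]
    trend = float(np.median(pos)) if len(pos) else DISPERSION_FLOOR
    working = np.maximum(np.nan_to_num(alpha_g, nan=-np.inf), trend)
    working = np.maximum(working, DISPERSION_FLOOR)
    working[np.isnan(alpha_g)] = np.nan
    return DispersionFit(per_gene, trend, pd.Series(working, index=counts.index))


def _nb_logpmf(k: np.ndarray, mean: float, var: float) -> np.ndarray:
    """NB log-pmf parameterized by mean and variance (Poisson if var <= mean)."""
    if var <= mean * (1 + 1e-12):
        return stats.poisson.logpmf(k, mean)
    r = mean**2 / (var - mean)
    p = r / (r + mean)
    return stats.nbinom.logpmf(k, r, p)


def nb_exact_test(k_a: int, k_b: int, sf_a, sf_b, alpha: float) -> float:
    """Conditional NB exact test for one gene.

    k_a, k_b: summed counts in the two groups; sf_a, sf_b: the size factors
    of each group's samples. The pooled per-unit mean q = K / sum(all sf)
    gives group-sum means q*sum(sf); the group-sum variance adds the
    per-sample NB overdispersion terms, m + alpha * q^2 * sum(sf^2). The
    p-value sums, over all K + 1 splits of K, the probabilities no larger
    than the observed split's, normalized over all splits. K = 0 returns 1.
    """
    sf_a = np.atleast_1d(np.asarray(sf_a, dtype=float))
    sf_b = np.atleast_1d(np.asarray(sf_b, dtype=float))
    K = int(k_a) + int(k_b)
    if K == 0:
        return 1.0
    q = K / (sf_a.sum() + sf_b.sum())
    ma, mb = q * sf_a.sum(), q * sf_b.sum()
    va = ma + alpha * q**2 * np.sum(sf_a**2)
    vb = mb + alpha * q**2 * np.sum(sf_b**2)
    a = np.arange(K + 1)
    lp = _nb_logpmf(a, ma, va) + _nb_logpmf(K - a, mb, vb)
    lobs = lp[int(k_a)]
    denom = logsumexp(lp)
    keep = lp <= lobs + 1e-10  # tolerate fp ties
    num = logsumexp(lp[keep])
    return float(min(1.0, np.exp(num - denom)))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR, order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def two_group_test(
    counts: pd.DataFrame,
    sf: pd.Series,
    groups: pd.Series,
    disp: DispersionFit | None = None,
) -> pd.DataFrame:
    """NB exact test per gene between exactly two groups.

    Returns a DataFrame indexed like counts with mean_norm_A, mean_norm_B,
    fold_change ((mean_A + 1)/(mean_B + 1)), p_value and BH fdr. All-zero
    genes get p = 1.
    """
    groups = groups.reindex(counts.columns)
    labs = pd.unique(groups.to_numpy())
    if len(labs) != 2:
        raise ValueError(f"exactly two groups required, got {list(labs)}")
    if disp is None:
        disp = fit_dispersion(counts, sf, groups)
    in_a = (groups == labs[0]).to_numpy()
    sfv = sf.reindex(counts.columns).to_numpy(dtype=float)
    sf_a, sf_b = sfv[in_a], sfv[~in_a]
    x = counts.to_numpy()
    norm = x / sfv
    mean_a = norm[:, in_a].mean(axis=1)
    mean_b = norm[:, ~in_a].mean(axis=1)
    pvals = np.ones(len(counts))
    alphas = disp.working.reindex(counts.index).to_numpy(dtype=float)
    for i in range(len(counts)):
        if np.isnan(alphas[i]):
            continue  # all-zero gene: p = 1
        pvals[i] = nb_exact_test(int(x[i, in_a].sum()), int(x[i, ~in_a].sum()), sf_a, sf_b, alphas[i])
    return pd.DataFrame(
        {
            "mean_norm_A": mean_a,
            "mean_norm_B": mean_b,
            "fold_change": (mean_a + 1.0) / (mean_b + 1.0),
            "p_value": pvals,
            "fdr": bh_adjust(pvals),
        },
        index=counts.index,
    )


def subtype_markers(
    counts: pd.DataFrame,
    sf: pd.Series,
    cluster_labels: pd.Series,
    target_cluster,
    fc_min: float = 2.0,
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """One-vs-rest marker genes for one cluster.

    Compares the target cluster against all other samples pooled; returns
    genes with fold_change >= fc_min (target over rest, pseudocount 1) and
    BH fdr < fdr_max, sorted by fdr ascending then fold_change descending.
    """
    cluster_labels = cluster_labels.reindex(counts.columns)
    if (cluster_labels == target_cluster).sum() < 2 or (cluster_labels != target_cluster).sum() < 2:
        raise ValueError("target cluster and rest each need >= 2 samples")
    onevs = pd.Series(
        np.where(cluster_labels == target_cluster, "target", "rest"), index=counts.columns
    )
    res = two_group_test(counts, sf, onevs)
    # labs order: first label seen in columns; make A = target explicitly
    if onevs.iloc[0] != "target":
        res = res.rename(columns={"mean_norm_A": "mean_norm_B", "mean_norm_B": "mean_norm_A"})
        res["fold_change"] = (res["mean_norm_A"] + 1.0) / (res["mean_norm_B"] + 1.0)
        res = res[["mean_norm_A", "mean_norm_B", "fold_change", "p_value", "fdr"]]
    hits = res[(res["fold_change"] >= fc_min) & (res["fdr"] < fdr_max)]
    return hits.sort_values(["fdr", "fold_change"], ascending=[True, False], kind="stable")


def vst(
    counts: pd.DataFrame, sf: pd.Series, trend_alpha: float, n_grid: int = 4096
) -> pd.DataFrame:
    """Variance-stabilizing transform of normalized counts.

    u(x) = integral_0^x dmu / sqrt(mu + alpha mu^2), evaluated by cumulative
    trapezoid on a dense grid, then affine-mapped so the transform agrees
    with log2(normalized count) at the 99th and 90th percentile of the
    normalized counts. alpha <= 0 falls back to 2*sqrt(x) (Poisson limit).
    """
    norm = normalize(counts, sf)
    x = norm.to_numpy(dtype=float)
    xmax = float(x.max())
    if trend_alpha <= 0:
        logger.warning("non-positive trend dispersion %g; Poisson-limit sqrt transform", trend_alpha)
        return 2.0 * np.sqrt(norm)
    # integrand ~ mu^-1/2 at 0: substitute mu = t^2, giving 2/sqrt(1+alpha t^2)
    t = np.linspace(0.0, np.sqrt(max(xmax, 1.0) * 1.01), n_grid)
    grid = t**2
    f = 2.0 / np.sqrt(1.0 + trend_alpha * t**2)
    cum = np.concatenate([[0.0], np.cumsum((f[1:] + f[:-1]) / 2.0 * np.diff(t))])
    u_of = lambda v: np.interp(v, grid, cum)  # noqa: E731
    hi = np.quantile(x, 0.99)
    lo = np.quantile(x, 0.90)
    if not (hi > lo > 0):
        pos = x[x > 0]
        hi = float(pos.max()) if len(pos) else 1.0
        lo = hi / 2.0
    a = (np.log2(hi) - np.log2(lo)) / (u_of(hi) - u_of(lo))
    b = np.log2(hi) - a * u_of(hi)
    return pd.DataFrame(a * u_of(x) + b, index=norm.index, columns=norm.columns)
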