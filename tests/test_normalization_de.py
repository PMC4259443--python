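"""Size factors, dispersion, NB exact test, BH, markers, VST."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import logsumexp

from lncscape.normalization_de import (
    bh_adjust,
    fit_dispersion,
    nb_exact_test,
    normalize,
    size_factors,
    subtype_markers,
    two_group_test,
    vst,
)


def nb_counts(rng, mean, alpha, size):
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mean), size=size)


class TestSizeFactors:
    def test_doubled_sample_gives_sqrt2_factors(self, rng):
        a = rng.integers(10, 100, size=20)
        counts = pd.DataFrame({"s1": a, "s2": 2 * a})
        sf = size_factors(counts)
        assert sf["s1"] == pytest.approx(1 / np.sqrt(2), rel=1e-12)
        assert sf["s2"] == pytest.approx(np.sqrt(2), rel=1e-12)

    def test_identical_samples_unit_factors(self, rng):
        a = rng.integers(1, 100, size=15)
        counts = pd.DataFrame({"s1": a, "s2": a, "s3": a})
        assert np.allclose(size_factors(counts), 1.0)

    def test_zero_gene_skipped_and_scalar_oracle(self, rng):
        counts = pd.DataFrame(rng.integers(0, 60, size=(40, 5)),
                              columns=[f"s{j}" for j in range(5)])
        counts.iloc[0] = [0, 5, 5, 5, 5]  # zero geometric mean: skipped
        sf = size_factors(counts)
        for j, s in enumerate(counts.columns):
            ratios = []
            for i in range(len(counts)):
                row = counts.iloc[i].to_numpy(dtype=float)
                gm = np.exp(np.mean(np.log(row))) if (row > 0).all() else 0.0
                if gm > 0:
                    ratios.append(counts.iloc[i, j] / gm)
            assert sf[s] == pytest.approx(np.median(sorted(ratios)), rel=1e-12)

    def test_all_zero_gene_matrix_errors(self):
        counts = pd.DataFrame({"s1": [0, 1], "s2": [2, 0]})
        with pytest.raises(ValueError):
            size_factors(counts)

    def test_gene_order_invariance(self, rng):
        counts = pd.DataFrame(rng.integers(1, 100, size=(30, 4)))
        perm = rng.permutation(30)
        assert np.allclose(size_factors(counts), size_factors(counts.iloc[perm]))


class TestNormalize:
    def test_scaled_samples_equal_after_normalization(self, rng):
        a = rng.integers(10, 100, size=20)
        counts = pd.DataFrame({"s1": a, "s2": 2 * a})
        norm = normalize(counts, size_factors(counts))
        assert np.allclose(norm["s1"], norm["s2"])
        # column medians of ratios to geometric means are ~1 after normalization
        gm = np.exp(np.mean(np.log(norm.to_numpy()), axis=1))
        assert np.allclose(np.median(norm.to_numpy() / gm[:, None], axis=0), 1.0)

    def test_missing_sample_errors(self, rng):
        counts = pd.DataFrame({"s1": [1, 2], "s2": [3, 4]})
        with pytest.raises(KeyError):
            normalize(counts, pd.Series({"s1": 1.0}))


class TestFitDispersion:
    def groups(self, n):
        return pd.Series(["a"] * (n // 2) + ["b"] * (n - n // 2),
                         index=[f"s{j}" for j in range(n)])

    def frame(self, x):
        return pd.DataFrame(x, columns=[f"s{j}" for j in range(x.shape[1])])

    def test_poisson_limit_small_trend(self, rng):
        counts = self.frame(rng.poisson(100, size=(300, 20)))
        fit = fit_dispersion(counts, pd.Series(1.0, index=counts.columns), self.groups(20))
        assert fit.trend_alpha <= 0.01

    def test_nb_dispersion_recovered(self, rng):
        counts = self.frame(nb_counts(rng, 100, 0.2, (200, 40)))
        fit = fit_dispersion(counts, pd.Series(1.0, index=counts.columns), self.groups(40))
        assert 0.1 <= fit.trend_alpha <= 0.4

    def test_constant_gene_floored_and_zero_gene_nan(self, rng):
        x = nb_counts(rng, 50, 0.2, (20, 10))
        x[0] = 7    # constant: MoM dispersion <= 0, floored to trend
        x[1] = 0    # all-zero: excluded from testing
        counts = self.frame(x)
        fit = fit_dispersion(counts, pd.Series(1.0, index=counts.columns), self.groups(10))
        assert fit.working.iloc[0] >= 1e-8
        assert np.isnan(fit.working.iloc[1])


def enumeration_oracle(k_a, k_b, sf_a, sf_b, alpha):
    """Independent scalar-loop enumeration of the conditional exact test."""
    K = k_a + k_b
    q = K / (sum(sf_a) + sum(sf_b))

    def logpmf(k, m, v):
        if v <= m:
            return stats.poisson.logpmf(k, m)
        r = m * m / (v - m)
        return stats.nbinom.logpmf(k, r, r / (r + m))

    ma, mb = q * sum(sf_a), q * sum(sf_b)
    va = ma + alpha * q * q * sum(s * s for s in sf_a)
    vb = mb + alpha * q * q * sum(s * s for s in sf_b)
    lp = [logpmf(a, ma, va) + logpmf(K - a, mb, vb) for a in range(K + 1)]
    obs = lp[k_a]
    num = logsumexp([v for v in lp if v <= obs + 1e-10])
    return float(np.exp(num - logsumexp(lp)))


class TestNbExactTest:
    def test_balanced_counts_p_one(self):
        assert nb_exact_test(20, 20, [1.0] * 5, [1.0] * 5, 0.1) == pytest.approx(1.0)

    def test_zero_total_p_one(self):
        assert nb_exact_test(0, 0, [1.0] * 5, [1.0] * 5, 0.1) == 1.0

    @pytest.mark.parametrize("ka,kb,sfa,sfb,alpha", [
        (3, 17, [1.0, 1.5, 2.5], [0.8, 1.2, 3.0], 0.1),
        (10, 40, [2.0, 2.0], [3.0, 3.0], 0.2),
        (0, 12, [1.5, 1.5], [1.0, 2.0], 0.05),
        (25, 25, [0.5, 1.5], [4.0, 4.0], 0.3),
        (1, 1, [1.0], [1.0], 0.5),
    ])
    def test_matches_enumeration_oracle(self, ka, kb, sfa, sfb, alpha):
        assert nb_exact_test(ka, kb, sfa, sfb, alpha) == pytest.approx(
            enumeration_oracle(ka, kb, sfa, sfb, alpha), rel=1e-9)

    def test_group_swap_symmetry(self):
        for ka, kb in [(3, 30), (8, 2), (0, 9)]:
            assert nb_exact_test(ka, kb, [2.0, 3.0], [3.5, 3.5], 0.15) == pytest.approx(
                nb_exact_test(kb, ka, [3.5, 3.5], [2.0, 3.0], 0.15), rel=1e-9)

    def test_null_type_i_error_within_binomial_interval(self, rng):
        """Same NB law in both groups: P(p <= 0.05) compatible with 0.05."""
        n_genes, n_per = 1000, 30
        means = rng.uniform(50, 500, size=n_genes)
        x = nb_counts(rng, means[:, None], 0.15, (n_genes, 2 * n_per))
        counts = pd.DataFrame(x, columns=[f"s{j}" for j in range(2 * n_per)])
        groups = pd.Series(["a"] * n_per + ["b"] * n_per, index=counts.columns)
        sf = size_factors(counts)
        res = two_group_test(counts, sf, groups)
        hits = int((res["p_value"] <= 0.05).sum())
        lo, hi = stats.binom.interval(0.95, n_genes, 0.05)
        assert lo <= hits <= hi, f"type-I hits {hits} outside [{lo}, {hi}]"


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_and_ties(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])
        assert np.allclose(bh_adjust([0.3, 0.3, 0.3]), [0.3] * 3)

    def test_permutation_invariance(self, rng):
        p = rng.uniform(size=25)
        perm = rng.permutation(25)
        q = bh_adjust(p)
        qp = bh_adjust(p[perm])
        assert np.allclose(q[perm], qp)
        assert (q >= p - 1e-15).all()


class TestSubtypeMarkers:
    def make_cohort(self, rng, n_up=20, n_null=200, n_per=25, fold=4.0):
        n = 4 * n_per
        labels = pd.Series(np.repeat([0, 1, 2, 3], n_per),
                           index=[f"s{j}" for j in range(n)])
        means = np.full((n_up + n_null, n), 100.0)
        means[:n_up, labels.to_numpy() == 1] *= fold
        x = nb_counts(rng, means, 0.15, means.shape)
        counts = pd.DataFrame(x, index=[f"G{i}" for i in range(n_up + n_null)],
                              columns=labels.index)
        return counts, labels

    def test_planted_marker_recovery(self, rng):
        counts, labels = self.make_cohort(rng)
        sf = size_factors(counts)
        res = subtype_markers(counts, sf, labels, 1)
        planted = {f"G{i}" for i in range(20)}
        assert len(planted & set(res.index)) >= 18
        assert len(set(res.index) - planted) <= 3

    def test_identical_groups_empty(self, rng):
        counts, labels = self.make_cohort(rng, n_up=0, n_null=60)
        res = subtype_markers(counts, size_factors(counts), labels, 2)
        assert len(res) == 0

    def test_infinite_fc_threshold_empty(self, rng):
        counts, labels = self.make_cohort(rng)
        res = subtype_markers(counts, size_factors(counts), labels, 1, fc_min=np.inf)
        assert len(res) == 0

    def test_small_cluster_errors(self, rng):
        counts, _ = self.make_cohort(rng, n_up=0, n_null=10, n_per=2)
        labels = pd.Series([0] + [1] * 7, index=counts.columns)
        with pytest.raises(ValueError):
            subtype_markers(counts, size_factors(counts), labels, 0)


class TestVst:
    def test_matches_asinh_closed_form(self, rng):
        counts = pd.DataFrame(nb_counts(rng, 200, 0.1, (100, 10)),
                              columns=[f"s{j}" for j in range(10)])
        sf = pd.Series(1.0, index=counts.columns)
        alpha = 0.1
        out = vst(counts, sf, alpha)
        x = counts.to_numpy(dtype=float)
        u = 2.0 / np.sqrt(alpha) * np.arcsinh(np.sqrt(alpha * x))
        hi, lo = np.quantile(x, 0.99), np.quantile(x, 0.90)
        uhi = 2.0 / np.sqrt(alpha) * np.arcsinh(np.sqrt(alpha * hi))
        ulo = 2.0 / np.sqrt(alpha) * np.arcsinh(np.sqrt(alpha * lo))
        a = (np.log2(hi) - np.log2(lo)) / (uhi - ulo)
        b = np.log2(hi) - a * uhi
        assert np.allclose(out.to_numpy(), a * u + b, atol=2e-3)

    def test_poisson_fallback_is_sqrt(self, rng):
        counts = pd.DataFrame(rng.poisson(50, size=(20, 5)),
                              columns=[f"s{j}" for j in range(5)])
        sf = pd.Series(1.0, index=counts.columns)
        out = vst(counts, sf, 0.0)
        assert np.allclose(out.to_numpy(), 2.0 * np.sqrt(counts.to_numpy()))

    def test_monotone(self, rng):
        counts = pd.DataFrame({"s1": np.arange(1, 200, 3), "s2": np.arange(2, 201, 3)})
        out = vst(counts, pd.Series(1.0, index=counts.columns), 0.2)
        flat_in = counts.to_numpy().ravel()
        flat_out = out.to_numpy().ravel()
        order = np.argsort(flat_in)
        assert (np.diff(flat_out[order]) >= -1e-12).all()

    def test_variance_flattening_across_mean_range(self, rng):
        """NB means spanning 10..1e4: per-gene VST SDs within 2x of each other."""
        means = np.geomspace(10, 1e4, 40)
        counts = pd.DataFrame(nb_counts(rng, means[:, None], 0.1, (40, 200)),
                              columns=[f"s{j}" for j in range(200)])
        sf = pd.Series(1.0, index=counts.columns)
        out = vst(counts, sf, 0.1)
        sds = out.std(axis=1)
        assert sds.max() / sds.min() < 2.0
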