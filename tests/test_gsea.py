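"""Weighted-KS enrichment, permutation NES/FDR, biclustering, hypergeometric."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lncscape.gsea import (
    RankedList,
    bicluster,
    enrichment_score,
    neighbor_set_enrichment,
    nes_fdr,
    rank_by_phenotype,
    read_gmt,
    ternary_nes_matrix,
)


def make_ranked(rng, n=50, name="L0"):
    scores = np.sort(rng.uniform(-1, 1, size=n))[::-1]
    return RankedList(name, [f"M{i:03d}" for i in range(n)], scores)


class TestRankByPhenotype:
    def frame(self, x, prefix):
        return pd.DataFrame(x, index=[f"{prefix}{i}" for i in range(x.shape[0])],
                            columns=[f"s{j}" for j in range(x.shape[1])])

    def test_identical_and_flipped_profiles_at_extremes(self, rng):
        prof = rng.normal(size=12)
        lnc = self.frame(prof[None, :], "L")
        mrna = self.frame(np.vstack([rng.normal(size=(5, 12)), prof, -prof]), "M")
        ranked = rank_by_phenotype("L0", lnc, mrna)
        assert ranked.genes[0] == "M5" and ranked.scores[0] == pytest.approx(1.0)
        assert ranked.genes[-1] == "M6" and ranked.scores[-1] == pytest.approx(-1.0)

    def test_order_matches_scalar_oracle(self, rng):
        lnc = self.frame(rng.normal(size=(1, 20)), "L")
        mrna = self.frame(rng.normal(size=(15, 20)), "M")
        ranked = rank_by_phenotype("L0", lnc, mrna)
        oracle = {}
        for g in mrna.index:
            oracle[g] = stats.pearsonr(lnc.iloc[0], mrna.loc[g]).statistic
        want = sorted(mrna.index, key=lambda g: (-oracle[g], g))
        assert ranked.genes == want

    def test_constant_profile_errors(self):
        lnc = self.frame(np.full((1, 8), 2.0), "L")
        mrna = self.frame(np.random.default_rng(0).normal(size=(3, 8)), "M")
        with pytest.raises(ValueError):
            rank_by_phenotype("L0", lnc, mrna)


def stepwise_oracle(ranked, members, p):
    """Literal step-by-step running sum, recomputed independently."""
    hits = [g in members for g in ranked.genes]
    nh = sum(hits)
    N = len(ranked.genes)
    denom = sum(abs(s) ** p for s, h in zip(ranked.scores, hits) if h)
    run, best = 0.0, 0.0
    track = []
    for s, h in zip(ranked.scores, hits):
        if h:
            run += abs(s) ** p / denom
        else:
            run -= 1.0 / (N - nh)
        track.append(run)
        if abs(run) > abs(best):
            best = run
    return best, track


class TestEnrichmentScore:
    def test_single_member_at_top_unweighted(self, rng):
        ranked = make_ranked(rng)
        es, _ = enrichment_score(ranked, {ranked.genes[0]}, weight=0)
        assert es == pytest.approx(1.0)

    def test_full_set_no_misses(self, rng):
        ranked = make_ranked(rng, n=20)
        es, run = enrichment_score(ranked, set(ranked.genes), weight=1)
        w = np.abs(ranked.scores)
        want = np.max(np.cumsum(w / w.sum()))
        assert es == pytest.approx(want)

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("p", [0, 1, 2])
    def test_matches_stepwise_oracle(self, seed, p):
        rng = np.random.default_rng(seed)
        ranked = make_ranked(rng)
        members = set(rng.choice(ranked.genes, size=5, replace=False))
        es, run = enrichment_score(ranked, members, weight=p)
        want, track = stepwise_oracle(ranked, members, p)
        assert es == pytest.approx(want, abs=1e-12)
        assert np.allclose(run, track)

    def test_reversed_list_negates_es_unweighted(self, rng):
        ranked = make_ranked(rng)
        members = set(rng.choice(ranked.genes, size=6, replace=False))
        es, _ = enrichment_score(ranked, members, weight=0)
        rev = RankedList("L0", ranked.genes[::-1], -ranked.scores[::-1])
        es_rev, _ = enrichment_score(rev, members, weight=0)
        assert es_rev == pytest.approx(-es, abs=1e-12)

    def test_empty_intersection_errors(self, rng):
        ranked = make_ranked(rng)
        with pytest.raises(ValueError):
            enrichment_score(ranked, {"NOPE"})


class TestNesFdr:
    def expr_pair(self, rng, n_mrna=80, n_samples=60, planted=0):
        """lncRNA phenotype plus mRNAs; first `planted` mRNAs correlated."""
        prof = rng.normal(size=n_samples)
        x = rng.normal(size=(n_mrna, n_samples))
        x[:planted] = 0.8 * prof + 0.4 * x[:planted]
        lnc = pd.DataFrame(prof[None, :], index=["L0"],
                           columns=[f"s{j}" for j in range(n_samples)])
        mrna = pd.DataFrame(x, index=[f"M{i:03d}" for i in range(n_mrna)],
                            columns=lnc.columns)
        return lnc, mrna

    def test_null_ternary_rate_bounded(self, rng):
        lnc, mrna = self.expr_pair(rng)
        ranked = {"L0": rank_by_phenotype("L0", lnc, mrna)}
        sets = {f"set{i}": list(rng.choice(mrna.index, size=10, replace=False))
                for i in range(40)}
        res = nes_fdr(ranked, sets, n_perm=200, seed=5)
        rate = (res["ternary"] != 0).mean()
        assert rate <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / 40)

    def test_planted_set_called_positive(self, rng):
        lnc, mrna = self.expr_pair(rng, planted=12)
        ranked = {"L0": rank_by_phenotype("L0", lnc, mrna)}
        sets = {"planted": [f"M{i:03d}" for i in range(12)],
                **{f"null{i}": list(rng.choice(mrna.index[20:], size=10, replace=False))
                   for i in range(10)}}
        res = nes_fdr(ranked, sets, n_perm=1000, seed=7).set_index("set_id")
        assert res.loc["planted", "ternary"] == 1
        assert res.loc["planted", "nes"] > 1

    def test_zero_permutations_error(self, rng):
        lnc, mrna = self.expr_pair(rng)
        ranked = {"L0": rank_by_phenotype("L0", lnc, mrna)}
        with pytest.raises(ValueError):
            nes_fdr(ranked, {"s": list(mrna.index[:5])}, n_perm=0)

    def test_ternary_rule(self, rng):
        lnc, mrna = self.expr_pair(rng, planted=12)
        ranked = {"L0": rank_by_phenotype("L0", lnc, mrna)}
        sets = {"planted": [f"M{i:03d}" for i in range(12)]}
        res = nes_fdr(ranked, sets, n_perm=500, seed=3)
        row = res.iloc[0]
        want = 0 if row["fdr"] > 0.05 else int(np.sign(row["nes"]))
        assert row["ternary"] == want


class TestBicluster:
    def test_planted_block_recovered(self, rng):
        T = pd.DataFrame(0, index=[f"L{i}" for i in range(20)],
                         columns=[f"S{j}" for j in range(15)])
        rows = [f"L{i}" for i in range(5, 15)]
        cols = [f"S{j}" for j in range(3, 8)]
        T.loc[rows, cols] = 1
        # sprinkle noise outside the block
        for _ in range(10):
            i, j = rng.integers(0, 20), rng.integers(0, 15)
            if f"L{i}" not in rows or f"S{j}" not in cols:
                T.iloc[i, j] = -1
        ro, co, blocks = bicluster(T, min_rows=4, min_cols=4)
        best = max((b for b in blocks if b["sign"] == 1),
                   key=lambda b: len(b["rows"]) * len(b["cols"]))
        assert set(best["rows"]) == set(rows)
        assert set(best["cols"]) == set(cols)

    def test_all_zero_no_blocks(self):
        T = pd.DataFrame(0, index=list("abcd"), columns=list("wxyz"))
        ro, co, blocks = bicluster(T)
        assert blocks == []

    def test_transposed_blocks(self, rng):
        T = pd.DataFrame(0, index=[f"L{i}" for i in range(8)],
                         columns=[f"S{j}" for j in range(8)])
        T.iloc[0:3, 0:3] = -1
        _, _, blocks = bicluster(T, min_rows=2, min_cols=2)
        _, _, blocks_t = bicluster(T.T, min_rows=2, min_cols=2)
        a = {(frozenset(b["rows"]), frozenset(b["cols"])) for b in blocks}
        b = {(frozenset(b["cols"]), frozenset(b["rows"])) for b in blocks_t}
        assert a == b


class TestNeighborSetEnrichment:
    def test_closed_form_five_choose_case(self):
        # universe of 10, set of 5, neighbors = the whole set:
        # p = P(X >= 5) = C(5,5)*C(5,0)/C(10,5) = 1/252
        universe = [f"g{i}" for i in range(10)]
        sets = {"s": universe[:5]}
        res = neighbor_set_enrichment(universe[:5], sets, universe)
        assert res.iloc[0]["p_value"] == pytest.approx(1 / 252)

    def test_empty_neighbors_p_one(self):
        universe = [f"g{i}" for i in range(8)]
        res = neighbor_set_enrichment([], {"s": universe[:3]}, universe)
        assert res.iloc[0]["p_value"] == pytest.approx(1.0)

    def test_set_equals_universe_p_one(self):
        universe = [f"g{i}" for i in range(6)]
        res = neighbor_set_enrichment(universe[:2], {"s": universe}, universe)
        assert res.iloc[0]["p_value"] == pytest.approx(1.0)


def test_read_gmt_and_ternary_matrix(tmp_path):
    p = tmp_path / "sets.gmt"
    p.write_text("setA\tdesc\tg1\tg2\tg3\nsetB\turl\tg4\n")
    sets = read_gmt(p)
    assert sets == {"setA": ["g1", "g2", "g3"], "setB": ["g4"]}
    res = pd.DataFrame({"lnc_id": ["L0", "L0"], "set_id": ["setA", "setB"],
                        "ternary": [1, -1]})
    M = ternary_nes_matrix(res)
    assert M.loc["L0", "setA"] == 1 and M.loc["L0", "setB"] == -1
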