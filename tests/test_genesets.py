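import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from plastevol.de import DEResult
from plastevol.genesets import (
    assimilation_accounting,
    binomial_proportion_test,
    call_assimilation,
    call_cec,
    call_dp,
    compare_similarity,
    fc_similarity,
    fisher_overlap,
)
from plastevol.io import PlastevolError


def _de(contrast, sig, direction, lfc=None, genes=None):
    genes = genes or [f"g{i}" for i in range(len(sig))]
    lfc = lfc if lfc is not None else [d if d == d else 0.0 for d in direction]
    table = pd.DataFrame(
        {
            "lfc_raw": lfc,
            "lfc_shrunk": lfc,
            "se": 0.1,
            "pvalue": 0.01,
            "padj": [0.01 if s else 0.5 for s in sig],
            "significant": sig,
            "direction": direction,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return DEResult(contrast, table, 0.05)


class TestCallCEC:
    def test_direction_rule(self):
        a = _de("T1vS1_C", [True, True, True, False], [1, 1, -1, 1])
        b = _de("T2vS2_C", [True, True, True, True], [1, -1, -1, 1])
        got = call_cec(a, b)
        # same direction both pairs -> in; discordant or non-significant -> out
        assert got.tolist() == [True, False, True, False]

    def test_universe_mismatch_rejected(self):
        a = _de("T1vS1_C", [True], [1], genes=["g1"])
        b = _de("T2vS2_C", [True], [1], genes=["g2"])
        with pytest.raises(PlastevolError, match="universes differ"):
            call_cec(a, b)


class TestCallDP:
    def _tables(self, sig_t1, sig_t2, eco):
        t1 = _de("CvZ_T1", sig_t1, [1] * 4)
        t2 = _de("CvZ_T2", sig_t2, [1] * 4)
        eco_tabs = [_de(f"eco{i}", flags, [1] * 4) for i, flags in enumerate(eco)]
        return t1, t2, eco_tabs

    def test_membership_requirements(self):
        # gene0: everything -> member; gene1: responsive in T1 only -> out;
        # gene2: no ecotype DE in pair 2 -> out; gene3: ecotype DE via zinc -> in
        t1, t2, eco = self._tables(
            sig_t1=[True, True, True, True],
            sig_t2=[True, False, True, True],
            eco=[
                [True, False, True, False],   # pair1 control
                [False, False, False, True],  # pair1 zinc
                [True, False, False, True],   # pair2 control
                [False, False, False, False], # pair2 zinc
            ],
        )
        got = call_dp(t1, t2, *eco)
        assert got.tolist() == [True, False, False, True]

    def test_opposite_zinc_responses_excluded(self):
        t1 = _de("CvZ_T1", [True], [1])
        t2 = _de("CvZ_T2", [True], [-1])
        eco = [_de(f"e{i}", [True], [1]) for i in range(4)]
        assert not call_dp(t1, t2, *eco).iloc[0]


class TestFisherOverlap:
    def test_independence_shaped_table(self):
        s = fisher_overlap(10, 20, 20, 40)
        assert s.sample_odds_ratio == pytest.approx(1.0)
        assert s.p_one_sided >= 0.5

    def test_negative_cell_rejected(self):
        with pytest.raises(PlastevolError):
            fisher_overlap(30, 20, 25, 100)

    def test_tail_matches_enumeration_small_universes(self):
        """Hypergeometric upper tail vs. exhaustive enumeration, N <= 30."""
        for N, K, n in [(10, 4, 5), (20, 8, 6), (30, 12, 10), (25, 5, 5)]:
            for a in range(0, min(K, n) + 1):
                expected = sum(
                    math.comb(K, k) * math.comb(N - K, n - k)
                    for k in range(a, min(K, n) + 1)
                ) / math.comb(N, n)
                got = fisher_overlap(a, K, n, N).p_one_sided
                assert got == pytest.approx(expected, rel=1e-10)

    def test_tail_monotone_in_overlap(self):
        ps = [fisher_overlap(a, 20, 25, 200).p_one_sided for a in range(3, 15)]
        assert all(x > y for x, y in zip(ps, ps[1:]))


class TestBinomialTest:
    def test_central_value_gives_one(self):
        assert binomial_proportion_test(5, 10, 0.5) == pytest.approx(1.0)

    def test_extreme_value_enumeration(self):
        assert binomial_proportion_test(10, 10, 0.5) == pytest.approx(2 / 1024)

    def test_matches_minlike_enumeration(self):
        """Two-sided = sum of outcome probabilities <= P(observed), n <= 10."""
        for n in range(1, 11):
            for p0 in (0.037, 0.2, 0.5, 0.8):
                pmf = [stats.binom.pmf(i, n, p0) for i in range(n + 1)]
                for k in range(n + 1):
                    expected = sum(p for p in pmf if p <= pmf[k] * (1 + 1e-10))
                    got = binomial_proportion_test(k, n, p0)
                    assert got == pytest.approx(min(1.0, expected), rel=1e-8)

    def test_degenerate_reference_rejected(self):
        with pytest.raises(PlastevolError):
            binomial_proportion_test(3, 10, 0.0)
        with pytest.raises(PlastevolError):
            binomial_proportion_test(3, 10, 1.0)


def _wilcoxon_oracle(x, y):
    """Exhaustive sign-flip null for the paired signed-rank test (no ties)."""
    d = np.asarray(x, float) - np.asarray(y, float)
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = [
        np.sum(ranks[np.array(signs)]) for signs in
        itertools.product([False, True], repeat=n)
    ]
    ws = np.array(ws)
    p_le = np.mean(ws <= w_obs)
    p_ge = np.mean(ws >= w_obs)
    return min(1.0, 2 * min(p_le, p_ge))


class TestSimilarity:
    def test_identical_groups_give_zero_median(self):
        de = _de("T1vT2_Z", [False] * 4, [np.nan] * 4, lfc=[0.0] * 4)
        stat = fc_similarity(de, de.gene_ids)
        assert stat.median == 0.0

    def test_absolute_value_symmetry(self):
        de_pos = _de("T1vT2_Z", [True] * 3, [1, 1, 1], lfc=[0.5, 1.0, 2.0])
        de_neg = _de("T2vT1_Z", [True] * 3, [-1, -1, -1], lfc=[-0.5, -1.0, -2.0])
        a = fc_similarity(de_pos, de_pos.gene_ids)
        b = fc_similarity(de_neg, de_neg.gene_ids)
        assert a.median == b.median

    def test_empty_gene_set_rejected(self):
        de = _de("T1vT2_Z", [True], [1])
        with pytest.raises(PlastevolError, match="empty"):
            fc_similarity(de, [])

    def test_wilcoxon_matches_sign_flip_oracle(self):
        rng = np.random.default_rng(3)
        for n in (4, 5, 6, 7, 8):
            x = rng.normal(0.3, 1, n)
            y = rng.normal(0.0, 1, n)
            # regenerate until tie-free in |d| and no zero differences
            while len(set(np.abs(x - y))) < n or np.any(x == y):
                x = rng.normal(0.3, 1, n)
            genes = [f"g{i}" for i in range(n)]
            a = fc_similarity(_de("a", [True] * n, [1] * n, lfc=x, genes=genes), genes)
            b = fc_similarity(_de("b", [True] * n, [1] * n, lfc=y, genes=genes), genes)
            got = compare_similarity(a, b)["pvalue"]
            # |FC| values here are positive so abs() is the identity
            assert got == pytest.approx(_wilcoxon_oracle(np.abs(x), np.abs(y)), rel=1e-8)


class TestAssimilation:
    def test_summary_arithmetic(self):
        s = assimilation_accounting(400, 310, 114, 69)
        assert s["n_assimilated"] == 183
        assert round(s["pct_of_cec"]) == 46

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(PlastevolError):
            assimilation_accounting(400, 310, 250, 69)

    def _fixture(self, responsive_t1, category, sub_pc=True, sub_ec=True):
        genes = ["g1"]
        gene_sets = pd.DataFrame({"is_cec": [True]}, index=genes)
        de_t1 = _de("CvZ_T1", [responsive_t1], [1], genes=genes)
        de_t2 = _de("CvZ_T2", [False], [np.nan], genes=genes)
        profiles = pd.DataFrame(
            {"substantial_PC": [sub_pc], "substantial_EC": [sub_ec]}, index=genes
        )
        calls = pd.DataFrame({"category": [category]}, index=genes)
        return call_assimilation(gene_sets, de_t1, de_t2, profiles, calls)

    def test_zinc_responsive_gene_not_canalized(self):
        table, _ = self._fixture(responsive_t1=True, category="reinforcement")
        assert not table["canalized"].iloc[0]

    def test_reversion_with_substantial_ec_not_assimilated(self):
        table, _ = self._fixture(responsive_t1=False, category="reversion")
        assert table["canalized"].iloc[0]
        assert not table["assimilated"].iloc[0]

    def test_no_residual_ec_is_assimilated(self):
        table, _ = self._fixture(responsive_t1=False, category="unclassified", sub_ec=False)
        assert table["assimilated"].iloc[0]

    def test_beneficial_plasticity_is_assimilated(self):
        table, _ = self._fixture(responsive_t1=False, category="reinforcement")
        assert table["assimilated"].iloc[0]

    def test_subset_chain_on_fitted_results(self, strong_sim_fit):
        _, res = strong_sim_fit
        g = res.gene_sets
        assert (g["assimilated"] <= g["canalized"]).all()
        assert (g["canalized"] <= g["is_cec"]).all()
        assert res.assimilation["n_assimilated"] == int(g["assimilated"].sum())
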