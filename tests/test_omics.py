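"""Tests for transcriptomic scoring, enrichment and calibration."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mpskit import omics
from mpskit.errors import InputError
from mpskit.fixtures import ExprSpec, gen_expression


def deg_table(rows):
    return pd.DataFrame(rows, columns=["gene", "log2fc", "p", "fdr"])


@pytest.fixture(scope="module")
def big_table():
    rng = np.random.default_rng(0)
    n = 1000
    return deg_table(
        {
            "gene": [f"g{i:04d}" for i in range(n)],
            "log2fc": rng.normal(0, 2, n),
            "p": rng.uniform(0, 1, n),
            "fdr": rng.uniform(0, 1, n),
        }
    )


class TestRankTopGenes:

    def test_returns_300_of_1000(self, big_table):
        assert len(omics.rank_top_genes(big_table, n=300)) == 300

    def test_n_larger_than_table(self):
        t = deg_table({"gene": ["a", "b"], "log2fc": [1, 2], "p": [0.5, 0.1], "fdr": [1, 1]})
        assert omics.rank_top_genes(t, n=300) == ["b", "a"]

    def test_tiebreak_by_abs_log2fc(self):
        t = deg_table(
            {"gene": ["small", "big"], "log2fc": [1.0, -3.0], "p": [0.01, 0.01], "fdr": [1, 1]}
        )
        # brute-force oracle: equal p, |log2fc| 3 beats 1
        assert omics.rank_top_genes(t, n=2) == ["big", "small"]

    def test_permutation_stable(self, big_table):
        base = omics.rank_top_genes(big_table, n=100)
        shuffled = big_table.sample(frac=1.0, random_state=7).reset_index(drop=True)
        assert omics.rank_top_genes(shuffled, n=100) == base


class TestConcordance:
    def test_nine_of_twelve_is_75_percent(self):
        genes = [f"m{i}" for i in range(12)]
        # brute-force construction: 9 below alpha, 3 above
        t = deg_table(
            {
                "gene": genes,
                "log2fc": [1.0] * 12,
                "p": [0.001] * 9 + [0.5] * 3,
                "fdr": [0.01] * 9 + [0.5] * 3,
            }
        )
        ref = omics.MarkerSet(name="set", members={g: 1 for g in genes})
        res = omics.concordance(t, ref)
        assert res.n_measured == 12
        assert res.n_de == 9
        assert res.pct_overlap == pytest.approx(75.0)

    def test_all_matching_signs_100_percent(self):
        t = deg_table(
            {"gene": ["a", "b"], "log2fc": [2.0, -1.0], "p": [0.001, 0.001], "fdr": [0.01, 0.01]}
        )
        ref = omics.MarkerSet(name="s", members={"a": 1, "b": -1})
        res = omics.concordance(t, ref)
        assert res.pct_overlap == 100.0
        assert res.pct_directional == 100.0

    def test_wrong_sign_in_de_not_directional(self):
        t = deg_table({"gene": ["a"], "log2fc": [-2.0], "p": [0.001], "fdr": [0.01]})
        res = omics.concordance(t, omics.MarkerSet(name="s", members={"a": 1}))
        assert res.n_de == 1
        assert res.n_directional == 0

    def test_direction_zero_counts_when_de(self):
        t = deg_table({"gene": ["a"], "log2fc": [-2.0], "p": [0.001], "fdr": [0.01]})
        res = omics.concordance(t, omics.MarkerSet(name="s", members={"a": 0}))
        assert res.n_directional == 1

    def test_absent_reference_flagged(self):
        t = deg_table({"gene": ["x"], "log2fc": [1.0], "p": [0.5], "fdr": [0.5]})
        res = omics.concordance(t, omics.MarkerSet(name="s", members={"absent": 1}))
        assert res.undefined
        assert res.pct_overlap is None

    def test_counts_match_brute_force_on_random_fixture(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(200)]
        t = deg_table(
            {
                "gene": genes,
                "log2fc": rng.normal(0, 1, 200),
                "p": rng.uniform(0, 1, 200),
                "fdr": rng.uniform(0, 1, 200),
            }
        )
        members = {g: int(rng.choice([-1, 0, 1])) for g in rng.choice(genes, 50, replace=False)}
        res = omics.concordance(t, omics.MarkerSet(name="s", members=members), alpha=0.3)
        # independent brute force over the joined table
        joined = t.set_index("gene")
        n_de = n_dir = 0
        for g, d in members.items():
            if joined.loc[g, "fdr"] < 0.3:
                n_de += 1
                if d == 0 or math.copysign(1, joined.loc[g, "log2fc"]) == d:
                    n_dir += 1
        assert (res.n_de, res.n_directional) == (n_de, n_dir)


def hypergeom_tail_brute_force(k, N, K, n):
    """P(X >= k) by exhaustive enumeration for small N."""
    total = 0.0
    for x in range(k, min(K, n) + 1):
        total += math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
    return total


class TestEnrich:
    def test_p_matches_brute_force_tail(self):
        universe = [f"u{i}" for i in range(20)]
        gene_set = set(universe[:5])
        query = universe[:4] + [universe[10]]
        (row,) = omics.enrich(query, {"term": gene_set}, universe)
        assert row.k == 4
        assert row.p == pytest.approx(hypergeom_tail_brute_force(4, 20, 5, 5), rel=1e-9)

    @pytest.mark.parametrize("N,K,n", [(10, 3, 4), (25, 10, 8), (15, 7, 7)])
    def test_brute_force_equivalence_small_universes(self, N, K, n):
        universe = [f"u{i}" for i in range(N)]
        gene_set = set(universe[:K])
        query = universe[N - n:]
        (row,) = omics.enrich(query, {"t": gene_set}, universe)
        assert row.p == pytest.approx(
            hypergeom_tail_brute_force(row.k, N, K, n), rel=1e-9
        )

    def test_zero_overlap_p_is_one(self):
        universe = [f"u{i}" for i in range(20)]
        (row,) = omics.enrich(universe[10:12], {"t": set(universe[:5])}, universe)
        assert row.k == 0
        assert row.p == pytest.approx(1.0)

    def test_single_set_bonferroni_identity(self):
        universe = [f"u{i}" for i in range(20)]
        (row,) = omics.enrich(universe[:4], {"t": set(universe[:5])}, universe)
        assert row.p_adj == pytest.approx(row.p)

    def test_bonferroni_multiplier(self):
        universe = [f"u{i}" for i in range(20)]
        sets = {"a": set(universe[:5]), "b": set(universe[5:10]), "c": set(universe[10:15])}
        rows = omics.enrich(universe[:4], sets, universe)
        for row in rows:
            assert row.p_adj == pytest.approx(min(1.0, 3 * row.p))

    def test_empty_universe_rejected(self):
        with pytest.raises(InputError, match="universe"):
            omics.enrich(["a"], {"t": {"a"}}, [])


class TestCompareClusters:
    UNIVERSE = [f"u{i}" for i in range(100)]
    COLLECTION = {"setA": set(UNIVERSE[:10]), "setB": set(UNIVERSE[10:20])}

    def test_random_list_produces_no_rows(self):
        rng = np.random.default_rng(11)
        random_list = list(rng.choice(self.UNIVERSE, 10, replace=False))
        # seeded draw chosen to be unenriched; p_adj stays above the cut
        out = omics.compare_clusters(
            {"cond": random_list}, self.COLLECTION, self.UNIVERSE, p_cut=0.01
        )
        assert out.empty

    def test_perfect_overlap_retained(self):
        out = omics.compare_clusters(
            {"cond": list(self.COLLECTION["setA"])}, self.COLLECTION, self.UNIVERSE
        )
        row = out[out.term == "setA"].iloc[0]
        assert row.gene_ratio == pytest.approx(1.0)
        assert row.condition == "cond"

    def test_shared_term_appears_under_both_conditions(self):
        lists = {
            "c1": list(self.COLLECTION["setA"]),
            "c2": list(self.COLLECTION["setA"])[:8],
        }
        out = omics.compare_clusters(lists, self.COLLECTION, self.UNIVERSE)
        assert set(out[out.term == "setA"].condition) == {"c1", "c2"}


class TestZScoreMatrix:
    def test_simple_row(self):
        values = pd.DataFrame([[1.0, 2.0, 3.0]], index=["r"], columns=["a", "b", "c"])
        zm = omics.zscore_matrix(values)
        np.testing.assert_allclose(zm.z.loc["r"], [-1.0, 0.0, 1.0])

    def test_constant_row_zeros_flagged(self):
        values = pd.DataFrame([[5.0, 5.0, 5.0]], index=["r"], columns=list("abc"))
        zm = omics.zscore_matrix(values)
        np.testing.assert_allclose(zm.z.loc["r"], 0.0)
        assert zm.degenerate_rows == ["r"]

    def test_complete_rows_mean0_sd1(self):
        rng = np.random.default_rng(3)
        values = pd.DataFrame(rng.normal(size=(10, 6)))
        zm = omics.zscore_matrix(values)
        for _, row in zm.z.iterrows():
            assert abs(row.mean()) < 1e-12
            assert abs(row.std(ddof=1) - 1.0) < 1e-12

    def test_masked_cells_excluded_and_stay_masked(self):
        values = pd.DataFrame([[1.0, 2.0, 3.0, 99.0]], index=["r"], columns=list("abcd"))
        mask = pd.DataFrame([[True, True, True, False]], index=["r"], columns=list("abcd"))
        zm = omics.zscore_matrix(values, mask)
        np.testing.assert_allclose(zm.z.loc["r", ["a", "b", "c"]], [-1.0, 0.0, 1.0])
        assert not zm.mask.loc["r", "d"]

    def test_under_two_values_row_masked(self):
        values = pd.DataFrame([[1.0, 2.0]], index=["r"], columns=["a", "b"])
        mask = pd.DataFrame([[True, False]], index=["r"], columns=["a", "b"])
        zm = omics.zscore_matrix(values, mask)
        assert zm.masked_rows == ["r"]
        assert not zm.mask.loc["r"].any()


class TestSimpleDE:
    def test_null_calibration(self):
        m, _ = gen_expression(ExprSpec(n_genes=1000, residual_sd=0.5, seed=13))
        groups = {c: c.rsplit("_", 1)[0] for c in m.columns}
        deg = omics.simple_de(m, groups)
        assert (deg.p < 0.05).mean() == pytest.approx(0.05, abs=0.025)
        assert deg.significant.sum() <= 2

    def test_power_on_planted_effect(self):
        spec = ExprSpec(
            n_genes=500, n_reps_per_group=5, residual_sd=0.2,
            de_genes={"g001": 2.0, "g002": -2.0}, seed=17,
        )
        m, _ = gen_expression(spec)
        deg = omics.simple_de(m, {c: c.rsplit("_", 1)[0] for c in m.columns})
        hits = set(deg[deg.significant].gene)
        assert {"g001", "g002"} <= hits
        assert deg.set_index("gene").loc["g001", "log2fc"] == pytest.approx(2.0, abs=0.5)

    def test_bh_hand_computation(self):
        # oracle: BH on (0.01, 0.02, 0.03, 0.5) -> (0.04, 0.04, 0.04, 0.5)
        from statsmodels.stats.multitest import multipletests

        _, adj, _, _ = multipletests([0.01, 0.02, 0.03, 0.5], method="fdr_bh")
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.5])

    def test_more_than_two_groups_rejected(self):
        m, _ = gen_expression(ExprSpec(n_genes=10, groups=("a", "b", "c"), seed=0))
        with pytest.raises(InputError, match="two groups"):
            omics.simple_de(m, {c: c.rsplit("_", 1)[0] for c in m.columns})


class TestSimulateBatchError:
    def test_zero_noise_zero_error(self):
        res = omics.simulate_batch_error(n_genes=100, batch_sd=0.0, residual_sd=0.0, seed=0)
        assert res.mean_error_rate_pct == 0.0

    def test_null_calibration_at_alpha(self):
        res = omics.simulate_batch_error(
            n_genes=10000, batch_sd=0.0, residual_sd=1.0, alpha=0.05, seed=1
        )
        # Monte-Carlo CI: 10000 genes x 20 repeats of an exact 5% test
        n_draws = 10000 * 20
        ci = 3.0 * math.sqrt(0.05 * 0.95 / n_draws) * 100
        assert abs(res.mean_error_rate_pct - 5.0) < ci

    def test_monotone_in_confounded_batch_sd(self):
        rates = [
            omics.simulate_batch_error(
                n_genes=2000, batch_sd=b, residual_sd=0.5, design="confounded", seed=3
            ).mean_error_rate_pct
            for b in (0.0, 0.25, 0.5, 1.0)
        ]
        assert rates == sorted(rates)

    def test_error_rates_bounded(self):
        res = omics.simulate_batch_error(n_genes=200, batch_sd=0.2, residual_sd=0.5, seed=4)
        assert 0.0 <= res.median_error_rate_pct <= 100.0
        assert res.error_rates.shape == (200,)


@given(st.integers(min_value=0, max_value=5))
@settings(max_examples=10, deadline=None)
def test_rank_total_order_under_shuffle(seed):
    rng = np.random.default_rng(42)
    t = deg_table(
        {
            "gene": [f"g{i}" for i in range(30)],
            "log2fc": rng.normal(size=30),
            "p": np.round(rng.uniform(size=30), 2),   # forces p ties
            "fdr": rng.uniform(size=30),
        }
    )
    base = omics.rank_top_genes(t, n=30)
    shuffled = t.sample(frac=1.0, random_state=seed).reset_index(drop=True)
    assert omics.rank_top_genes(shuffled, n=30) == base
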