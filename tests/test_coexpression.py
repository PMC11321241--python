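"""Co-expression network construction: variance filter, PCC ranking,
thresholding, seed-edge retention and network assembly."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, given, settings, strategies as st

import stemwalk as sw


def _expr(values, biotypes, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return sw.ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        biotype=dict(zip(genes, biotypes)),
    )


class TestVarianceFilter:
    def test_bottom_quartile_gene_removed(self):
        rows = [
            [1.0, 1.0, 1.0, 1.0],  # variance 0
            [0.0, 1.0, 1.0, 2.0],
            [0.0, 1.0, 2.0, 3.0],
            [0.0, 2.0, 3.0, 5.0],
        ]
        expr = _expr(rows, ["PCG"] * 4)
        out = sw.filter_low_variance(expr, 0.25)
        assert out.gene_ids == ["g1", "g2", "g3"]

    def test_drop_fraction_zero_is_identity(self, random_expr):
        out = sw.filter_low_variance(random_expr, 0.0)
        assert out.gene_ids == random_expr.gene_ids

    def test_hundred_distinct_variances_keep_75(self):
        # brute-force oracle: sort variances, drop the lowest quarter
        rng = np.random.default_rng(0)
        scales = rng.permutation(np.linspace(0.5, 10, 100))
        values = scales[:, None] * rng.standard_normal((100, 50))
        expr = _expr(values, ["PCG"] * 100)
        variances = np.var(values, axis=1, ddof=1)
        expected = {expr.gene_ids[i] for i in np.argsort(variances)[25:]}
        out = sw.filter_low_variance(expr, 0.25)
        assert out.values.shape[0] == 75
        assert set(out.gene_ids) == expected

    def test_all_dropped_is_an_error(self):
        expr = _expr([[1, 1, 1], [2, 2, 2]], ["PCG", "PCG"])
        with pytest.raises(ValueError, match="every gene"):
            sw.filter_low_variance(expr, 0.5)


class TestComputePairs:
    def test_single_pair_categories(self):
        rng = np.random.default_rng(1)
        values = rng.standard_normal((3, 10))
        expr = _expr(values, ["PCG", "PCG", "lncRNA"])
        ranked = sw.compute_pairs(expr)
        assert len(ranked.pairs["PCG-PCG"]) == 1
        assert ranked.pairs["PCG-PCG"]["rank"].iloc[0] == 1
        assert len(ranked.pairs["PCG-lncRNA"]) == 2

    def test_mirna_pairs_ranked_most_negative_first(self):
        # construct three miRNA-PCG pairs with PCCs around -0.8, +0.9, -0.1
        rng = np.random.default_rng(2)
        z = rng.standard_normal(500)
        p = z
        m1 = -0.8 * z + 0.6 * rng.standard_normal(500)
        m2 = 0.9 * z + math.sqrt(1 - 0.81) * rng.standard_normal(500)
        m3 = -0.1 * z + math.sqrt(1 - 0.01) * rng.standard_normal(500)
        expr = _expr(
            np.vstack([p, m1, m2, m3]),
            ["PCG", "miRNA", "miRNA", "miRNA"],
            genes=["p", "m1", "m2", "m3"],
        )
        df = sw.compute_pairs(expr).pairs["miRNA-PCG"]
        by_gene = {
            row.gene_a if row.gene_a != "p" else row.gene_b: row.rank
            for row in df.itertuples()
        }
        assert by_gene == {"m1": 1, "m3": 2, "m2": 3}

    def test_pcc_matches_textbook_formula(self, random_expr):
        # independent oracle: explicit covariance/sd quotient per pair
        ranked = sw.compute_pairs(random_expr)
        vals = random_expr.values

        def pcc(a, b):
            x, y = vals.loc[a].to_numpy(), vals.loc[b].to_numpy()
            xc, yc = x - x.mean(), y - y.mean()
            return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))

        checked = 0
        for df in ranked.pairs.values():
            for row in df.itertuples():
                assert row.pcc == pytest.approx(pcc(row.gene_a, row.gene_b), abs=1e-12)
                checked += 1
        assert checked == ranked.n_pairs() > 0

    def test_pair_category_counts_match_combinatorics(self, random_expr):
        # 10 PCG-like (8 PCG + 2 TF), 5 lncRNA, 5 miRNA
        ranked = sw.compute_pairs(random_expr)
        assert len(ranked.pairs["PCG-PCG"]) == 45
        assert len(ranked.pairs["PCG-lncRNA"]) == 50
        assert len(ranked.pairs["miRNA-PCG"]) == 50
        assert len(ranked.pairs["miRNA-lncRNA"]) == 25

    def test_each_unordered_pair_appears_once(self, random_expr):
        ranked = sw.compute_pairs(random_expr)
        for df in ranked.pairs.values():
            keys = [frozenset((a, b)) for a, b in zip(df["gene_a"], df["gene_b"])]
            assert len(keys) == len(set(keys))

    def test_zero_variance_gene_is_an_error(self):
        expr = _expr([[1, 1, 1, 1], [0, 1, 2, 3]], ["PCG", "PCG"])
        with pytest.raises(ValueError, match="zero-variance"):
            sw.compute_pairs(expr)


class TestThreshold:
    def test_one_percent_of_thousand_is_ten(self):
        df = pd.DataFrame(
            {
                "gene_a": [f"a{i}" for i in range(1000)],
                "gene_b": [f"b{i}" for i in range(1000)],
                "pcc": np.linspace(1, 0, 1000),
                "rank": np.arange(1, 1001),
            }
        )
        ranked = sw.RankedPairSet(pairs={"PCG-PCG": df})
        out = sw.threshold_pairs(ranked, 1)
        assert len(out.pairs["PCG-PCG"]) == 10

    def test_hundred_percent_is_identity(self, random_expr):
        ranked = sw.compute_pairs(random_expr)
        out = sw.threshold_pairs(ranked, 100)
        assert out.n_pairs() == ranked.n_pairs()

    def test_ceiling_convention_on_seven_pairs(self):
        df = pd.DataFrame(
            {
                "gene_a": [f"a{i}" for i in range(7)],
                "gene_b": [f"b{i}" for i in range(7)],
                "pcc": np.linspace(1, 0.4, 7),
                "rank": np.arange(1, 8),
            }
        )
        ranked = sw.RankedPairSet(pairs={"PCG-PCG": df})
        assert len(sw.threshold_pairs(ranked, 20).pairs["PCG-PCG"]) == math.ceil(1.4)

    @pytest.mark.parametrize("cutoff", [0, -1, 101])
    def test_out_of_range_cutoff_rejected(self, random_expr, cutoff):
        ranked = sw.compute_pairs(random_expr)
        with pytest.raises(ValueError):
            sw.threshold_pairs(ranked, cutoff)

    def test_nesting_across_the_five_cutoffs(self, random_expr):
        ranked = sw.compute_pairs(random_expr)
        cutoffs = [0.1, 1, 5, 10, 20]
        sets = [sw.threshold_pairs(ranked, c).unordered_pairs() for c in cutoffs]
        for smaller, larger in zip(sets, sets[1:]):
            assert smaller <= larger
        counts = [len(s) for s in sets]
        assert counts == sorted(counts)


class TestRetainSeedEdges:
    def test_definition(self):
        df = pd.DataFrame(
            {
                "gene_a": ["s1", "x", "s2"],
                "gene_b": ["x", "y", "s3"],
                "pcc": [0.9, 0.8, 0.7],
                "rank": [1, 2, 3],
            }
        )
        ranked = sw.RankedPairSet(pairs={"PCG-PCG": df})
        out = sw.retain_seed_edges(ranked, sw.SeedSet.of(["s1", "s2", "s3"]))
        kept = set(zip(out.pairs["PCG-PCG"]["gene_a"], out.pairs["PCG-PCG"]["gene_b"]))
        assert kept == {("s1", "x"), ("s2", "s3")}

    def test_disjoint_seed_set_warns_and_empties(self, random_expr):
        ranked = sw.compute_pairs(random_expr)
        with pytest.warns(UserWarning, match="seed"):
            out = sw.retain_seed_edges(ranked, sw.SeedSet.of(["absent"]))
        assert out.n_pairs() == 0

    # the fixture is deterministic and read-only, so sharing it across
    # generated inputs is safe
    @settings(
        max_examples=30,
        derandomize=True,
        suppress_health_check=[HealthCheck.function_scoped_fixture],
    )
    @given(st.sets(st.sampled_from([f"g{i:02d}" for i in range(20)]), min_size=1))
    def test_matches_brute_force_membership_filter(self, random_expr, seed_ids):
        ranked = sw.compute_pairs(random_expr)
        out = sw.retain_seed_edges(ranked, sw.SeedSet.of(seed_ids))
        for cat, df in ranked.pairs.items():
            expected = {
                (a, b)
                for a, b in zip(df["gene_a"], df["gene_b"])
                if a in seed_ids or b in seed_ids
            }
            got = set(zip(out.pairs[cat]["gene_a"], out.pairs[cat]["gene_b"]))
            assert got == expected


class TestBuildNetwork:
    def test_counts(self):
        df = pd.DataFrame(
            {
                "gene_a": ["a", "b", "c"],
                "gene_b": ["b", "c", "d"],
                "pcc": [0.9, 0.8, 0.7],
                "rank": [1, 2, 3],
            }
        )
        net = sw.build_network(sw.RankedPairSet(pairs={"PCG-PCG": df}))
        assert net.number_of_nodes() == 4
        assert net.number_of_edges() == 3

    def test_duplicate_pair_merges_category_labels(self):
        d1 = pd.DataFrame({"gene_a": ["a"], "gene_b": ["b"], "pcc": [0.9], "rank": [1]})
        d2 = pd.DataFrame({"gene_a": ["a"], "gene_b": ["b"], "pcc": [0.9], "rank": [1]})
        net = sw.build_network(
            sw.RankedPairSet(pairs={"PCG-PCG": d1, "PCG-lncRNA": d2})
        )
        assert net.number_of_edges() == 1
        assert set(net.edges["a", "b"]["categories"]) == {"PCG-PCG", "PCG-lncRNA"}

    def test_node_set_is_union_of_endpoints(self, random_expr):
        ranked = sw.threshold_pairs(sw.compute_pairs(random_expr), 10)
        net = sw.build_network(ranked)
        expected = set()
        for df in ranked.pairs.values():
            expected |= set(df["gene_a"]) | set(df["gene_b"])
        assert set(net.nodes) == expected
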