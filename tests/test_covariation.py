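"""Quantile co-variation selection, gene mapping, hypergeometric enrichment."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from methmark.annotation import GeneModel
from methmark.covariation import (
    geneset_enrichment,
    hypergeom_tail,
    map_to_genes,
    overlap_enrichment,
    select_covariation,
)


def dmr_frame(cls, d2, d3, chrom="chr1"):
    n = len(d2)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(n) * 1000,
            "end": np.arange(n) * 1000 + 500,
            "dmr_class": cls,
            "H3K4me2": d2,
            "H3K4me3": d3,
        }
    )


def brute_force_select(df):
    um = df[df["dmr_class"] == "UM"]
    mu = df[df["dmr_class"] == "MU"]
    sel1 = [
        i
        for i in um.index
        if um.loc[i, "H3K4me2"] < np.quantile(um["H3K4me2"], 0.75)
        and um.loc[i, "H3K4me3"] < np.quantile(um["H3K4me3"], 0.75)
    ]
    sel2 = [
        i
        for i in mu.index
        if mu.loc[i, "H3K4me2"] > np.quantile(mu["H3K4me2"], 0.25)
        and mu.loc[i, "H3K4me3"] > np.quantile(mu["H3K4me3"], 0.25)
    ]
    return set(sel1), set(sel2)


class TestSelection:
    def test_hand_quantile_example(self):
        # deltas (-3,-2,-1,0): Q3 = -0.75 by linear interpolation; three pass
        df = dmr_frame("UM", [-3, -2, -1, 0], [-3, -2, -1, 0])
        sel = select_covariation(df)
        assert len(sel.covar1) == 3
        assert sel.covar1["H3K4me2"].max() == -1

    def test_identical_deltas_select_none(self):
        df = dmr_frame("UM", [1.0] * 5, [1.0] * 5)
        assert len(select_covariation(df).covar1) == 0

    def test_empty_class_warns_and_returns_empty(self):
        df = dmr_frame("UM", [-1.0, -2.0, 0.0], [-1.0, -2.0, 0.0])
        sel = select_covariation(df)
        assert len(sel.covar2) == 0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        df = pd.concat(
            [dmr_frame("UM", rng.normal(size=20), rng.normal(size=20)),
             dmr_frame("MU", rng.normal(size=20), rng.normal(size=20))],
            ignore_index=True,
        )
        shuffled = df.sample(frac=1.0, random_state=1)
        a = select_covariation(df)
        b = select_covariation(shuffled)
        key = ["chrom", "start", "dmr_class"]
        assert set(map(tuple, a.covar1[key].values)) == set(map(tuple, b.covar1[key].values))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_filter(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 40))
        m = int(rng.integers(6, 40))
        df = pd.concat(
            [dmr_frame("UM", rng.normal(size=n), rng.normal(size=n)),
             dmr_frame("MU", rng.normal(size=m), rng.normal(size=m))],
            ignore_index=True,
        )
        sel = select_covariation(df)
        exp1, exp2 = brute_force_select(df)
        assert set(sel.covar1.index) == exp1
        assert set(sel.covar2.index) == exp2

    def test_strict_rule_is_subset(self):
        rng = np.random.default_rng(9)
        df = dmr_frame("UM", rng.normal(size=30), rng.normal(size=30))
        literal = select_covariation(df, quantile_rule="literal")
        strict = select_covariation(df, quantile_rule="strict")
        assert set(strict.covar1.index) <= set(literal.covar1.index)


GENES = [
    GeneModel("A", "chr1", 10_000, 30_000, "+"),
    GeneModel("B", "chr1", 40_000, 60_000, "+"),
]


class TestGeneMapping:
    def test_promoter_dmr_maps_to_gene(self):
        dmrs = pd.DataFrame({"chrom": ["chr1"], "start": [9_100], "end": [9_300]})
        assert map_to_genes(dmrs, GENES, "promoter") == ["A"]

    def test_two_dmrs_one_promoter_deduplicated(self):
        dmrs = pd.DataFrame({"chrom": ["chr1"] * 2, "start": [9_100, 9_600], "end": [9_300, 9_800]})
        assert map_to_genes(dmrs, GENES, "promoter") == ["A"]

    def test_intergenic_dmr_maps_nowhere(self):
        dmrs = pd.DataFrame({"chrom": ["chr1"], "start": [35_000], "end": [35_200]})
        for cat in ("promoter", "gene_body", "downstream"):
            assert map_to_genes(dmrs, GENES, cat) == []

    def test_intergenic_category_rejected(self):
        with pytest.raises(ValueError):
            map_to_genes(pd.DataFrame(columns=["chrom", "start", "end"]), GENES, "intergenic")


def direct_hypergeom_tail(k, N, K, n):
    return sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1)) / comb(N, n)


class TestGenesetEnrichment:
    def test_counted_example(self):
        # k=2 of K=3 annotated drawn in n=3 from N=10 -> 22/120
        assert hypergeom_tail(2, 10, 3, 3) == pytest.approx(22 / 120)

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            N = int(rng.integers(5, 31))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            assert hypergeom_tail(k, N, K, n) == pytest.approx(direct_hypergeom_tail(k, N, K, n))

    def test_exact_set_has_minimum_p(self):
        background = {f"g{i}" for i in range(50)}
        target = {f"g{i}" for i in range(5)}
        sets = {"hit": target, "other": {f"g{i}" for i in range(20, 30)}}
        out = geneset_enrichment(target, background, sets)
        assert out.iloc[0]["set"] == "hit"
        assert out.iloc[0]["p_value"] < out.iloc[1]["p_value"]

    def test_null_study_rarely_significant(self):
        rng = np.random.default_rng(1)
        background = {f"g{i}" for i in range(200)}
        sets = {f"s{j}": set(rng.choice(sorted(background), 20, replace=False)) for j in range(10)}
        n_sig = 0
        for _ in range(30):
            study = set(rng.choice(sorted(background), 15, replace=False))
            out = geneset_enrichment(study, background, sets)
            n_sig += int((out["q_value"] < 0.05).sum())
        assert n_sig / (30 * 10) < 0.02

    def test_errors(self):
        with pytest.raises(ValueError):
            geneset_enrichment({"a"}, set(), {})
        with pytest.raises(ValueError):
            geneset_enrichment({"zz"}, {"a", "b"}, {})


def bed(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


class TestOverlapEnrichment:
    def test_query_covering_universe(self):
        uni = bed([("chr1", i * 100, i * 100 + 50) for i in range(10)])
        res = overlap_enrichment(bed([("chr1", 0, 10_000)]), uni.iloc[:4], uni)
        assert res["fraction"] == 1.0

    def test_disjoint_query_target(self):
        uni = bed([("chr1", 0, 100), ("chr1", 200, 300)])
        res = overlap_enrichment(bed([("chr1", 0, 100)]), bed([("chr1", 200, 300)]), uni)
        assert res["fraction"] == 0.0
        assert res["p_value"] == pytest.approx(1.0)

    def test_counted_example_matches_summation(self):
        # N=20 universe elements, K=8 overlap target, n=5 overlap query, k=4
        uni = bed([("chr1", i * 1000, i * 1000 + 100) for i in range(20)])
        target = bed([("chr1", i * 1000, i * 1000 + 100) for i in range(8)])
        query = bed([("chr1", i * 1000, i * 1000 + 100) for i in [0, 1, 2, 3, 15]])
        res = overlap_enrichment(query, target, uni)
        assert (res["N"], res["K"], res["n"], res["k"]) == (20, 8, 5, 4)
        assert res["p_value"] == pytest.approx(direct_hypergeom_tail(4, 20, 8, 5))

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            overlap_enrichment(bed([]), bed([]), bed([]))
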