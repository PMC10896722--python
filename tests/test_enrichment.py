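"""Enrichment tests vs enumeration oracles; matching; tiers."""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from rvarch.enrichment import (
    assign_tiers,
    bh_qvalues,
    enrich_gene_sets,
    fold_enrichment,
    hypergeom_overlap,
    match_background,
    ranksum_enrichment,
    read_gmt,
    restrict_to_universe,
)
from rvarch.io import write_gmt


def hypergeom_tail_oracle(overlap, universe, set_size, top):
    """Exact upper-tail by direct summation with rationals."""
    total = Fraction(0)
    for k in range(overlap, min(set_size, top) + 1):
        total += Fraction(comb(set_size, k) * comb(universe - set_size, top - k),
                          comb(universe, top))
    return float(total)


class TestHypergeomOverlap:
    def test_forced_total_overlap_gives_one(self):
        u = {f"g{i}" for i in range(30)}
        assert hypergeom_overlap(u, u, u) == pytest.approx(1.0)

    def test_zero_overlap_tiny_expectation_near_one(self):
        universe = {f"g{i}" for i in range(10000)}
        top = {f"g{i}" for i in range(50)}
        gene_set = {f"g{i}" for i in range(9000, 9010)}
        assert hypergeom_overlap(top, gene_set, universe) > 0.9

    @pytest.mark.parametrize("overlap", [1, 3, 5])
    def test_matches_summation_oracle(self, overlap):
        n_universe, n_top, n_set = 19020, 50, 20
        universe = {f"g{i}" for i in range(n_universe)}
        top = {f"g{i}" for i in range(n_top)}
        gene_set = {f"g{i}" for i in range(overlap)} | {
            f"g{i}" for i in range(1000, 1000 + n_set - overlap)
        }
        expected = hypergeom_tail_oracle(overlap, n_universe, n_set, n_top)
        assert hypergeom_overlap(top, gene_set, universe) == pytest.approx(
            expected, abs=1e-10, rel=1e-10
        )

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_overlap(set(), set(), set())


class TestBhQvalues:
    def test_single_p_identity(self):
        assert bh_qvalues([0.03])[0] == pytest.approx(0.03)

    def test_step_up_arithmetic(self):
        np.testing.assert_allclose(
            bh_qvalues([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_qvalues([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_q_at_least_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        assert np.all(bh_qvalues(p) >= p - 1e-12)


class TestMatchBackground:
    def _features(self, rng, n=400):
        return pd.DataFrame(
            {
                "n_variants": rng.integers(2, 60, n),
                "cumulative_af": rng.uniform(1e-4, 0.05, n),
            },
            index=[f"g{i}" for i in range(n)],
        )

    def test_exact_feature_twins_matched_first(self):
        feats = pd.DataFrame(
            {"n_variants": [10, 10, 10, 50], "cumulative_af": [0.01, 0.01, 0.01, 0.04]},
            index=["target", "twin1", "twin2", "far"],
        )
        got = match_background(["target"], feats, fold=2)
        assert set(got) == {"twin1", "twin2"}

    def test_matched_features_close_to_target_means(self):
        rng = np.random.default_rng(1)
        feats = self._features(rng)
        target = list(feats.sample(20, random_state=2).index)
        matched = match_background(target, feats, fold=5)
        assert len(matched) == 100
        for col in ("n_variants", "cumulative_af"):
            t = feats.loc[target, col].mean()
            m = feats.loc[matched, col].mean()
            assert m == pytest.approx(t, rel=0.10)

    def test_fivefold_returns_five_per_gene_without_replacement(self):
        rng = np.random.default_rng(3)
        feats = self._features(rng, 200)
        target = list(feats.index[:10])
        matched = match_background(target, feats, fold=5)
        assert len(matched) == 50
        assert len(set(matched)) == 50
        assert not set(matched) & set(target)

    def test_insufficient_pool_warns_and_shrinks(self):
        feats = pd.DataFrame(
            {"n_variants": [5, 5, 5], "cumulative_af": [0.01, 0.01, 0.01]},
            index=["a", "b", "c"],
        )
        with pytest.warns(UserWarning):
            matched = match_background(["a"], feats, fold=5)
        assert set(matched) == {"b", "c"}


class TestRanksumEnrichment:
    def test_null_centered(self):
        rng = np.random.default_rng(4)
        ps = [
            ranksum_enrichment(rng.uniform(size=20), rng.uniform(size=100))
            for _ in range(200)
        ]
        assert np.mean(ps) == pytest.approx(0.5, abs=0.06)

    def test_shifted_set_highly_significant(self):
        # mirrors the 24-gene set vs 1,132 matched background comparison
        rng = np.random.default_rng(5)
        set_ps = rng.uniform(0, 0.05, 24)
        bg_ps = rng.uniform(size=1132)
        assert ranksum_enrichment(set_ps, bg_ps) < 0.001

    def test_3v3_exact_enumeration(self):
        # all C(6,3)=20 rank splits enumerated directly
        set_ps = np.array([0.1, 0.2, 0.3])
        bg_ps = np.array([0.15, 0.4, 0.5])
        combined = np.concatenate([set_ps, bg_ps])
        ranks = combined.argsort().argsort() + 1
        obs = ranks[:3].sum()
        all_sums = [sum(c) for c in combinations(ranks, 3)]
        expected = np.mean([s <= obs for s in all_sums])
        assert ranksum_enrichment(set_ps, bg_ps) == pytest.approx(expected, rel=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ranksum_enrichment([], [0.1])


class TestFoldEnrichment:
    def test_background_sample_near_one(self):
        rng = np.random.default_rng(6)
        bg = rng.uniform(size=2000)
        folds = [fold_enrichment(rng.choice(bg, 200), bg) for _ in range(50)]
        assert np.mean(folds) == pytest.approx(1.0, abs=0.15)

    def test_top_decile_set_is_ten(self):
        bg = np.linspace(0.001, 1.0, 1000)
        top = bg[:50]
        assert fold_enrichment(top, bg) == pytest.approx(10.0, rel=0.02)

    def test_half_in_top_decile_is_five(self):
        bg = np.linspace(0.001, 1.0, 1000)
        mixed = np.concatenate([bg[:10], bg[500:510]])
        assert fold_enrichment(mixed, bg) == pytest.approx(5.0, rel=0.05)

    def test_small_background_rejected(self):
        with pytest.raises(ValueError):
            fold_enrichment([0.1], [0.2] * 5)


class TestAssignTiers:
    def _gene_ps(self):
        return pd.Series(
            {f"g{i}": p for i, p in enumerate(np.linspace(1e-6, 0.9, 100))}
        )

    def test_no_membership_no_tier(self):
        tiers = assign_tiers(self._gene_ps(), {"s": []}, top_k=50)
        assert tiers["tier"].isna().all()

    def test_rank_rule_separates_tier3_and_tier4(self):
        gene_ps = self._gene_ps()
        # g0 in top-50 and 2 sets -> tier 3; g60 (rank 61, P<0.05?) check below
        sets = {"a": ["g0", "g60"], "b": ["g0", "g60"], "c": ["g60"]}
        tiers = assign_tiers(gene_ps, sets, top_k=50).set_index("gene_id")
        assert tiers.loc["g0", "tier"] == 3
        # g60 is outside the top 50 so it can at best be tier 4
        expected = 4 if gene_ps["g60"] < 0.05 else None
        got = tiers.loc["g60", "tier"]
        assert (got == expected) if expected else pd.isna(got)

    def test_synthetic_fixture_counts_match_recount(self):
        rng = np.random.default_rng(7)
        gene_ps = pd.Series(rng.uniform(size=200),
                            index=[f"g{i}" for i in range(200)])
        sets = {
            f"s{k}": list(rng.choice(gene_ps.index, 30, replace=False))
            for k in range(4)
        }
        tiers = assign_tiers(gene_ps, sets, top_k=50)
        top = set(gene_ps.nsmallest(50).index)
        n3 = n4 = 0
        for g in gene_ps.index:
            m = sum(g in s for s in sets.values())
            if g in top and m >= 2:
                n3 += 1
            elif m >= 1 and gene_ps[g] < 0.05:
                n4 += 1
        assert (tiers["tier"] == 3).sum() == n3
        assert (tiers["tier"] == 4).sum() == n4


class TestGmtAndPipelineGlue:
    def test_gmt_round_trip(self, tmp_path):
        sets = {"setA": ["g1", "g2"], "setB": ["g3"]}
        path = tmp_path / "sets.gmt"
        write_gmt(sets, path)
        assert read_gmt(path) == sets

    def test_universe_restriction_logs_drops(self):
        sets, dropped = restrict_to_universe(
            {"s": ["a", "b", "zzz"]}, {"a", "b", "c"}
        )
        assert sets["s"] == ["a", "b"]
        assert dropped["s"] == 1

    def test_enrich_gene_sets_end_to_end(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(300)]
        gene_ps = pd.Series(rng.uniform(size=300), index=genes)
        # plant a set concentrated in the top 50
        top = list(gene_ps.nsmallest(50).index)
        sets = {
            "planted": top[:15],
            "random": list(rng.choice(genes, 15, replace=False)),
        }
        feats = pd.DataFrame(
            {"n_variants": rng.integers(2, 40, 300),
             "cumulative_af": rng.uniform(1e-4, 0.05, 300)},
            index=genes,
        )
        out = enrich_gene_sets(gene_ps, sets, features=feats, top_k=50,
                               background_fold=5).set_index("set")
        assert out.loc["planted", "hypergeom_p"] < 1e-10
        assert out.loc["planted", "significant"]
        assert out.loc["random", "hypergeom_p"] > 0.001
        assert out.loc["planted", "q"] >= out.loc["planted", "hypergeom_p"]


class TestRandomLabelCalibration:
    def test_ranksum_false_positive_rate(self):
        # under random gene labels ~5% of sets reach P < 0.05
        rng = np.random.default_rng(9)
        n_sets = 300
        hits = 0
        bg = rng.uniform(size=500)
        for _ in range(n_sets):
            s = rng.choice(bg, 25, replace=False)
            if ranksum_enrichment(s, bg) < 0.05:
                hits += 1
        rate = hits / n_sets
        se = np.sqrt(0.05 * 0.95 / n_sets)
        assert abs(rate - 0.05) < 3 * se + 0.02
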