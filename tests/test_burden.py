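"""Mask assembly, burden tests, Meff and min-P consolidation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

import rvarch as rv
from rvarch.burden import (
    burden_test,
    consolidate_min_p,
    effective_mask_count,
    gene_results_frame,
    gene_significance_threshold,
    mask_burden_scores,
)
from rvarch.masks import MASK_NAMES, REQUIRED_COLUMNS, assign_strata, stratum_annotations


def truth_table_stratum(row):
    """Independent rule-table evaluation of the seven stratum predicates."""
    core = ["polyphen_hdiv", "polyphen_hvar", "sift", "lrt", "mutation_taster"]
    mid = ["fathmm", "fathmm_mkl", "provean", "metasvm", "metalr", "mcap"]
    rank = ["vest3", "cadd", "dann", "eigen_raw", "eigen_pc_raw"]
    c5 = all(row[c] for c in core)
    m6 = all(row[c] for c in mid)
    r5 = all(row[c] for c in rank)
    n5 = sum(bool(row[c]) for c in core)
    rare = row["max_maf"] < 0.01
    if row["loftee"] == "HC":
        return "lof_hc"
    if c5 and m6 and r5:
        return "16of16"
    if c5 and m6:
        return "11of11"
    if c5:
        return "5of5"
    if (c5 or row["vep_impact"] == "HIGH") and row["loftee"] == "LC" and rare:
        return "5of5_lof_lc_1pct"
    if n5 >= 1 and row["vep_impact"] == "MODERATE" and rare:
        return "1of5_1pct"
    if n5 == 0 and row["vep_impact"] == "MODERATE" and rare:
        return "0of5_1pct"
    return ""


class TestAssignStrata:
    def test_loftee_hc_is_first_stratum(self):
        ann = pd.DataFrame([stratum_annotations("lof_hc", 0.001)])
        assert assign_strata(ann).iloc[0] == "lof_hc"

    def test_5of5_failing_11of11_mid_maf(self):
        # missense passing the five core predictors but failing the 11/11
        # extension lands in the fourth stratum even at MAF 0.5%
        row = stratum_annotations("5of5", 0.005)
        assert assign_strata(pd.DataFrame([row])).iloc[0] == "5of5"

    def test_synthetic_inverse_round_trip(self):
        rows = [stratum_annotations(m, 0.002) for m in MASK_NAMES]
        ann = pd.DataFrame(rows)
        assert list(assign_strata(ann)) == list(MASK_NAMES)

    def test_random_fixture_matches_truth_table(self):
        rng = np.random.default_rng(0)
        rows = []
        for _ in range(200):
            row = {c: bool(rng.integers(2)) for c in REQUIRED_COLUMNS
                   if c not in ("loftee", "vep_impact", "max_maf")}
            row["loftee"] = rng.choice(["HC", "LC", ""])
            row["vep_impact"] = rng.choice(["HIGH", "MODERATE", "LOW"])
            row["max_maf"] = float(rng.choice([0.001, 0.005, 0.02]))
            rows.append(row)
        ann = pd.DataFrame(rows)
        got = list(assign_strata(ann))
        expected = [truth_table_stratum(r) for r in rows]
        assert got == expected

    def test_missing_column_named(self):
        ann = pd.DataFrame([stratum_annotations("5of5", 0.001)]).drop(columns=["sift"])
        with pytest.raises(KeyError, match="sift"):
            assign_strata(ann)


class TestMaskNesting:
    def test_masks_accumulate_strata(self):
        rows = []
        for i, m in enumerate(MASK_NAMES):
            row = stratum_annotations(m, 0.002)
            row["variant_id"] = f"v{i}"
            row["gene_id"] = "G"
            rows.append(row)
        masks = rv.build_masks(pd.DataFrame(rows))["G"]
        for i, m in enumerate(MASK_NAMES):
            assert masks[m] == [f"v{j}" for j in range(i + 1)]


class TestBurdenTest:
    def test_single_variant_mask_equals_single_variant_test(self):
        rng = np.random.default_rng(1)
        g = rng.binomial(2, 0.05, 600).astype(float)
        y = rng.binomial(1, 0.25, 600)
        bres = burden_test(g, y, mask="m")
        sres = rv.firth_test(g, y)
        assert bres.beta == pytest.approx(sres.beta, abs=1e-8)
        assert bres.p == pytest.approx(sres.p, rel=1e-8)

    def test_zero_carriers_returns_none(self):
        assert burden_test(np.zeros(100), np.tile([0, 1], 50)) is None

    def test_null_consolidated_p_uniform_and_qq_slope(self):
        # mirrors the rare-synonymous-variant negative control: permuted
        # phenotypes must give uniform consolidated gene P values
        from rvarch.pipeline import synthetic_annotations
        from rvarch.synthetic import default_gene_panel

        ps = []
        for seed in range(2):
            cfg = rv.CohortConfig(
                n_cases=400, n_controls=1200, n_clusters=1, seed=seed,
                genes=default_gene_panel(50, 6),
            )
            coh = rv.simulate_cohort(cfg)
            ann = synthetic_annotations(coh)
            res = rv.gene_burden_scan(
                coh.dosages, coh.variants["variant_id"].tolist(),
                coh.phenotype, ann, None,
            )
            ps += gene_results_frame(res)["consolidated_p"].tolist()
        ps = np.asarray(ps)
        assert kstest(ps, "uniform").pvalue > 0.01
        assert rv.qq_slope(ps) == pytest.approx(1.0, abs=0.12)

    def test_spiked_gene_effect_recovered(self):
        from rvarch.pipeline import synthetic_annotations

        betas = []
        for seed in range(8):
            genes = [rv.GeneSpec("SPIKED", 6, maf_range=(1.5e-3, 2e-3),
                                 mask_labels=["lof_hc"] * 6,
                                 effects={"lof_hc": 1.0})]
            cfg = rv.CohortConfig(n_cases=1500, n_controls=4900, n_clusters=1,
                                  seed=seed, genes=genes)
            coh = rv.simulate_cohort(cfg)
            ann = synthetic_annotations(coh)
            res = rv.gene_burden_scan(
                coh.dosages, coh.variants["variant_id"].tolist(),
                coh.phenotype, ann, None,
            )
            betas.append(gene_results_frame(res)["beta"].iloc[0])
        assert np.mean(betas) == pytest.approx(1.0, abs=0.25)

    def test_spiked_gene_wins_ranking(self, small_cohort, small_annotations,
                                      burden_results):
        _, df = burden_results
        assert df.sort_values("consolidated_p")["gene_id"].iloc[0] == "GENE000"


class TestEffectiveMaskCount:
    def test_single_mask(self):
        rng = np.random.default_rng(2)
        assert effective_mask_count(rng.binomial(2, 0.1, 100).astype(float)) == 1.0

    def test_identical_masks_collapse_to_one(self):
        rng = np.random.default_rng(3)
        col = rng.binomial(2, 0.1, 500).astype(float)
        S = np.column_stack([col] * 7)
        assert effective_mask_count(S) == pytest.approx(1.0, abs=1e-9)

    def test_independent_masks_approach_count(self):
        rng = np.random.default_rng(4)
        S = rng.binomial(1, 0.5, size=(10000, 7)).astype(float)
        assert effective_mask_count(S) == pytest.approx(7.0, abs=0.5)

    def test_constant_column_dropped(self):
        rng = np.random.default_rng(5)
        S = np.column_stack([rng.normal(size=200), np.zeros(200)])
        assert effective_mask_count(S) == 1.0

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError):
            effective_mask_count(np.zeros((10, 3)))


class TestConsolidateMinP:
    def test_single_mask_identity(self):
        assert consolidate_min_p([0.03], 1.0) == pytest.approx(0.03)

    def test_sidak_closed_form(self):
        assert consolidate_min_p([0.01, 0.5, 0.9], 7.0) == pytest.approx(
            1 - (1 - 0.01) ** 7, rel=1e-12
        )

    def test_monotone_in_meff_and_bounded_below_by_min_p(self):
        for meff in (1.0, 2.5, 5.0, 7.0):
            p = consolidate_min_p([0.02, 0.4], meff)
            assert p >= 0.02 - 1e-15
        ps = [consolidate_min_p([0.02, 0.4], m) for m in (1, 2, 4, 7)]
        assert ps == sorted(ps)

    def test_all_nan_gives_nan(self):
        assert np.isnan(consolidate_min_p([np.nan], 2.0))

    def test_two_mask_permutation_null_quantiles(self):
        # empirical min-P null with correlated scores: the Sidak-Meff
        # consolidated P must be close to uniform
        rng = np.random.default_rng(6)
        n, reps = 300, 2000
        y = np.zeros(n)
        y[:75] = 1
        base = rng.binomial(1, 0.1, n).astype(float)
        extra = base + rng.binomial(1, 0.05, n)
        S = np.column_stack([base, extra])
        meff = effective_mask_count(S)
        assert 1.0 <= meff <= 2.0
        cons = []
        from scipy.stats import pearsonr

        for _ in range(reps):
            yp = rng.permutation(y)
            ps = []
            for j in range(2):
                r = pearsonr(S[:, j], yp)
                ps.append(r.pvalue)
            cons.append(consolidate_min_p(ps, meff))
        frac_05 = np.mean(np.asarray(cons) < 0.05)
        assert frac_05 == pytest.approx(0.05, abs=0.015)


class TestSignificanceThreshold:
    @pytest.mark.parametrize(
        "alpha,n,expected",
        [(0.05, 19020, 2.6e-6), (0.05, 1, 0.05), (0.05, 2, 0.025)],
    )
    def test_values(self, alpha, n, expected):
        assert gene_significance_threshold(alpha, n) == pytest.approx(expected)

    def test_invalid_gene_count(self):
        with pytest.raises(ValueError):
            gene_significance_threshold(0.05, 0)


class TestMaskBurdenScores:
    def test_allele_counting(self):
        dos = np.array([[0, 1], [2, 1], [0, 0]], dtype=np.int8)
        scores = mask_burden_scores(dos, ["a", "b"], {"lof_hc": ["a"], "16of16": ["a", "b"]})
        np.testing.assert_array_equal(scores["lof_hc"], [0, 2, 0])
        np.testing.assert_array_equal(scores["16of16"], [1, 3, 0])
        np.testing.assert_array_equal(scores["0of5_1pct"], [0, 0, 0])
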