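"""Two-replicate screening, Wilcoxon comparison and the differential set."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from meripscore import (
    differential_exon_genes,
    differential_table,
    rep_scores_from_table,
    screen_genes,
    wilcoxon_compare,
)

FOUR_GENE_FIXTURE = {
    "g1": (1.5, 2.0),   # passes everything
    "g2": (0.8, 1.2),   # fails score under "both" (0.8 <= 1)
    "g3": (2.0, 5.0),   # fails fold change (2.5 >= 2)
    "g4": (3.0, None),  # fails presence
}


class TestScreenGenes:
    def test_four_gene_fixture_rule_both(self):
        tbl = screen_genes(FOUR_GENE_FIXTURE, score_rule="both")
        assert list(tbl["gene_id"]) == ["g1"]
        row = tbl.iloc[0]
        assert row["group_score"] == pytest.approx(1.75)
        assert row["fold_change"] == pytest.approx(2.0 / 1.5)

    def test_four_gene_fixture_rule_either(self):
        tbl = screen_genes(FOUR_GENE_FIXTURE, score_rule="either")
        assert list(tbl["gene_id"]) == ["g1", "g2"]

    def test_fold_change_boundary_is_strict(self):
        assert screen_genes({"g": (2.0, 4.0)}).empty  # FC exactly 2 rejected
        assert list(screen_genes({"g": (2.0, 3.99)})["gene_id"]) == ["g"]

    def test_score_boundary_is_strict(self):
        assert screen_genes({"g": (1.0, 1.5)}).empty  # score exactly 1 rejected

    def test_fold_change_at_least_one(self):
        tbl = screen_genes({"g": (4.0, 2.5)})
        assert (tbl["fold_change"] >= 1).all()

    def test_negative_scores_rejected(self):
        with pytest.raises(ValueError):
            screen_genes({"g": (-1.0, 2.0)})

    def test_idempotent(self):
        tbl = screen_genes({"g1": (1.5, 2.0), "g3": (2.0, 5.0), "g5": (7.0, 6.0)})
        again = screen_genes(
            {r.gene_id: (r.score_rep1, r.score_rep2) for r in tbl.itertuples()}
        )
        pd.testing.assert_frame_equal(tbl.reset_index(drop=True), again)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(8)
        scores = {f"g{i}": (float(a), float(b)) for i, (a, b) in
                  enumerate(zip(rng.lognormal(0.5, 1, 200), rng.lognormal(0.5, 1, 200)))}
        sizes_min = [len(screen_genes(scores, score_min=m)) for m in (0.5, 1.0, 2.0, 4.0)]
        assert sizes_min == sorted(sizes_min, reverse=True)
        sizes_fc = [len(screen_genes(scores, fc_max=f)) for f in (1.2, 1.5, 2.0, 4.0)]
        assert sizes_fc == sorted(sizes_fc)

    def test_rep_scores_from_table(self):
        df = pd.DataFrame(
            {
                "gene_id": ["g1", "g1", "g2"],
                "group": ["WT"] * 3,
                "replicate": ["rep1", "rep2", "rep1"],
                "score": [1.5, 2.0, 3.0],
                "exon_score": [1.0, 1.2, 2.0],
            }
        )
        assert rep_scores_from_table(df, "WT") == {"g1": (1.5, 2.0), "g2": (3.0, None)}
        assert rep_scores_from_table(df, "WT", value="exon_score")["g1"] == (1.0, 1.2)


def exact_rank_sum_p(a: list[float], b: list[float]) -> float:
    """Independent oracle: enumerate all rank arrangements of the pooled sample."""
    pooled = sorted(a + b)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    observed = sum(ranks[v] for v in a)
    n = len(a)
    stats = [sum(comb) for comb in itertools.combinations(range(1, len(pooled) + 1), n)]
    mean = sum(stats) / len(stats)
    extreme = sum(1 for s in stats if abs(s - mean) >= abs(observed - mean) - 1e-12)
    return extreme / len(stats)


class TestWilcoxonCompare:
    def test_exact_small_sample_against_enumeration(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        res = wilcoxon_compare(a, b, variant="rank_sum")
        assert res.method == "exact"
        assert res.p_value == pytest.approx(0.1)
        assert res.p_value == pytest.approx(exact_rank_sum_p(a, b))

    def test_exact_matches_enumeration_on_random_samples(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            a = list(rng.normal(0, 1, int(rng.integers(3, 7))))
            b = list(rng.normal(0.5, 1, int(rng.integers(3, 7))))
            res = wilcoxon_compare(a, b, variant="rank_sum")
            assert res.method == "exact"
            assert res.p_value == pytest.approx(exact_rank_sum_p(a, b), abs=1e-12)

    def test_signed_rank_all_zero_differences(self):
        with pytest.raises(ValueError, match="no informative pairs"):
            wilcoxon_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], variant="signed_rank")

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_compare([], [1.0], variant="rank_sum")

    def test_unknown_variant(self):
        with pytest.raises(ValueError):
            wilcoxon_compare([1.0], [2.0], variant="median")

    def test_rank_sum_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(10)
        a = rng.lognormal(0, 1, 40)
        b = rng.lognormal(0.5, 1, 60)
        p0 = wilcoxon_compare(a, b).p_value
        for f in (np.log, np.sqrt, lambda x: x**3 + x):
            assert wilcoxon_compare(f(a), f(b)).p_value == pytest.approx(p0, abs=1e-12)

    def test_exact_and_normal_approximation_agree_at_n20(self):
        """Exact and tie-corrected normal p-values within 0.01 at n=20 per group."""
        rng = np.random.default_rng(12)
        for _ in range(100):
            a = rng.normal(0, 1, 20)
            b = rng.normal(rng.uniform(-1, 1), 1, 20)
            exact = wilcoxon_compare(a, b).p_value
            from scipy.stats import mannwhitneyu

            approx = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
            assert abs(exact - approx) < 0.01

    def test_signed_rank_detects_paired_shift(self):
        rng = np.random.default_rng(13)
        base = rng.lognormal(1, 0.8, 100)
        shifted = base * np.exp(rng.normal(0.3, 0.1, 100))
        res = wilcoxon_compare(shifted, base, variant="signed_rank")
        assert res.p_value < 1e-6


class TestDifferentialExonGenes:
    def wt_ko(self):
        wt = pd.DataFrame({"gene_id": ["g1", "g2"], "score_rep1": [0.4, 2.1], "score_rep2": [0.6, 1.9],
                           "group_score": [0.5, 2.0], "fold_change": [1.5, 1.1]})
        ko = pd.DataFrame({"gene_id": ["g1", "g2", "g3"], "score_rep1": [1.1, 1.4, 5.0],
                           "score_rep2": [0.9, 1.6, 5.0], "group_score": [1.0, 1.5, 5.0],
                           "fold_change": [1.2, 1.1, 1.0]})
        return wt, ko

    def test_strictly_increased_intersection(self):
        wt, ko = self.wt_ko()
        assert differential_exon_genes(wt, ko) == {"g1"}

    def test_include_ko_only_flag(self):
        wt, ko = self.wt_ko()
        assert differential_exon_genes(wt, ko, include_ko_only=True) == {"g1", "g3"}

    def test_identical_tables_give_empty_set(self):
        wt, _ = self.wt_ko()
        assert differential_exon_genes(wt, wt.copy()) == set()

    def test_empty_intersection_warns(self, caplog):
        wt, ko = self.wt_ko()
        ko = ko[ko.gene_id == "g3"]
        with caplog.at_level("WARNING"):
            assert differential_exon_genes(wt, ko) == set()

    def test_table_reports_ratio(self):
        wt, ko = self.wt_ko()
        tbl = differential_table(wt, ko).set_index("gene_id")
        assert tbl.loc["g1", "ratio"] == pytest.approx(2.0)
        assert not tbl.loc["g2", "increased"]
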