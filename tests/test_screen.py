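"""Screen statistics: normalization invariances, log2FC closed forms,
robust z-scores, depletion-AUC geometry and permutation gene calling."""

import numpy as np
import pandas as pd
import pytest

from epidrift.screen import (
    GuideStats,
    GuideTable,
    call_genes,
    depletion_auc,
    guide_log2fc,
    guide_zscore,
    normalize_counts,
    reference_screen_calls,
    summarize_calls,
)
from epidrift.synthetic import ScreenConfig, expected_screen_log2fc, gen_screen_counts


def small_table(counts_by_guide, genes=None, categories=None):
    """GuideTable with one replicate from {guide: (week0, week3)} counts."""
    gids = list(counts_by_guide)
    guides = pd.DataFrame(
        {
            "gene": [genes.get(g) if genes else None for g in gids],
            "category": [categories.get(g, "NT") if categories else "NT" for g in gids],
        },
        index=pd.Index(gids, name="guide_id"),
    )
    counts = pd.DataFrame(
        {
            ("rep1", "week0"): [counts_by_guide[g][0] for g in gids],
            ("rep1", "week3"): [counts_by_guide[g][1] for g in gids],
        },
        index=guides.index,
    )
    counts.columns = pd.MultiIndex.from_tuples(counts.columns)
    return GuideTable(guides=guides, counts=counts)


def stats_from_lfc(lfc: dict, genes=None, categories=None) -> GuideStats:
    frame = pd.DataFrame(
        {
            "gene": [genes.get(g) if genes else None for g in lfc],
            "category": [categories.get(g, "NT") if categories else "NT" for g in lfc],
            "log2fc": list(lfc.values()),
        },
        index=pd.Index(list(lfc), name="guide_id"),
    )
    return GuideStats(frame=frame, per_replicate=pd.DataFrame(index=frame.index))


class TestNormalizeCounts:
    def test_proportional_samples_identical_profiles(self):
        t = small_table({"g1": (10, 30), "g2": (20, 60), "g3": (70, 210)})
        norm = normalize_counts(t, pseudocount=0.0)
        assert np.allclose(norm[("rep1", "week0")], norm[("rep1", "week3")])

    def test_single_guide_sample_is_one_million(self):
        t = small_table({"g1": (5, 7)})
        norm = normalize_counts(t)
        assert np.allclose(norm.sum(axis=0), 1e6)

    def test_per_sample_sums_equal_one_million(self):
        rng = np.random.default_rng(0)
        t = small_table({f"g{i}": tuple(rng.integers(0, 500, 2)) for i in range(100)})
        norm = normalize_counts(t)
        assert np.allclose(norm.sum(axis=0), 1e6, rtol=1e-9)


class TestGuideLog2FC:
    def test_identical_counts_zero_fc(self):
        t = small_table({"g1": (50, 50), "g2": (10, 10)})
        stats = guide_log2fc(t)
        assert np.allclose(stats.log2fc, 0.0)

    def test_fourfold_increase_under_equal_library_size(self):
        t = small_table({"g1": (100, 400), "g2": (400, 100)})
        stats = guide_log2fc(t, pseudocount=0.0)
        assert stats.log2fc["g1"] == pytest.approx(2.0)
        assert stats.log2fc["g2"] == pytest.approx(-2.0)

    def test_noiseless_generator_matches_closed_form(self):
        """Expected-count mode reproduces the generator's analytic log2FC
        (selection attenuated by the targeted fraction, renormalized by the
        total library growth) to 1e-6."""
        fitness = {"ESS01": -0.8, "DRV01": 0.4}
        cfg = ScreenConfig(fitness=fitness, depth=None, seed=5)
        stats = guide_log2fc(gen_screen_counts(cfg), pseudocount=0.0)
        for gene in ("ESS01", "DRV01", "EC01"):
            expect = expected_screen_log2fc(cfg, gene)
            got = stats.frame.loc[stats.frame["gene"] == gene, "log2fc"]
            assert np.allclose(got, expect, atol=1e-6)
        nt = stats.frame["category"] == "NT"
        assert np.allclose(
            stats.frame.loc[nt, "log2fc"], expected_screen_log2fc(cfg, None), atol=1e-6
        )


class TestGuideZScore:
    def test_nt_median_guide_zero_and_location_invariance(self):
        rng = np.random.default_rng(3)
        lfc = {f"NT{i}": float(v) for i, v in enumerate(rng.normal(0.3, 1.0, 101))}
        stats = guide_zscore(stats_from_lfc(lfc))
        med_guide = stats.frame["log2fc"].sub(stats.nt_median).abs().idxmin()
        assert stats.frame.loc[med_guide, "z"] == pytest.approx(0.0, abs=1e-12)
        shifted = guide_zscore(
            stats_from_lfc({g: v + 5.0 for g, v in lfc.items()})
        )
        assert np.allclose(shifted.frame["z"], stats.frame["z"], atol=1e-9)

    def test_standard_normal_nt_half_normal_mean(self):
        rng = np.random.default_rng(4)
        lfc = {f"NT{i}": float(v) for i, v in enumerate(rng.normal(0, 1, 10_000))}
        stats = guide_zscore(stats_from_lfc(lfc))
        mean_abs = np.abs(stats.frame["z"]).mean()
        half_normal = np.sqrt(2 / np.pi)
        se = np.sqrt(1 - 2 / np.pi) / np.sqrt(10_000)
        assert abs(mean_abs - half_normal) < 5 * se  # MAD estimate adds noise

    def test_too_few_nt_rejected(self):
        with pytest.raises(ValueError):
            guide_zscore(stats_from_lfc({f"NT{i}": float(i) for i in range(5)}))


class TestDepletionAUC:
    def test_set_ranked_first_attains_geometric_maximum(self):
        n, s = 200, 40
        lfc = {f"g{i:03d}": float(i) for i in range(n)}
        stats = stats_from_lfc(lfc)
        set_ids = [f"g{i:03d}" for i in range(s)]
        res = depletion_auc(stats, set_ids)
        assert res.auc == pytest.approx(1 - s / (2 * n), abs=1e-9)

    def test_uniformly_interleaved_set_near_half(self):
        n = 1000
        lfc = {f"g{i:04d}": float(i) for i in range(n)}
        stats = stats_from_lfc(lfc)
        set_ids = [f"g{i:04d}" for i in range(0, n, 10)]
        res = depletion_auc(stats, set_ids)
        assert res.auc == pytest.approx(0.5, abs=0.01)

    def test_random_sets_average_half(self):
        rng = np.random.default_rng(9)
        n, s = 1000, 100
        lfc = {f"g{i:04d}": float(v) for i, v in enumerate(rng.normal(size=n))}
        stats = stats_from_lfc(lfc)
        ids = np.array(list(lfc))
        aucs = [
            depletion_auc(stats, rng.choice(ids, s, replace=False)).auc
            for _ in range(200)
        ]
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)

    def test_full_or_empty_set_rejected(self):
        stats = stats_from_lfc({"a": 0.0, "b": 1.0})
        with pytest.raises(ValueError):
            depletion_auc(stats, ["a", "b"])
        with pytest.raises(ValueError):
            depletion_auc(stats, [])

    def test_deterministic_tie_break(self):
        lfc = {"b": 0.0, "a": 0.0, "c": 0.0, "d": 1.0}
        stats = stats_from_lfc(lfc)
        r1 = depletion_auc(stats, ["a"]).auc
        r2 = depletion_auc(stats_from_lfc(dict(reversed(list(lfc.items())))), ["a"]).auc
        assert r1 == r2


class TestCallGenes:
    def test_strongly_depleted_gene_called(self):
        cfg = ScreenConfig(fitness={"ESS01": -1.0}, seed=21)
        stats = guide_log2fc(gen_screen_counts(cfg))
        calls = call_genes(stats, seed=0).set_index("gene")
        assert calls.loc["ESS01", "direction"] == "depleted"
        assert calls.loc["ESS01", "fdr"] < 0.1

    def test_direction_consistent_with_median_sign(self):
        cfg = ScreenConfig(
            fitness={"DRV01": 0.8, "ESS01": -0.8, "ESS02": -0.6}, seed=22
        )
        calls = call_genes(guide_log2fc(gen_screen_counts(cfg)), seed=0)
        assert (calls.loc[calls["direction"] == "enriched", "median_log2fc"] > 0).all()
        assert (calls.loc[calls["direction"] == "depleted", "median_log2fc"] < 0).all()

    def test_seeded_permutations_reproducible(self):
        stats = guide_log2fc(gen_screen_counts(ScreenConfig(seed=23)))
        c1 = call_genes(stats, seed=7)
        c2 = call_genes(stats, seed=7)
        pd.testing.assert_frame_equal(c1, c2)

    def test_single_guide_gene_unchanged_with_warning(self):
        lfc = {f"NT{i}": 0.0 for i in range(20)}
        lfc["solo_g1"] = -5.0
        genes = {"solo_g1": "Solo"}
        cats = {"solo_g1": "driver"}
        stats = stats_from_lfc(lfc, genes=genes, categories=cats)
        calls = call_genes(stats, seed=0).set_index("gene")
        assert calls.loc["Solo", "direction"] == "unchanged"
        assert calls.loc["Solo", "warnings"] == "lt2guides"


class TestSummarizeCalls:
    def test_reference_driver_and_candidate_outcomes(self):
        """The published per-gene outcomes give 78% altered drivers, 49
        altered candidates and 67 fitness-regulating genes in total."""
        calls = reference_screen_calls()
        cats = dict(zip(calls["gene"], calls["category"]))
        summary = summarize_calls(calls, cats).set_index("category")
        assert summary.loc["driver", "percent_altered"] == 78
        cand = summary.loc["cancer_candidate"]
        assert cand["n_enriched"] + cand["n_depleted"] == 49
        altered_total = int(
            summary["n_enriched"].sum() + summary["n_depleted"].sum()
        )
        assert altered_total == 67

    def test_empty_category_flagged(self):
        calls = pd.DataFrame(
            {"gene": ["A"], "direction": ["enriched"]}
        )
        cats = {"A": "driver", "B": "essential"}
        summary = summarize_calls(calls, cats).set_index("category")
        assert bool(summary.loc["essential", "empty"])
        assert summary.loc["essential", "n_total"] == 0

    def test_unknown_gene_rejected(self):
        calls = pd.DataFrame({"gene": ["X"], "direction": ["enriched"]})
        with pytest.raises(ValueError):
            summarize_calls(calls, {"A": "driver"})


class TestPipelineInvariance:
    def test_scaling_one_sample_leaves_log2fc_unchanged(self):
        rng = np.random.default_rng(11)
        base = {f"g{i}": (int(c0), int(c3)) for i, (c0, c3) in enumerate(
            zip(rng.integers(1000, 5000, 50), rng.integers(1000, 5000, 50))
        )}
        t1 = small_table(base)
        t2 = small_table({g: (c0 * 7, c3) for g, (c0, c3) in base.items()})
        l1 = guide_log2fc(t1).log2fc
        l2 = guide_log2fc(t2).log2fc
        assert np.allclose(l1, l2, atol=1e-3)  # pseudocount perturbation only
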