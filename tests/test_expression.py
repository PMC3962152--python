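import numpy as np
import pandas as pd
import pytest

import oracles
from hubnet import (
    ExpressionDataset,
    ExpressionMeta,
    SyntheticExpressionSpec,
    classify_hub_expression,
    differential_stats,
    make_expression_pair,
    meta_combine,
    rank_percentiles,
)
from hubnet.datasets import expression_summary_stats, load_hub_genes


def _dataset(gene_rows: dict, n_normal: int, n_disease: int, name="ds"):
    samples = [f"N{i}" for i in range(n_normal)] + [f"D{i}" for i in range(n_disease)]
    mat = pd.DataFrame(gene_rows, index=samples).T
    mat.columns = samples
    groups = pd.Series(
        ["normal"] * n_normal + ["disease"] * n_disease, index=samples
    )
    return ExpressionDataset(matrix=mat, groups=groups, name=name)


class TestDifferentialStats:
    def test_flat_gene_has_no_signal(self):
        ds = _dataset({"flat": [1.0] * 6, "varying": [0, 1, 2, 3, 4, 5]}, 3, 3)
        stats = differential_stats(ds)
        row = stats.loc["flat"]
        assert row["t_statistic"] == 0.0
        assert row["p_value"] == 1.0
        assert row["fold_change"] == 0.0
        assert row["direction"] == "none"

    def test_zero_variance_with_separated_means_is_flagged(self):
        ds = _dataset({"step": [0.0, 0.0, 1.0, 1.0], "noise": [0.1, 0.4, 0.2, 0.9]}, 2, 2)
        with pytest.warns(UserWarning, match="zero within-group variance"):
            stats = differential_stats(ds)
        row = stats.loc["step"]
        assert row["degenerate"]
        assert row["p_value"] == np.nextafter(0.0, 1.0)
        assert np.isposinf(row["t_statistic"])

    def test_pooled_t_matches_hand_formula(self):
        normal = [1.2, 0.8, 1.5, 1.1]
        disease = [2.3, 2.9, 1.9, 2.5]
        ds = _dataset({"gene": normal + disease, "other": list(range(8))}, 4, 4)
        stats = differential_stats(ds)
        t, p = oracles.pooled_t_two_sided(normal, disease)
        assert stats.at["gene", "t_statistic"] == pytest.approx(t, abs=1e-10)
        assert stats.at["gene", "p_value"] == pytest.approx(p, abs=1e-10)
        assert stats.at["gene", "fold_change"] == pytest.approx(
            np.mean(disease) - np.mean(normal), abs=1e-12
        )
        assert stats.at["gene", "direction"] == "over"

    def test_welch_flag_matches_scipy(self):
        from scipy import stats as sps

        rng = np.random.default_rng(3)
        rows = {f"g{i}": list(rng.normal(size=10)) for i in range(5)}
        ds = _dataset(rows, 5, 5)
        ours = differential_stats(ds, welch=True)
        for g, values in rows.items():
            t, p = sps.ttest_ind(values[5:], values[:5], equal_var=False)
            assert ours.at[g, "t_statistic"] == pytest.approx(t, abs=1e-10)
            assert ours.at[g, "p_value"] == pytest.approx(p, abs=1e-10)


class TestRankPercentiles:
    def _frame(self, ps, direction):
        return pd.DataFrame(
            {
                "p_value": ps,
                "fold_change": [-1.0 if direction == "under" else 1.0] * len(ps),
                "direction": [direction] * len(ps),
            },
            index=[f"g{i:03d}" for i in range(len(ps))],
        )

    def test_best_and_worst_of_class(self):
        ps = list(np.linspace(0.001, 0.9, 100))
        out = rank_percentiles(self._frame(ps, "under"))
        assert out.at["g000", "rank"] == 1
        assert out.at["g000", "rank_percentile"] == 1
        assert out.at["g099", "rank_percentile"] == 100

    def test_ties_broken_by_symbol(self):
        frame = self._frame([0.5, 0.5, 0.1], "over")
        out = rank_percentiles(frame)
        assert out.at["g002", "rank"] == 1
        assert out.at["g000", "rank"] == 2  # tie with g001 broken by symbol
        assert out.at["g001", "rank"] == 3

    def test_percentile_monotone_in_p_within_class(self):
        rng = np.random.default_rng(4)
        frame = self._frame(list(rng.uniform(size=50)), "under")
        out = rank_percentiles(frame).sort_values("p_value")
        assert out["rank_percentile"].is_monotonic_increasing

    def test_planted_genes_outrank_null_genes(self):
        """A 3-s.d. shift puts every planted gene ahead of every null gene."""
        spec = SyntheticExpressionSpec(
            n_genes=200, n_normal=20, n_disease=20, planted_fraction=0.1,
            effect_size=3.0, seed=21,
        )
        a, _, planted = make_expression_pair(spec)
        stats = differential_stats(a)
        for cls in ("under", "over"):
            members = stats[stats["direction"] == cls]
            planted_pct = members.loc[
                [g for g in members.index if g in planted], "rank_percentile"
            ]
            null_pct = members.loc[
                [g for g in members.index if g not in planted], "rank_percentile"
            ]
            if len(planted_pct) and len(null_pct):
                assert planted_pct.max() < null_pct.min()


class TestMetaCombine:
    def _stats(self, rows):
        df = pd.DataFrame(rows).set_index("gene")
        return df

    def test_gene_missing_from_one_dataset_is_absent(self):
        a = self._stats(
            [{"gene": "X", "fold_change": -2.0, "rank_percentile": 10.0}]
        )
        b = self._stats(
            [{"gene": "Y", "fold_change": -2.0, "rank_percentile": 10.0}]
        )
        rec = meta_combine(a, b)
        assert (rec["direction"] == "absent").all()
        assert not rec["passes_filter"].any()

    def test_sign_disagreement_is_discordant(self):
        a = self._stats([{"gene": "X", "fold_change": -2.1, "rank_percentile": 5.0}])
        b = self._stats([{"gene": "X", "fold_change": 1.3, "rank_percentile": 5.0}])
        rec = meta_combine(a, b)
        assert rec.at["X", "direction"] == "discordant"
        assert not rec.at["X", "passes_filter"]

    def test_cumulative_rules(self):
        a = self._stats([{"gene": "X", "fold_change": -1.0, "rank_percentile": 10.0}])
        b = self._stats([{"gene": "X", "fold_change": -1.0, "rank_percentile": 30.0}])
        assert meta_combine(a, b, rule="mean").at["X", "cumulative_percentile"] == 20.0
        assert meta_combine(a, b, rule="sum").at["X", "cumulative_percentile"] == 40.0
        assert meta_combine(a, b, rule="max").at["X", "cumulative_percentile"] == 30.0

    def test_symmetric_in_datasets(self):
        a, b = expression_summary_stats()
        ab = meta_combine(a, b)
        ba = meta_combine(b, a)
        pd.testing.assert_series_equal(ab["direction"], ba["direction"])
        pd.testing.assert_series_equal(
            ab["cumulative_percentile"], ba["cumulative_percentile"]
        )

    def test_published_summary_classifies_16_under_11_over(self):
        """The bundled two-study hub summary splits 16 under / 11 over."""
        a, b = expression_summary_stats()
        rec = meta_combine(a, b)
        counts = rec["direction"].value_counts()
        assert counts.get("under", 0) == 16
        assert counts.get("over", 0) == 11

    def test_borderline_gene_fails_mean_rule_filter(self):
        """EGFR's percentiles average to 36.5, just outside the top-36% band."""
        a, b = expression_summary_stats()
        rec = meta_combine(a, b, threshold_pct=36.0)
        assert rec.at["EGFR", "cumulative_percentile"] == pytest.approx(36.5)
        assert not rec.at["EGFR", "passes_filter"]
        failing = rec[(rec["direction"].isin(["under", "over"])) & ~rec["passes_filter"]]
        assert list(failing.index) == ["EGFR"]


class TestClassifyHubExpression:
    def test_disjoint_hubs_give_empty_report(self):
        a, b = expression_summary_stats()
        rec = meta_combine(a, b)
        report = classify_hub_expression({"ZZZ1", "ZZZ2"}, rec)
        assert report.n_under == report.n_over == 0
        assert report.discordant.empty and report.absent.empty

    def test_published_hub_list_yields_27_records(self):
        a, b = expression_summary_stats()
        rec = meta_combine(a, b)
        report = classify_hub_expression(load_hub_genes(), rec)
        total = (
            report.n_under + report.n_over + len(report.discordant) + len(report.absent)
        )
        assert total == 27
        assert report.n_under == 16 and report.n_over == 11
        assert "underexpressed  16" in report.summary()

    def test_restriction_equals_set_filter_oracle(self):
        a, b = expression_summary_stats()
        rec = meta_combine(a, b)
        rng = np.random.default_rng(5)
        hubs = set(rng.choice(rec.index, size=10, replace=False))
        report = classify_hub_expression(hubs, rec)
        combined = pd.concat(
            [report.under, report.over, report.discordant, report.absent]
        )
        assert set(combined.index) == {g for g in rec.index if g in hubs}


class TestCalibrationAndRecovery:
    def test_null_type_one_error_rate(self):
        """With no planted signal the p<0.05 rate stays near 5%."""
        spec = SyntheticExpressionSpec(
            n_genes=2000, n_normal=20, n_disease=20, effect_size=0.0,
            planted_fraction=0.1, seed=31,
        )
        a, _, _ = make_expression_pair(spec)
        stats = differential_stats(a)
        frac = float((stats["p_value"] < 0.05).mean())
        se = np.sqrt(0.05 * 0.95 / 2000)
        assert abs(frac - 0.05) < 3 * se

    def test_planted_median_percentile_recovered(self):
        """2-s.d. planted genes concentrate in the top ranks of their class."""
        spec = SyntheticExpressionSpec(
            n_genes=1000, n_normal=30, n_disease=30, planted_fraction=0.1,
            effect_size=2.0, seed=41,
        )
        a, _, planted = make_expression_pair(spec)
        stats = differential_stats(a)
        pct = stats.loc[list(planted), "rank_percentile"]
        assert float(pct.median()) < 15

    def test_meta_model_end_to_end_on_synthetic_pair(self):
        spec = SyntheticExpressionSpec(
            n_genes=400, n_normal=20, n_disease=20, planted_fraction=0.1,
            effect_size=4.0, seed=51,
        )
        a, b, planted = make_expression_pair(spec)
        res = ExpressionMeta.from_datasets(a, b).fit()
        rec = res.records
        for gene, sign in planted.items():
            expected = "under" if sign < 0 else "over"
            assert rec.at[gene, "direction"] == expected
        assert "underexpressed" in res.summary()


class TestDatasetValidation:
    def test_requires_two_samples_per_group(self):
        with pytest.raises(ValueError, match=">=2 samples"):
            _dataset({"g": [1.0, 2.0, 3.0]}, 1, 2)

    def test_duplicate_genes_rejected(self):
        samples = ["N0", "N1", "D0", "D1"]
        mat = pd.DataFrame(
            [[1.0] * 4, [2.0] * 4], index=["dup", "dup"], columns=samples
        )
        groups = pd.Series(["normal", "normal", "disease", "disease"], index=samples)
        with pytest.raises(ValueError, match="duplicate"):
            ExpressionDataset(matrix=mat, groups=groups)
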