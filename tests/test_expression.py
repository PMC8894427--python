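import numpy as np
import pandas as pd
import pytest
from scipy import stats

from transplantomics import (ExpressionMatrix, classify_po_gc, de_test,
                             filter_low_expression, lfc_slope,
                             normalize_and_transform, plastic_gene_sets)
from conftest import make_de_frame


def _expr(mini_design, counts, gene_ids=None):
    counts = np.asarray(counts)
    ids = gene_ids or [f"g{i}" for i in range(counts.shape[0])]
    return ExpressionMatrix(pd.Index(ids), counts, mini_design)


class TestLowExpressionFilter:
    @pytest.mark.parametrize("n_high,expected_kept", [
        (0, False),   # all-zero gene removed
        (6, True),    # >=10 in 6 of 48: 87.5% low <= 90% -> kept
        (4, False),   # >=10 in 4 of 48: 91.7% low > 90% -> removed
    ])
    def test_boundary_enumeration(self, n_high, expected_kept):
        from transplantomics import SampleDesign
        design = SampleDesign.full_design()
        counts = np.zeros((1, 48), dtype=int)
        counts[0, :n_high] = 10
        expr = ExpressionMatrix(pd.Index(["g"]), counts, design)
        out = filter_low_expression(expr)
        assert (out.n_genes == 1) is expected_kept


class TestNormalization:
    def test_doubled_sample_size_factors(self, mini_design):
        rng = np.random.default_rng(0)
        a = rng.integers(10, 1000, size=100)
        counts = np.tile(a[:, None], (1, 8))
        counts[:, 1::2] *= 2  # half the samples at exactly double depth
        expr = normalize_and_transform(_expr(mini_design, counts))
        np.testing.assert_allclose(expr.size_factors[::2], 1 / np.sqrt(2), rtol=1e-12)
        np.testing.assert_allclose(expr.size_factors[1::2], np.sqrt(2), rtol=1e-12)

    def test_identical_samples_unit_factors(self, mini_design):
        counts = np.tile(np.arange(1, 51)[:, None], (1, 8))
        expr = normalize_and_transform(_expr(mini_design, counts))
        np.testing.assert_allclose(expr.size_factors, 1.0, rtol=1e-12)
        np.testing.assert_allclose(expr.transformed, np.log2(counts + 1.0))

    def test_all_zero_sample_errors(self, mini_design):
        counts = np.ones((10, 8), dtype=int)
        counts[:, 0] = 0
        with pytest.raises(ValueError):
            normalize_and_transform(_expr(mini_design, counts))


class TestDETest:
    def test_identical_counts_give_null(self, pair_design):
        rng = np.random.default_rng(1)
        counts = rng.integers(20, 200, size=(50, 8))
        counts[0] = [50, 60, 55, 45, 50, 60, 55, 45]  # same values both cells
        expr = normalize_and_transform(_expr(pair_design, counts))
        de = de_test(expr, ("AM", "AM"), ("AM", "OWA"), "F1")
        row = de.iloc[0]
        assert abs(row["lfc"]) < 0.2
        assert row["p"] > 0.5

    def test_null_calibration(self, pair_design):
        rng = np.random.default_rng(2)
        mu = rng.uniform(20, 500, size=2000)
        k = 5.0
        counts = rng.negative_binomial(k, k / (k + mu[:, None]), size=(2000, 8))
        expr = normalize_and_transform(_expr(pair_design, counts))
        de = de_test(expr, ("AM", "AM"), ("AM", "OWA"), "F1")
        p = de["p"].dropna().to_numpy()
        assert (de["padj"].dropna() < 0.05).mean() <= 0.05
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_planted_lfc_power(self, pair_design):
        rng = np.random.default_rng(3)
        k = 5.0
        mu = np.full((500, 8), 100.0)
        # |log2 FC| = 2 planted in 100 genes, balanced up/down so the
        # median-of-ratios normalization stays neutral
        mu[:50, 4:] *= 4.0
        mu[50:100, 4:] /= 4.0
        counts = rng.negative_binomial(k, k / (k + mu))
        expr = normalize_and_transform(_expr(pair_design, counts))
        de = de_test(expr, ("AM", "AM"), ("AM", "OWA"), "F1")
        planted = de.iloc[:100]
        assert (planted["padj"] < 0.05).mean() >= 0.90
        assert planted["lfc"].abs().mean() == pytest.approx(2.0, abs=0.15)

    def test_wald_fit_matches_statsmodels_glm(self, pair_design):
        import statsmodels.api as sm
        rng = np.random.default_rng(4)
        k = 5.0
        mu = np.concatenate([np.full(4, 80.0), np.full(4, 200.0)])
        counts = rng.negative_binomial(k, k / (k + mu), size=(5, 8))
        expr = normalize_and_transform(_expr(pair_design, counts))
        de = de_test(expr, ("AM", "AM"), ("AM", "OWA"), "F1")
        x = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)
        X = sm.add_constant(x)
        from transplantomics.expression import _dispersion_mom
        alpha = _dispersion_mom(counts / expr.size_factors[None, :], x)
        for g in range(5):
            fit = sm.GLM(counts[g], X, offset=np.log(expr.size_factors),
                         family=sm.families.NegativeBinomial(alpha=alpha[g])
                         ).fit()
            assert de["lfc"].iloc[g] * np.log(2) == pytest.approx(
                fit.params[1], abs=1e-5)

    def test_bh_adjusted_monotone_in_raw_p(self, pair_design):
        rng = np.random.default_rng(5)
        counts = rng.integers(5, 500, size=(300, 8))
        expr = normalize_and_transform(_expr(pair_design, counts))
        de = de_test(expr, ("AM", "AM"), ("AM", "OWA"), "F1").dropna(subset=["p"])
        by_p = de.sort_values("p")
        assert (np.diff(by_p["padj"].to_numpy()) >= -1e-12).all()
        assert (by_p["padj"] >= by_p["p"] - 1e-12).all()

    def test_too_few_samples_errors(self, pair_design):
        counts = np.ones((5, 8), dtype=int) * 50
        expr = normalize_and_transform(_expr(pair_design, counts))
        with pytest.raises(ValueError):
            de_test(expr, ("AM", "AM"), ("AM", "OWA"), "F2")  # empty generation


class TestPlasticSets:
    def _de_results(self, n_am, n_owa, n_genes=100):
        genes = [f"g{i}" for i in range(n_genes)]
        p_am = [0.001] * n_am + [0.5] * (n_genes - n_am)
        p_owa = [0.001] * n_owa + [0.5] * (n_genes - n_owa)
        return {
            "AM_AM_vs_AM_OWA": make_de_frame(genes, p_am, "AM_AM_vs_AM_OWA"),
            "OWA_OWA_vs_OWA_AM": make_de_frame(genes, p_owa, "OWA_OWA_vs_OWA_AM"),
        }

    def test_fold_ratio(self):
        sets = plastic_gene_sets(self._de_results(80, 10))
        assert len(sets["AM"]) == 80 and len(sets["OWA"]) == 10
        assert sets["ratio"] == pytest.approx(8.0)

    def test_equal_sets_ratio_one(self):
        assert plastic_gene_sets(self._de_results(5, 5))["ratio"] == 1.0

    def test_empty_owa_set_flagged_infinite(self):
        sets = plastic_gene_sets(self._de_results(5, 0))
        assert sets["ratio"] == float("inf") and sets["ratio_infinite"]


class TestPoGcClassification:
    @staticmethod
    def _results(eligible, plastic, transplant_de):
        sig, ns = 0.001, 0.9
        genes = ["g"]
        return {
            "AM_AM_vs_OWA_OWA": make_de_frame(genes, [sig if eligible else ns],
                                              "AM_AM_vs_OWA_OWA"),
            "AM_AM_vs_AM_OWA": make_de_frame(genes, [sig if plastic else ns],
                                             "AM_AM_vs_AM_OWA"),
            "AM_OWA_vs_OWA_OWA": make_de_frame(genes, [sig if transplant_de else ns],
                                               "AM_OWA_vs_OWA_OWA"),
            "OWA_OWA_vs_OWA_AM": make_de_frame(genes, [sig if plastic else ns],
                                               "OWA_OWA_vs_OWA_AM"),
            "OWA_AM_vs_AM_AM": make_de_frame(genes, [sig if transplant_de else ns],
                                             "OWA_AM_vs_AM_AM"),
        }

    @pytest.mark.parametrize("eligible,plastic,transplant_de,expected", [
        (True, True, False, "PO"),
        (True, False, False, "unclassified"),
        (True, True, True, "GC"),   # transplant-vs-destination DE wins
        (True, False, True, "GC"),
        (False, True, False, None),  # ineligible genes are absent
        (False, False, False, None),
        (False, True, True, None),
        (False, False, True, None),
    ])
    def test_all_boolean_combinations(self, eligible, plastic, transplant_de,
                                      expected):
        for direction in ("forward", "reverse"):
            out = classify_po_gc(self._results(eligible, plastic, transplant_de),
                                 direction)
            if expected is None:
                assert out.empty
            else:
                assert list(out["class"]) == [expected]

    def test_missing_contrast_named(self):
        res = self._results(True, True, False)
        del res["AM_OWA_vs_OWA_OWA"]
        with pytest.raises(ValueError, match="AM_OWA_vs_OWA_OWA"):
            classify_po_gc(res, "forward")


class TestLfcSlope:
    def test_identity_and_reflection(self):
        x = np.linspace(-3, 3, 20)
        assert lfc_slope(x, x)["slope"] == pytest.approx(1.0)
        assert lfc_slope(x, -x)["slope"] == pytest.approx(-1.0)

    def test_noisy_recovery(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, 500)
        y = 0.37 * x + rng.normal(0, 0.1, 500)
        assert lfc_slope(x, y)["slope"] == pytest.approx(0.37, abs=0.02)

    def test_degenerate_x_errors(self):
        with pytest.raises(ValueError):
            lfc_slope(np.ones(10), np.arange(10.0))
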