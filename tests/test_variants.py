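import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from transplantomics import (AlleleCountTable, FilterRules,
                             adaptive_loci_intersection, allele_expression_qc,
                             bonferroni_threshold, cmh_test, filter_variants)
from transplantomics.variants import cmh_components


def _table(mini_design, rows):
    """rows: list of (ref_counts[8], alt_counts[8])."""
    sites = pd.DataFrame({
        "contig": ["sc1"] * len(rows),
        "pos": np.arange(1, len(rows) + 1) * 10,
        "ref_allele": "A", "alt_allele": "T",
    })
    ref = np.array([r for r, _ in rows])
    alt = np.array([a for _, a in rows])
    return AlleleCountTable(sites, ref, alt, mini_design)


class TestFilterCascade:
    def test_hand_enumerated_five_site_toy(self, mini_design):
        n = 8
        rows = [
            # A: 60x everywhere, alt fraction 0.1 in 4 samples -> kept
            ([54] * 4 + [60] * 4, [6] * 4 + [0] * 4),
            # B: one sample at 30x -> dropped by the coverage rule
            ([30] + [54] * 7, [0] + [6] * 7),
            # C: MAF exactly 0.025 in exactly 4 samples -> kept (inclusive)
            ([78] * 4 + [80] * 4, [2] * 4 + [0] * 4),
            # D: variable in only 3 samples -> dropped
            ([54] * 3 + [60] * 5, [6] * 3 + [0] * 5),
            # E: depth 4x the dataset median -> dropped
            ([216] * 4 + [240] * 4, [24] * 4 + [0] * 4),
        ]
        table = _table(mini_design, rows)
        out, ledger = filter_variants(table, FilterRules())
        assert list(out.sites["pos"]) == [10, 30]  # sites A and C survive
        assert ledger["low_coverage_or_missing"] == 1
        assert ledger["excess_depth"] == 1
        assert ledger["too_few_variable_samples"] == 1
        removed = (ledger["low_coverage_or_missing"] + ledger["excess_depth"]
                   + ledger["too_few_variable_samples"])
        assert removed == ledger["input_sites"] - ledger["output_sites"]

    def test_monomorphic_sites_all_removed(self, mini_design):
        table = _table(mini_design, [([60] * 8, [0] * 8)] * 3)
        out, _ = filter_variants(table)
        assert out.n_sites == 0

    def test_disabled_rules_are_identity(self, mini_design):
        rules = FilterRules(min_sample_coverage=0, min_sample_maf=0.0,
                            min_variable_samples=0, max_depth_factor=10**9)
        table = _table(mini_design, [([60] * 8, [6] * 8), ([5] * 8, [0] * 8)])
        out, _ = filter_variants(table, rules)
        assert out.n_sites == table.n_sites

    def test_empty_input_errors(self, mini_design):
        with pytest.raises(ValueError):
            empty = _table(mini_design, [([1] * 8, [0] * 8)]).subset_sites(
                np.array([], dtype=int))
            filter_variants(empty)


class TestCMH:
    def test_no_association_gives_p_one(self):
        tables = [[[10, 10], [10, 10]]] * 4
        stat, p = cmh_test(tables)
        assert stat == 0.0 and p == 1.0

    def test_single_stratum_hand_formula(self):
        # a=8,b=2,c=2,d=8: E=5, Var=10^4/(400*19), X^2=9/Var=6.84
        stat, p = cmh_test([[[8, 2], [2, 8]]])
        var = 10 * 10 * 10 * 10 / (400 * 19)
        assert stat == pytest.approx(9 / var, rel=1e-12)
        assert stat == pytest.approx(6.84, abs=0.005)
        assert p == pytest.approx(stats.chi2.sf(6.84, 1), abs=1e-4)

    def test_two_identical_strata_additivity(self):
        stat, _ = cmh_test([[[8, 2], [2, 8]]] * 2)
        assert stat == pytest.approx((3 + 3) ** 2 / (2 * (10**4 / (400 * 19))),
                                     rel=1e-12)
        assert stat == pytest.approx(13.68, abs=0.01)

    def test_degenerate_strata_skipped(self):
        stat, p = cmh_test([[[0, 0], [5, 5]], [[8, 2], [2, 8]]])
        ref_stat, ref_p = cmh_test([[[8, 2], [2, 8]]])
        assert stat == ref_stat and p == ref_p
        stat, p = cmh_test([[[0, 0], [5, 5]]])
        assert stat == 0.0 and p == 1.0

    def test_against_statsmodels_stratified_table(self):
        from statsmodels.stats.contingency_tables import StratifiedTable
        rng = np.random.default_rng(4)
        for _ in range(20):
            tables = rng.integers(1, 40, size=(3, 2, 2))
            stat, _ = cmh_test(tables)
            st = StratifiedTable(np.moveaxis(tables, 0, -1).astype(float))
            ref = st.test_null_odds(correction=False).statistic
            assert stat == pytest.approx(float(ref), rel=1e-8)


def exact_cmh_midp(tables) -> float:
    """Exact permutation p for the CMH statistic with fixed margins.

    Enumerates all joint tables with each stratum's margins fixed, weighting
    by the product of hypergeometric probabilities, and uses the mid-p
    convention (half weight on the observed statistic's probability mass),
    the standard exact comparator for the uncorrected chi-square.
    """
    tables = np.asarray(tables, dtype=float)
    num, var = cmh_components(tables[:, 0, 0], tables[:, 0, 1],
                              tables[:, 1, 0], tables[:, 1, 1])
    obs = abs(num.sum())
    supports = []
    for t in tables:
        row1, col1 = t[0].sum(), t[:, 0].sum()
        n = t.sum()
        lo, hi = int(max(0, row1 + col1 - n)), int(min(row1, col1))
        avals = np.arange(lo, hi + 1)
        pmf = stats.hypergeom.pmf(avals, int(n), int(row1), int(col1))
        supports.append(list(zip(avals - row1 * col1 / n, pmf)))
    p_more = p_equal = 0.0
    for combo in itertools.product(*supports):
        dev = abs(sum(c[0] for c in combo))
        prob = np.prod([c[1] for c in combo])
        if dev > obs + 1e-9:
            p_more += prob
        elif dev > obs - 1e-9:
            p_equal += prob
    return p_more + 0.5 * p_equal


class TestCMHExactOracle:
    @pytest.mark.parametrize("tables", [
        [[[8, 2], [2, 8]]],
        [[[7, 3], [3, 7]], [[6, 4], [4, 6]]],
        [[[5, 5], [5, 5]], [[9, 1], [2, 8]]],
        [[[4, 6], [7, 3]], [[5, 5], [6, 4]], [[8, 2], [3, 7]]],
    ])
    def test_asymptotic_p_within_twofold_of_exact(self, tables):
        _, p = cmh_test(tables)
        p_exact = exact_cmh_midp(tables)
        assert p_exact / 2 <= p <= min(1.0, p_exact * 2)

    def test_random_small_margin_battery(self):
        rng = np.random.default_rng(9)
        checked = 0
        for _ in range(30):
            k = rng.integers(1, 4)
            tables = rng.integers(1, 8, size=(k, 2, 2))  # margins <= 15
            _, p = cmh_test(tables)
            if p > 0.999:  # near-degenerate: both conventions say "null"
                continue
            p_exact = exact_cmh_midp(tables)
            assert p_exact / 2 <= p <= min(1.0, p_exact * 2)
            checked += 1
        assert checked >= 20


class TestThresholdAndIntersection:
    def test_bonferroni_examples(self):
        assert bonferroni_threshold(322595, 3, 0.05) == \
            pytest.approx(5.17e-08, rel=5e-3)
        assert bonferroni_threshold(10, 1, 0.05) == pytest.approx(0.005)
        assert bonferroni_threshold(1, 1, 0.05) == pytest.approx(0.05)
        with pytest.raises(ValueError):
            bonferroni_threshold(0, 3, 0.05)

    def test_intersection_examples(self):
        assert adaptive_loci_intersection([[1, 2, 3], [2, 3], [2, 3, 4]]) == [2, 3]
        assert adaptive_loci_intersection([[1, 2], []]) == []
        assert adaptive_loci_intersection([[3, 1, 2]]) == [3, 1, 2]


class TestAlleleExpressionQC:
    def test_identical_vectors(self):
        p = np.array([0.1, 0.01, 0.5, 0.9, 0.3])
        assert allele_expression_qc(p, p)["r_squared"] == pytest.approx(1.0)

    def test_independent_p_values_near_zero(self):
        rng = np.random.default_rng(5)
        res = allele_expression_qc(rng.uniform(size=10_000),
                                   rng.uniform(size=10_000))
        assert res["r_squared"] < 0.01

    def test_anticorrelated_vectors_sign_blind(self):
        p = np.array([0.1, 0.01, 0.5, 0.9, 0.3])
        q = 10.0 ** (np.log10(p) * -1 - 2)  # -log10 q = -(-log10 p) + 2
        res = allele_expression_qc(p, q)
        assert res["r_squared"] == pytest.approx(1.0)
        assert res["slope"] < 0
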