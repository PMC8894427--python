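"""Variant filtering and replicate-stratified allele-divergence testing.

The filter cascade keeps only sites with complete, well-covered data:
a minimum per-sample coverage (which also removes all missing data), a cap on
sites at multiples of the dataset-wide median depth (collapsed paralogs), and
a minimum number of samples segregating above a pool-aware minor-allele
frequency (0.025 = one heterozygote in a pool of 20 diploids).

Divergence between the two selection lines is scored per generation with the
classic Cochran-Mantel-Haenszel chi-square over the four replicate cultures
(strata), read counts entering the 2x2 tables directly. Sites below the
Bonferroni threshold in every tested generation form the adaptive set.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import GENERATIONS
from .io import AlleleCountTable


@dataclass
class FilterRules:
    """Thresholds of the variant filter cascade."""

    min_variable_samples: int = 4
    min_sample_maf: float = 0.025
    max_depth_factor: float = 3.0
    min_sample_coverage: int = 50
    require_no_missing: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.min_sample_maf < 0.5:
            raise ValueError("min_sample_maf must be in [0, 0.5)")
        if self.max_depth_factor <= 0:
            raise ValueError("max_depth_factor must be positive")
        if self.min_sample_coverage < 0 or self.min_variable_samples < 0:
            raise ValueError("thresholds must be non-negative")


def filter_variants(table: AlleleCountTable, rules: FilterRules | None = None):
    """Apply the filter cascade; returns (filtered table, rejection ledger).

    Rules run in order: (1) per-sample coverage >= min_sample_coverage at
    every sample (zero-depth "missing" samples fall here too); (2) site
    median depth <= max_depth_factor x the dataset-wide median site depth;
    (3) at least min_variable_samples samples with within-sample minor-allele
    read frequency >= min_sample_maf. The ledger counts, per rule, sites
    removed by that rule among survivors of the previous rules and sums to
    input - output.
    """
    rules = rules or FilterRules()
    if table.n_sites == 0:
        raise ValueError("empty allele count table")
    depth = table.depth
    ledger = {}

    keep = (depth >= rules.min_sample_coverage).all(axis=1)
    ledger["low_coverage_or_missing"] = int((~keep).sum())

    site_median = np.median(depth, axis=1)
    dataset_median = float(np.median(site_median))
    high = site_median > rules.max_depth_factor * dataset_median
    drop = keep & high
    ledger["excess_depth"] = int(drop.sum())
    keep &= ~high

    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(depth > 0, table.alt_counts / depth, 0.0)
    maf = np.minimum(af, 1.0 - af)
    n_variable = (maf >= rules.min_sample_maf).sum(axis=1)
    low_var = n_variable < rules.min_variable_samples
    drop = keep & low_var
    ledger["too_few_variable_samples"] = int(drop.sum())
    keep &= ~low_var

    out = table.subset_sites(np.flatnonzero(keep))
    ledger["input_sites"] = table.n_sites
    ledger["output_sites"] = out.n_sites
    if out.n_sites == 0:
        ledger["all_sites_removed"] = 1
    return out, ledger


# ---------------------------------------------------------------------------
# Cochran-Mantel-Haenszel


def cmh_components(a, b, c, d):
    """Per-stratum numerator terms and variances of the CMH statistic.

    The 2x2 table per stratum is [[a, b], [c, d]] (rows alleles, columns
    lines). Strata with any zero margin contribute zero to both sums.
    """
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    row1, row2 = a + b, c + d
    col1, col2 = a + c, b + d
    n = row1 + row2
    ok = (row1 > 0) & (row2 > 0) & (col1 > 0) & (col2 > 0) & (n > 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        e = row1 * col1 / n
        v = row1 * row2 * col1 * col2 / (n**2 * (n - 1.0))
    num = np.where(ok, a - e, 0.0)
    var = np.where(ok, v, 0.0)
    return num, var


def cmh_test(tables) -> tuple[float, float]:
    """Classic CMH chi-square (1 df, no continuity correction) for one site.

    ``tables`` is (R, 2, 2): R replicate strata of allele x line counts.
    All-degenerate strata give statistic 0, p = 1.
    """
    t = np.asarray(tables, dtype=float)
    if t.ndim == 2:
        t = t[None]
    num, var = cmh_components(t[:, 0, 0], t[:, 0, 1], t[:, 1, 0], t[:, 1, 1])
    v = var.sum()
    if v == 0:
        return 0.0, 1.0
    stat = num.sum() ** 2 / v
    return float(stat), float(stats.chi2.sf(stat, df=1))


def cmh_scan(table: AlleleCountTable, generation: str,
             line1: str = "AM", line2: str = "OWA") -> pd.DataFrame:
    """Vectorized CMH over all sites for home-line divergence in one generation.

    Stratifies by replicate, comparing ``line1`` in its home environment with
    ``line2`` in its home environment (alt/ref read counts as table entries).
    Returns per-site statistic, p-value and the mean allele-frequency
    difference across strata.
    """
    design = table.design
    idx1 = [design.indices(line=line1, environment=line1, generation=generation,
                           replicate=r) for r in (1, 2, 3, 4)]
    idx2 = [design.indices(line=line2, environment=line2, generation=generation,
                           replicate=r) for r in (1, 2, 3, 4)]
    strata = [(i1, i2) for i1, i2 in zip(idx1, idx2) if len(i1) and len(i2)]
    if not strata:
        raise ValueError(f"no replicate strata for generation {generation}")
    n_sites = table.n_sites
    num = np.zeros(n_sites)
    var = np.zeros(n_sites)
    afd = np.zeros(n_sites)
    for i1, i2 in strata:
        a = table.alt_counts[:, i1].sum(axis=1)
        b = table.alt_counts[:, i2].sum(axis=1)
        c = table.ref_counts[:, i1].sum(axis=1)
        d = table.ref_counts[:, i2].sum(axis=1)
        nu, va = cmh_components(a, b, c, d)
        num += nu
        var += va
        with np.errstate(invalid="ignore", divide="ignore"):
            f1 = np.where(a + c > 0, a / (a + c), np.nan)
            f2 = np.where(b + d > 0, b / (b + d), np.nan)
        afd += np.nan_to_num(f1 - f2)
    afd /= len(strata)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(var > 0, num**2 / var, 0.0)
    p = np.where(var > 0, stats.chi2.sf(stat, df=1), 1.0)
    out = table.sites[["contig", "pos"]].copy()
    out["statistic"] = stat
    out["p_value"] = p
    out["mean_af_diff"] = afd
    out["generation"] = generation
    return out


def bonferroni_threshold(n_snps: int, n_tests_per_snp: int, alpha: float) -> float:
    """Family-wise threshold alpha / (n_snps * n_tests_per_snp)."""
    if n_snps <= 0 or n_tests_per_snp <= 0:
        raise ValueError("counts must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / (n_snps * n_tests_per_snp)


def adaptive_loci_intersection(significant_sets) -> list:
    """Order-preserving intersection of per-generation significant site sets."""
    sets = [list(s) for s in significant_sets]
    if not sets:
        raise ValueError("need at least one significant set")
    common = set(sets[0])
    for s in sets[1:]:
        common &= set(s)
    return [x for x in sets[0] if x in common]


def allele_expression_qc(cmh_p, de_p) -> dict:
    """OLS R-squared between -log10 allelic and expression p-values per gene.

    A near-zero R-squared indicates allele-frequency estimates are not driven
    by expression differences. Returns slope and R2 (NaN when degenerate).
    """
    x = -np.log10(np.asarray(cmh_p, dtype=float))
    y = -np.log10(np.asarray(de_p, dtype=float))
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 genes with both statistics")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"r_squared": float("nan"), "slope": float("nan"), "n": len(x)}
    res = stats.linregress(x, y)
    return {"r_squared": float(res.rvalue**2), "slope": float(res.slope), "n": len(x)}


def adaptive_scan(table: AlleleCountTable, alpha: float = 0.05,
                  generations=GENERATIONS) -> dict:
    """Full divergence analysis: per-generation CMH + Bonferroni intersection."""
    per_gen = {g: cmh_scan(table, g) for g in generations}
    thr = bonferroni_threshold(table.n_sites, len(per_gen), alpha)
    sig_sets = [list(np.flatnonzero(per_gen[g]["p_value"].to_numpy() < thr))
                for g in per_gen]
    adaptive = adaptive_loci_intersection(sig_sets)
    return {"per_generation": per_gen, "threshold": thr,
            "significant_sets": dict(zip(per_gen, sig_sets)),
            "adaptive_set": adaptive}
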