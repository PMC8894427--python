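"""Rank-based (Mann-Whitney) functional enrichment without a significance
threshold.

Each functional category is tested for whether its genes' statistics fall
toward one tail of the genome-wide distribution: one-sided Mann-Whitney U of
in-category vs all other genes, exact enumeration for small categories
(both group sizes <= 8, no ties) and a tie- and continuity-corrected normal
approximation otherwise, with BH adjustment across categories. Categories are flat sets;
no ontology-graph propagation or merging is performed.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def collapse_snp_stats(snp_p: pd.Series, snp_to_gene: pd.Series) -> pd.Series:
    """Collapse per-SNP p-values to one statistic per gene.

    The gene statistic is -log10 of the minimum p over the gene's SNPs.
    Genes without SNPs are absent. ``snp_p`` and ``snp_to_gene`` are aligned
    by index (SNP identifier).
    """
    df = pd.DataFrame({"p": snp_p, "gene": snp_to_gene}).dropna()
    minp = df.groupby("gene")["p"].min()
    return -np.log10(minp)


def _mwu_one_sided(in_cat: np.ndarray, rest: np.ndarray, direction: str,
                   method: str | None = None):
    """One-sided MWU p; exact when both sizes <= 8 and values untied."""
    alternative = "less" if direction == "low" else "greater"
    pooled = np.concatenate([in_cat, rest])
    no_ties = len(np.unique(pooled)) == len(pooled)
    if method is None:
        method = "exact" if (len(in_cat) <= 8 and len(rest) <= 8 and no_ties) \
            else "asymptotic"
    res = stats.mannwhitneyu(in_cat, rest, alternative=alternative,
                             method=method)
    return float(res.statistic), float(res.pvalue)


def go_mwu_test(gene_stats: pd.Series, category_map: pd.DataFrame,
                direction: str = "low", min_category_size: int = 5) -> pd.DataFrame:
    """Rank-based enrichment of every category against the background.

    ``gene_stats`` is indexed by gene_id; ``category_map`` has columns
    gene_id and category_id (one row per pair). ``direction`` "low" asks
    whether category genes have disproportionately low statistics, "high"
    the opposite. Categories smaller than ``min_category_size`` (after
    restricting to scored genes) or spanning all genes are excluded.
    """
    if direction not in ("low", "high"):
        raise ValueError("direction must be 'low' or 'high'")
    stats_map = gene_stats.dropna()
    scored = set(stats_map.index)
    cm = category_map[category_map["gene_id"].isin(scored)]
    rows = []
    for cat, grp in cm.groupby("category_id"):
        genes = set(grp["gene_id"])
        if len(genes) < min_category_size or len(genes) >= len(scored):
            continue
        in_cat = stats_map.loc[sorted(genes)].to_numpy()
        rest = stats_map.drop(index=sorted(genes)).to_numpy()
        u, p = _mwu_one_sided(in_cat, rest, direction)
        rows.append({"category_id": cat, "n_genes": len(genes),
                     "statistic": u, "p": p, "direction": direction})
    if len(rows) < 2:
        raise ValueError("need >= 2 categories after size filtering")
    out = pd.DataFrame(rows)
    out["padj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out.sort_values("p", kind="stable").reset_index(drop=True)
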