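"""Pooled nucleotide diversity in non-overlapping windows and tests for
targeted diversity loss.

Per-site diversity is the unbiased read-pair heterozygosity
2*ref*alt / (C*(C-1)): the probability that two distinct reads drawn from
the pool differ. Window diversity sums site values over a window and divides
by the full window length (invariant sites contribute zero). Median per-
replicate diversity is compared across treatment x generation cells by
one-way ANOVA with Tukey HSD; targeted loss is tested by comparing the
change in window diversity (relative to the ambient-control baseline)
between windows containing adaptive SNPs and all other windows with two-
sided rank-sum tests, Bonferroni-corrected across cells.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .io import AlleleCountTable


def site_pi(ref_count, alt_count):
    """Unbiased per-site heterozygosity from read counts.

    pi = 2*ref*alt / (C*(C-1)) with C = ref+alt; NaN where C < 2 (site
    unusable at that coverage).
    """
    ref = np.asarray(ref_count, dtype=float)
    alt = np.asarray(alt_count, dtype=float)
    c = ref + alt
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * ref * alt / (c * (c - 1.0))
    return np.where(c >= 2, pi, np.nan)


def window_pi(table: AlleleCountTable, window_size: int = 100,
              adaptive_sites: np.ndarray | None = None,
              pool_correction: bool = False, pool_size: int = 20) -> pd.DataFrame:
    """Per-sample window diversity over non-overlapping tiles.

    Windows tile each contig [0, w), [w, 2w), ... (0-based half-open); a
    1-based site at position p falls in window (p-1)//w. Sites with coverage
    < 2 in a sample are skipped for that sample. The optional n/(n-1) pool
    correction (n = 2*pool_size chromosomes) rescales toward the population
    heterozygosity; it is off by default because it cancels in the
    delta-diversity contrasts.

    Returns a long DataFrame: contig, start, end, sample, pi,
    n_variant_sites, adaptive_flag.
    """
    pi = site_pi(table.ref_counts, table.alt_counts)
    if pool_correction:
        n_chr = 2 * pool_size
        pi = pi * n_chr / (n_chr - 1.0)
    sites = table.sites
    win_idx = (sites["pos"].to_numpy() - 1) // window_size
    adaptive = np.zeros(table.n_sites, dtype=bool)
    if adaptive_sites is not None and len(adaptive_sites):
        adaptive[np.asarray(adaptive_sites, dtype=int)] = True
    samples = table.design.sample_ids

    rows = []
    key = pd.DataFrame({"contig": sites["contig"], "win": win_idx,
                        "adaptive": adaptive})
    for (contig, win), grp in key.groupby(["contig", "win"], sort=True):
        idx = grp.index.to_numpy()
        sub = pi[idx]
        variant = (table.ref_counts[idx] > 0) & (table.alt_counts[idx] > 0)
        win_pi = np.nansum(sub, axis=0) / window_size
        n_var = (variant & np.isfinite(sub)).sum(axis=0)
        flag = bool(grp["adaptive"].any())
        for j, s in enumerate(samples):
            rows.append({"contig": contig, "start": int(win) * window_size,
                         "end": (int(win) + 1) * window_size, "sample": s,
                         "pi": float(win_pi[j]), "n_variant_sites": int(n_var[j]),
                         "adaptive_flag": flag})
    return pd.DataFrame(rows)


def replicate_median_pi(windows: pd.DataFrame, design) -> pd.DataFrame:
    """Median window diversity per sample, annotated with its design cell."""
    med = windows.groupby("sample")["pi"].median().rename("median_pi").reset_index()
    t = design.table.rename(columns={"sample_id": "sample"})
    out = med.merge(t, on="sample")
    out["cell"] = out["line"] + "_" + out["environment"] + "_" + out["generation"]
    return out


def _letter_groups(labels, sig_pairs) -> dict:
    """Compact letter display: groups sharing a letter are not significantly
    different (greedy insert-and-absorb)."""
    letters = {lab: set() for lab in labels}
    groups: list[set] = []
    for lab in labels:
        placed = False
        for g in groups:
            if all((min(lab, o), max(lab, o)) not in sig_pairs for o in g):
                g.add(lab)
                placed = True
        if not placed:
            groups.append({lab})
    groups = [g for i, g in enumerate(groups)
              if not any(g < h for j, h in enumerate(groups) if i != j)]
    for i, g in enumerate(groups):
        for lab in g:
            letters[lab].add(chr(ord("a") + i))
    return {lab: "".join(sorted(v)) for lab, v in letters.items()}


def median_pi_tests(median_pi: pd.DataFrame, group_col: str = "cell",
                    value_col: str = "median_pi", alpha: float = 0.05) -> dict:
    """One-way ANOVA over cells plus all pairwise Tukey HSD comparisons."""
    groups = [g[value_col].to_numpy() for _, g in median_pi.groupby(group_col)]
    labels = [lab for lab, _ in median_pi.groupby(group_col)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 replicates each")
    if all(np.ptp(g) == 0 for g in groups):
        raise ValueError("zero within-group variance everywhere")
    f, p = stats.f_oneway(*groups)
    tk = pairwise_tukeyhsd(median_pi[value_col].to_numpy(),
                           median_pi[group_col].to_numpy(), alpha=alpha)
    pairs = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    sig = {(min(r["group1"], r["group2"]), max(r["group1"], r["group2"]))
           for _, r in pairs.iterrows() if r["reject"]}
    return {"anova_f": float(f), "anova_p": float(p), "tukey": pairs,
            "letters": _letter_groups(labels, sig)}


def delta_pi_by_class(windows: pd.DataFrame, design,
                      baseline=("AM", "AM", "F1")) -> dict:
    """Change in window diversity vs the baseline cell, by adaptive class.

    Delta pi(window, cell) = mean-over-replicates pi(cell) - mean pi
    (baseline). Per non-baseline cell, a two-sided rank-sum test compares
    adaptive-window deltas with non-adaptive-window deltas; Bonferroni
    correction across the cells tested. Cells with < 2 windows in either
    class are skipped with a flag.
    """
    t = design.table.rename(columns={"sample_id": "sample"})
    w = windows.merge(t[["sample", "line", "environment", "generation"]], on="sample")
    w["cell"] = list(zip(w["line"], w["environment"], w["generation"]))
    mean_pi = (w.groupby(["contig", "start", "cell"], sort=False)
               .agg(pi=("pi", "mean"), adaptive_flag=("adaptive_flag", "first"))
               .reset_index())
    base = mean_pi[mean_pi["cell"] == tuple(baseline)]
    if base.empty:
        raise ValueError(f"baseline cell {baseline} absent")
    base = base.set_index(["contig", "start"])["pi"]

    delta_rows, tests = [], []
    cells = [c for c in mean_pi["cell"].unique() if c != tuple(baseline)]
    for cell in cells:
        sub = mean_pi[mean_pi["cell"] == cell].set_index(["contig", "start"])
        common = sub.index.intersection(base.index)
        sub = sub.loc[common]
        delta = sub["pi"] - base.loc[common]
        adaptive = sub["adaptive_flag"].to_numpy(dtype=bool)
        for (contig, start), d, a in zip(common, delta, adaptive):
            delta_rows.append({"contig": contig, "start": start,
                               "cell": "_".join(map(str, cell)), "delta_pi": d,
                               "class": "adaptive" if a else "non-adaptive"})
        da, dn = delta[adaptive], delta[~adaptive]
        if len(da) < 2 or len(dn) < 2:
            tests.append({"cell": "_".join(map(str, cell)), "skipped": True,
                          "p": np.nan, "p_bonferroni": np.nan,
                          "mean_delta_adaptive": np.nan,
                          "mean_delta_nonadaptive": np.nan})
            continue
        u, p = stats.mannwhitneyu(da, dn, alternative="two-sided")
        tests.append({"cell": "_".join(map(str, cell)), "skipped": False,
                      "statistic": float(u), "p": float(p),
                      "mean_delta_adaptive": float(da.mean()),
                      "mean_delta_nonadaptive": float(dn.mean())})
    tests = pd.DataFrame(tests)
    n_tested = int((~tests["skipped"]).sum()) if "skipped" in tests else 0
    if n_tested:
        tests["p_bonferroni"] = np.minimum(tests["p"] * n_tested, 1.0)
    return {"delta": pd.DataFrame(delta_rows), "tests": tests}


def gene_delta_pi(delta: pd.DataFrame, cell: str) -> pd.Series:
    """Per-gene (contig) mean change in diversity for one cell, for
    enrichment scans."""
    sub = delta[delta["cell"] == cell]
    return sub.groupby("contig")["delta_pi"].mean()
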