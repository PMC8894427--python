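"""Expression filtering, normalization, differential expression, and
plasticity partitioning.

Differential expression uses a negative-binomial log-linear model fitted per
gene by iteratively reweighted least squares, with a method-of-moments
dispersion estimate shrunk 50% toward a log-linear mean-dispersion trend
(moment-matched on the ratio scale to undo the Jensen bias of the log fit)
and a Wald test on the group contrast; p-values are Benjamini-Hochberg
adjusted across genes. This is a deliberately simple, fully documented NB GLM — not a
re-implementation of any particular reference tool.

Plastic gene sets are the within-line home-vs-transplant contrasts; the
plasticity-only (PO) vs genetic-change (GC) partition classifies genes that
diverged between the two home lines by whether the transplanted line reaches
the destination expression state without heritable change (PO) or not (GC).
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, SampleDesign

_DISP_FLOOR = 1e-8
_MAX_LOG_LFC = 20.0  # natural-log bound on the IRLS coefficient


def contrast_label(cell1: tuple[str, str], cell2: tuple[str, str]) -> str:
    return f"{cell1[0]}_{cell1[1]}_vs_{cell2[0]}_{cell2[1]}"


def filter_low_expression(expr: ExpressionMatrix, min_count: int = 10,
                          max_low_fraction: float = 0.9) -> ExpressionMatrix:
    """Drop genes whose counts are < min_count in more than max_low_fraction
    of samples."""
    low_frac = (expr.counts < min_count).mean(axis=1)
    keep = low_frac <= max_low_fraction
    return ExpressionMatrix(expr.gene_ids[keep], expr.counts[keep], expr.design)


def normalize_and_transform(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Median-of-ratios size factors and a log2(normalized + 1) transform.

    The reference per gene is the geometric mean across samples, computed
    over genes with all-positive counts; each sample's size factor is the
    median ratio of its counts to that reference.
    """
    counts = expr.counts.astype(float)
    if (counts.sum(axis=0) == 0).any():
        raise ValueError("sample with all-zero counts cannot be normalized")
    allpos = (counts > 0).all(axis=1)
    if not allpos.any():
        raise ValueError("cannot form reference: no gene with all-positive counts")
    logc = np.log(counts[allpos])
    log_ref = logc.mean(axis=1)
    sf = np.exp(np.median(logc - log_ref[:, None], axis=0))
    transformed = np.log2(counts / sf[None, :] + 1.0)
    return ExpressionMatrix(expr.gene_ids, expr.counts, expr.design,
                            size_factors=sf, transformed=transformed)


# ---------------------------------------------------------------------------
# NB GLM differential expression


def _dispersion_mom(norm_counts: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Method-of-moments NB dispersion (alpha, variance = mu + alpha mu^2),
    pooled within groups, shrunk 50% toward a log-linear trend on the mean."""
    means = norm_counts.mean(axis=1)
    var_within = np.zeros(norm_counts.shape[0])
    dof = 0
    for g in np.unique(groups):
        sub = norm_counts[:, groups == g]
        if sub.shape[1] > 1:
            var_within += sub.var(axis=1, ddof=1) * (sub.shape[1] - 1)
            dof += sub.shape[1] - 1
    var_within = var_within / max(dof, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = (var_within - means) / means**2
    raw = np.where(np.isfinite(raw), raw, _DISP_FLOOR)
    raw = np.maximum(raw, _DISP_FLOOR)

    informative = (raw > 1e-6) & (means > 1)
    log_m, log_a = np.log(means[informative]), np.log(raw[informative])
    if informative.sum() >= 10 and np.ptp(log_m) > 0:
        slope, intercept = np.polyfit(log_m, log_a, 1)
        with np.errstate(divide="ignore"):
            trend = np.exp(intercept + slope * np.log(np.maximum(means, 1e-8)))
        # the log-scale fit is Jensen-biased low for noisy per-gene
        # estimates; moment-match the trend on the ratio scale
        trend = np.maximum(trend, _DISP_FLOOR)
        trend *= np.mean(raw[informative] / trend[informative])
    else:
        trend = np.full_like(raw, max(np.mean(raw), _DISP_FLOOR))
    trend = np.maximum(trend, _DISP_FLOOR)
    return np.exp(0.5 * np.log(raw) + 0.5 * np.log(trend))


def _nb_irls_two_group(y: np.ndarray, x: np.ndarray, offset: np.ndarray,
                       alpha: np.ndarray, max_iter: int = 50, tol: float = 1e-8):
    """Vectorized two-group NB IRLS across genes.

    y is (G, n), x is (n,) in {0,1}, offset (n,) on the natural-log scale,
    alpha (G,) NB dispersions. Returns (b0, b1, se_b1, converged), natural
    log scale.
    """
    G, n = y.shape
    eps = 1e-8
    q = y / np.exp(offset)[None, :]
    m0 = q[:, x == 0].mean(axis=1) + eps
    m1 = q[:, x == 1].mean(axis=1) + eps
    b0 = np.log(m0)
    b1 = np.log(m1) - np.log(m0)
    converged = np.zeros(G, dtype=bool)
    se_b1 = np.full(G, np.nan)
    for _ in range(max_iter):
        eta = b0[:, None] + b1[:, None] * x[None, :] + offset[None, :]
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha[:, None] * mu)
        z = (eta - offset[None, :]) + (y - mu) / mu
        S0 = w.sum(axis=1)
        S1 = (w * x[None, :]).sum(axis=1)
        T0 = (w * z).sum(axis=1)
        T1 = (w * x[None, :] * z).sum(axis=1)
        det = S0 * S1 - S1**2  # S2 == S1 for binary x
        det = np.where(np.abs(det) < 1e-12, np.nan, det)
        new_b1 = (S0 * T1 - S1 * T0) / det
        new_b0 = (T0 - S1 * new_b1) / S0
        new_b1 = np.clip(new_b1, -_MAX_LOG_LFC, _MAX_LOG_LFC)
        step = np.maximum(np.abs(new_b0 - b0), np.abs(new_b1 - b1))
        b0, b1 = np.where(np.isfinite(new_b0), new_b0, b0), \
            np.where(np.isfinite(new_b1), new_b1, b1)
        just = step < tol
        converged |= np.where(np.isfinite(step), just, False)
        if converged.all():
            break
    eta = np.clip(b0[:, None] + b1[:, None] * x[None, :] + offset[None, :], -30, 30)
    mu = np.exp(eta)
    w = mu / (1.0 + alpha[:, None] * mu)
    S0 = w.sum(axis=1)
    S1 = (w * x[None, :]).sum(axis=1)
    det = S0 * S1 - S1**2
    with np.errstate(invalid="ignore", divide="ignore"):
        se_b1 = np.sqrt(np.where(det > 0, S0 / det, np.nan))
    converged &= np.isfinite(se_b1) & (np.abs(b1) < _MAX_LOG_LFC)
    return b0, b1, se_b1, converged


def de_test(expr: ExpressionMatrix, cell1: tuple[str, str],
            cell2: tuple[str, str], generation: str) -> pd.DataFrame:
    """NB Wald differential expression between two design cells.

    The reported log2 fold change is cell2 relative to cell1. Genes whose
    fit does not converge get missing p-values and are excluded from the BH
    denominator.
    """
    if expr.size_factors is None:
        expr = normalize_and_transform(expr)
    design = expr.design
    i1 = design.indices(line=cell1[0], environment=cell1[1], generation=generation)
    i2 = design.indices(line=cell2[0], environment=cell2[1], generation=generation)
    if len(i1) < 2 or len(i2) < 2:
        raise ValueError("need >= 2 samples per contrasted cell")
    idx = np.concatenate([i1, i2])
    y = expr.counts[:, idx].astype(float)
    x = np.concatenate([np.zeros(len(i1)), np.ones(len(i2))])
    offset = np.log(expr.size_factors[idx])
    norm = y / np.exp(offset)[None, :]
    alpha = _dispersion_mom(norm, x)
    b0, b1, se, conv = _nb_irls_two_group(y, x, offset, alpha)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = b1 / se
    p = np.where(conv, 2.0 * stats.norm.sf(np.abs(z)), np.nan)
    padj = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        padj[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return pd.DataFrame({
        "gene_id": expr.gene_ids,
        "lfc": b1 / np.log(2.0),
        "p": p,
        "padj": padj,
        "converged": conv,
        "contrast": contrast_label(cell1, cell2),
        "generation": generation,
    })


STANDARD_CONTRASTS = (
    (("AM", "AM"), ("AM", "OWA")),      # AM-line plasticity
    (("OWA", "OWA"), ("OWA", "AM")),    # OWA-line plasticity
    (("AM", "AM"), ("OWA", "OWA")),     # home-vs-home divergence
    (("AM", "OWA"), ("OWA", "OWA")),    # forward transplant vs destination
    (("OWA", "AM"), ("AM", "AM")),      # reverse transplant vs destination
)


def run_de_suite(expr: ExpressionMatrix, generation: str,
                 contrasts=STANDARD_CONTRASTS) -> dict[str, pd.DataFrame]:
    """All standard contrasts for one generation, keyed by contrast label."""
    if expr.size_factors is None:
        expr = normalize_and_transform(expr)
    return {contrast_label(c1, c2): de_test(expr, c1, c2, generation)
            for c1, c2 in contrasts}


def _sig_genes(de: pd.DataFrame, alpha: float) -> set:
    return set(de.loc[de["padj"] < alpha, "gene_id"])


def plastic_gene_sets(de_results: dict[str, pd.DataFrame], alpha: float = 0.05):
    """Per-line plastic gene sets and their fold-ratio of sizes (AM / OWA)."""
    am = _sig_genes(de_results["AM_AM_vs_AM_OWA"], alpha)
    owa = _sig_genes(de_results["OWA_OWA_vs_OWA_AM"], alpha)
    ratio = len(am) / len(owa) if owa else float("inf")
    return {"AM": am, "OWA": owa, "ratio": ratio,
            "ratio_infinite": not owa and bool(am)}


def classify_po_gc(de_results: dict[str, pd.DataFrame], direction: str,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Partition home-line-divergent genes into plasticity-only vs genetic
    change.

    direction "forward" follows the ancestral line into the novel conditions
    (AM -> OWA): over genes differentially expressed between the two home
    lines, a gene is GC when the transplanted line still differs from its
    destination home line (AM_OWA vs OWA_OWA), PO when it is plastic within
    the source line (AM_AM vs AM_OWA) and not GC; otherwise unclassified.
    "reverse" mirrors this for OWA -> AM. PO and GC are mutually exclusive
    and do not exhaust the eligible set.
    """
    if direction == "forward":
        plastic_key, gc_key = "AM_AM_vs_AM_OWA", "AM_OWA_vs_OWA_OWA"
    elif direction == "reverse":
        plastic_key, gc_key = "OWA_OWA_vs_OWA_AM", "OWA_AM_vs_AM_AM"
    else:
        raise ValueError("direction must be 'forward' or 'reverse'")
    for key in ("AM_AM_vs_OWA_OWA", plastic_key, gc_key):
        if key not in de_results:
            raise ValueError(f"missing contrast: {key}")
    eligible = _sig_genes(de_results["AM_AM_vs_OWA_OWA"], alpha)
    plastic = _sig_genes(de_results[plastic_key], alpha)
    gc = _sig_genes(de_results[gc_key], alpha)
    rows = []
    gen = de_results["AM_AM_vs_OWA_OWA"]["generation"].iloc[0]
    for g in sorted(eligible):
        if g in gc:
            cls = "GC"
        elif g in plastic:
            cls = "PO"
        else:
            cls = "unclassified"
        rows.append({"gene_id": g, "direction": direction, "generation": gen,
                     "class": cls})
    out = pd.DataFrame(rows, columns=["gene_id", "direction", "generation", "class"])
    po_set = set(out.loc[out["class"] == "PO", "gene_id"])
    gc_set = set(out.loc[out["class"] == "GC", "gene_id"])
    assert not (po_set & gc_set)
    assert (po_set | gc_set) <= eligible
    return out


def lfc_slope(lfc_line1, lfc_line2, gene_mask=None) -> dict:
    """OLS slope of line-2 log2 fold changes on line-1 log2 fold changes.

    A slope of 1 means equal plastic responses in the two lines; the masked
    gene set is typically "differentially expressed in one or both lines".
    """
    x = np.asarray(lfc_line1, dtype=float)
    y = np.asarray(lfc_line2, dtype=float)
    if gene_mask is not None:
        mask = np.asarray(gene_mask, dtype=bool)
        x, y = x[mask], y[mask]
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 genes in the mask")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x: slope undefined")
    res = stats.linregress(x, y)
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "n": int(len(x)), "r_squared": float(res.rvalue**2)}
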