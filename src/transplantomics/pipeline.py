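"""End-to-end orchestration: run every analysis stage and write result
tables plus a manifest.

Stage order mirrors the analysis flow: variant filtering -> per-generation
CMH divergence and the adaptive-locus intersection -> per-generation
expression filtering, differential expression, plastic sets, PO/GC
partition and the plasticity slope -> DAPC coordinates and transplant-shift
inference (expression and allele-frequency spaces) -> windowed nucleotide
diversity, median tests and targeted-loss tests -> rank-based enrichment ->
life-history lambda table and log-rank survivorship comparisons.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import dapc, diversity, enrich, expression, lifehistory, variants
from .config import GENERATIONS, RunConfig, child_seed
from .io import ExpressionMatrix, load_experiment


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write(df: pd.DataFrame, path: Path, manifest: list) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
    manifest.append({"file": path.name, "rows": len(df)})


def run_pipeline(config: RunConfig, input_dir, output_dir) -> pd.DataFrame:
    """Run every stage on an input directory; returns the output manifest."""
    input_dir, output_dir = Path(input_dir), Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - reported with stage name
                raise PipelineStageError(name, exc) from exc
        return deco

    @stage("load")
    def loaded():
        return load_experiment(input_dir / "counts.sync",
                               input_dir / "expression.tsv",
                               input_dir / "design.tsv", config)

    counts, expr, design, _ = loaded

    @stage("filter_variants")
    def filtered():
        table, ledger = variants.filter_variants(counts)
        led = pd.DataFrame([{"rule": k, "count": v} for k, v in ledger.items()])
        _write(led, output_dir / "filter_ledger.tsv", manifest)
        _write(table.sites, output_dir / "filtered_sites.tsv", manifest)
        return table

    @stage("cmh")
    def scan():
        gens = GENERATIONS[: config.n_generations_tested]
        if config.alpha >= 1.0:  # degenerate pass-through threshold
            per_gen = {g: variants.cmh_scan(filtered, g) for g in gens}
            thr = config.alpha
            sig = [list(np.flatnonzero(per_gen[g]["p_value"].to_numpy() < thr))
                   for g in gens]
            res = {"per_generation": per_gen, "threshold": thr,
                   "significant_sets": dict(zip(gens, sig)),
                   "adaptive_set": variants.adaptive_loci_intersection(sig)}
        else:
            res = variants.adaptive_scan(filtered, config.alpha, gens)
        for g, df in res["per_generation"].items():
            _write(df, output_dir / f"cmh_{g}.tsv", manifest)
        adaptive = pd.DataFrame({"site_index": res["adaptive_set"]})
        adaptive = adaptive.join(
            filtered.sites.iloc[res["adaptive_set"]].reset_index(drop=True))
        _write(adaptive, output_dir / "adaptive_loci.tsv", manifest)
        return res

    de_by_gen: dict[str, dict[str, pd.DataFrame]] = {}
    expr_by_gen: dict[str, ExpressionMatrix] = {}

    @stage("differential_expression")
    def _de():
        for g in GENERATIONS:
            idx = design.indices(generation=g)
            sub = ExpressionMatrix(expr.gene_ids, expr.counts[:, idx],
                                   design.subset(np.array(design.sample_ids)[idx]))
            sub = expression.filter_low_expression(sub)
            sub = expression.normalize_and_transform(sub)
            expr_by_gen[g] = sub
            de = expression.run_de_suite(sub, g)
            de_by_gen[g] = de
            _write(pd.concat(de.values(), ignore_index=True),
                   output_dir / f"de_{g}.tsv", manifest)


    @stage("plasticity")
    def _plast():
        rows, cls_rows, slope_rows = [], [], []
        for g in GENERATIONS:
            de = de_by_gen[g]
            sets = expression.plastic_gene_sets(de, config.de_alpha)
            rows.append({"generation": g, "n_am_plastic": len(sets["AM"]),
                         "n_owa_plastic": len(sets["OWA"]),
                         "ratio_am_owa": sets["ratio"]})
            for direction in ("forward", "reverse"):
                cls_rows.append(expression.classify_po_gc(de, direction,
                                                          config.de_alpha))
            am = de["AM_AM_vs_AM_OWA"].set_index("gene_id")
            owa = de["OWA_OWA_vs_OWA_AM"].set_index("gene_id")
            mask = ((am["padj"] < config.de_alpha)
                    | (owa["padj"] < config.de_alpha)).to_numpy()
            if mask.sum() >= 3:
                # orient the second line as home/transplant so equal plasticity
                # gives slope 1 and a shared transplant response gives -1
                fit = expression.lfc_slope(am["lfc"].to_numpy(),
                                           -owa["lfc"].to_numpy(), mask)
                slope_rows.append({"generation": g, **fit})
        _write(pd.DataFrame(rows), output_dir / "plastic_sets.tsv", manifest)
        _write(pd.concat(cls_rows, ignore_index=True),
               output_dir / "po_gc_classes.tsv", manifest)
        _write(pd.DataFrame(slope_rows), output_dir / "lfc_slopes.tsv", manifest)


    @stage("dapc")
    def _dapc():
        coord_rows, inf_rows = [], []
        freqs = filtered.allele_frequencies()
        for g in GENERATIONS:
            for kind, n_pcs in (("expression", config.n_pcs_expression),
                                ("allele_freq", config.n_pcs_allele)):
                if kind == "expression":
                    sub = expr_by_gen[g]
                    feats = sub.transformed.T
                    dsub = sub.design
                    coords, model = dapc.dapc_coordinates(feats, dsub, g, n_pcs)
                else:
                    idx = design.indices(generation=g)
                    feats = np.nan_to_num(freqs[:, idx].T, nan=0.5)
                    dsub = design.subset(np.array(design.sample_ids)[idx])
                    coords, model = dapc.dapc_coordinates(feats, dsub, g, n_pcs)
                coords["data_type"] = kind
                coord_rows.append(coords)
                inf = dapc.shift_inference(
                    coords, n_draws=config.mcmc_draws,
                    seed=child_seed(config.seed, f"dapc_{kind}_{g}"))
                for line in ("AM", "OWA", "magnitude_difference"):
                    inf_rows.append({"generation": g, "data_type": kind,
                                     "effect": line, **inf[line],
                                     "variance_fraction": model.variance_fraction})
        _write(pd.concat(coord_rows, ignore_index=True),
               output_dir / "dapc_coordinates.tsv", manifest)
        _write(pd.DataFrame(inf_rows), output_dir / "dapc_shifts.tsv", manifest)


    @stage("diversity")
    def _pi():
        adaptive_sites = np.asarray(scan["adaptive_set"], dtype=int)
        windows = diversity.window_pi(filtered, config.window_size,
                                      adaptive_sites=adaptive_sites)
        med = diversity.replicate_median_pi(windows, design)
        _write(med, output_dir / "median_pi.tsv", manifest)
        tests = diversity.median_pi_tests(med)
        _write(tests["tukey"], output_dir / "pi_tukey.tsv", manifest)
        dres = diversity.delta_pi_by_class(windows, design)
        _write(dres["tests"], output_dir / "delta_pi_tests.tsv", manifest)
        _write(dres["delta"], output_dir / "delta_pi.tsv", manifest)
        return {"windows": windows, "delta": dres}

    pi_res = _pi

    @stage("allele_expression_qc")
    def _qc():
        # independence of allelic and expression signals: per-gene minimum
        # CMH p vs home-line DE p; near-zero R2 means allele-frequency
        # estimates are not driven by expression differences
        rows = []
        for g in GENERATIONS[: config.n_generations_tested]:
            cmh = scan["per_generation"][g]
            gene_p = cmh.groupby(filtered.sites["contig"])["p_value"].min()
            de = de_by_gen[g]["AM_AM_vs_OWA_OWA"].set_index("gene_id")["p"]
            common = gene_p.index.intersection(de.dropna().index)
            if len(common) < 3:
                continue
            res = variants.allele_expression_qc(gene_p.loc[common],
                                                de.loc[common])
            rows.append({"generation": g, **res})
        _write(pd.DataFrame(rows), output_dir / "allele_expression_qc.tsv",
               manifest)

    go_path = input_dir / "go_map.tsv"
    if go_path.exists():
        @stage("enrichment")
        def _enrich():
            go = pd.read_csv(go_path, sep="\t")
            out = []
            # allelic divergence: per-gene minimum CMH p at F1
            cmh = scan["per_generation"]["F1"]
            gene_stat = enrich.collapse_snp_stats(
                pd.Series(cmh["p_value"].to_numpy(), index=cmh.index),
                pd.Series(cmh["contig"].to_numpy(), index=cmh.index))
            res = enrich.go_mwu_test(-gene_stat, go, direction="low")
            res["statistic_kind"] = "cmh_min_p"
            out.append(res)
            # expression divergence between home lines at F1
            de = de_by_gen["F1"]["AM_AM_vs_OWA_OWA"].dropna(subset=["p"])
            stat = pd.Series(np.log10(de["p"].to_numpy()),
                             index=de["gene_id"])
            res = enrich.go_mwu_test(stat, go, direction="low")
            res["statistic_kind"] = "de_p"
            out.append(res)
            # diversity change for the back-transplanted line by F3
            gd = diversity.gene_delta_pi(pi_res["delta"]["delta"], "OWA_AM_F3")
            if len(gd) >= 10:
                res = enrich.go_mwu_test(gd, go, direction="low")
                res["statistic_kind"] = "delta_pi_owa_am_f3"
                out.append(res)
            _write(pd.concat(out, ignore_index=True),
                   output_dir / "enrichment.tsv", manifest)


    surv_path = input_dir / "survivorship.csv"
    pairs_path = input_dir / "matepairs.csv"
    if surv_path.exists() and pairs_path.exists():
        @stage("life_history")
        def _lh():
            surv = pd.read_csv(surv_path)
            pairs = pd.read_csv(pairs_path)
            lam = lifehistory.lambda_ensemble(surv, pairs)
            _write(lam, output_dir / "lambda.tsv", manifest)
            rows = []
            for food in surv["food"].unique():
                sub = surv[surv["food"] == food]
                base = sub[sub["treatment"] == "AM_AM"]
                for tr in sorted(sub["treatment"].unique()):
                    if tr == "AM_AM" or base.empty:
                        continue
                    res = lifehistory.logrank_test(base, sub[sub["treatment"] == tr])
                    rows.append({"food": food, "treatment": tr, **res})
            _write(pd.DataFrame(rows), output_dir / "logrank.tsv", manifest)


    man = pd.DataFrame(manifest)
    man.to_csv(output_dir / "manifest.tsv", sep="\t", index=False)
    return man
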