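"""Synthetic data with the statistical structure the analysis assumes.

Emulates a 20-generation two-line selection experiment (ambient AM vs.
warming-and-acidification OWA, 4 replicate cultures each) followed by a
three-generation reciprocal transplant, sampled as pooled RNA-seq:

* Wright-Fisher allele trajectories with a selected-locus subset (selection in
  the OWA line during burn-in; reversed selection in OWA-line replicates
  transplanted back to ambient),
* pooled binomial read sampling at negative-binomially dispersed coverage,
* negative-binomial expression with genetic (line), plastic (environment) and
  plasticity-loss (assimilation) effects,
* day-structured survival and mate-pair fecundity assays.

Ground truth is recorded in a :class:`TruthTable` before any sampling noise so
recovery tests can score every downstream stage; no analysis stage reads it.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import GENERATIONS, LINES, stage_rng
from .io import AlleleCountTable, ExpressionMatrix, SampleDesign, write_sync

LN2 = np.log(2.0)

TREATMENTS = ("AM_AM", "AM_OWA", "OWA_AM", "OWA_OWA")
FOOD_LEVELS = ("replete", "limited", "starved")


@dataclass
class SimulationConfig:
    """Study conditions for the generator.

    The design constants (48 samples, pools of 20 diploids, 174x mean
    coverage, 20 burn-in + 3 transplant generations) mirror the experiment;
    the problem sizes (n_loci, n_genes) are desk-scale. Effect sizes are in
    log2 units. ``prop_plastic_lost_in_owa`` is the fraction of plastic genes
    whose environmental response the OWA line has lost (genetic
    assimilation).
    """

    n_loci: int = 4000
    prop_selected: float = 0.055
    s_selected: float = 0.3
    s_transplant: float | None = None  # reverse-selection coefficient; None -> s_selected
    ne: int = 1000
    n_burnin_gens: int = 20
    n_transplant_gens: int = 3
    pool_size: int = 20
    mean_coverage: float = 174.0
    coverage_dispersion: float = 8.0  # NB size of per-site depth
    allele_bias: float = 0.0  # allele-biased expression knob; 0 = unbiased
    n_genes: int = 3000
    nb_dispersion: float = 5.0  # NB size of expression counts
    prop_genetic_genes: float = 0.05
    prop_plastic_genes: float = 0.2
    effect_genetic: float = 1.0
    effect_plastic: float = 1.5
    prop_plastic_lost_in_owa: float = 0.9
    # life-history assay conditions
    n_start: int = 25
    n_beakers: int = 4
    n_pairs: int = 12
    n_days: int = 14
    maturity_day: int = 11
    egg_days: int = 3
    prop_female: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("prop_selected", "prop_genetic_genes", "prop_plastic_genes",
                     "prop_plastic_lost_in_owa", "prop_female"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.s_selected < 0:
            raise ValueError("s_selected must be >= 0")
        if self.ne <= 0 or self.pool_size < 1:
            raise ValueError("ne and pool_size must be positive")
        if self.mean_coverage < 0:
            raise ValueError("mean_coverage must be >= 0")

    @property
    def reverse_s(self) -> float:
        return self.s_selected if self.s_transplant is None else self.s_transplant


@dataclass
class TruthTable:
    """Ground truth recorded before sampling noise."""

    selected_loci: np.ndarray = field(default_factory=lambda: np.array([], int))
    genetic_genes: np.ndarray = field(default_factory=lambda: np.array([], int))
    plastic_genes_am: np.ndarray = field(default_factory=lambda: np.array([], int))
    plastic_genes_owa: np.ndarray = field(default_factory=lambda: np.array([], int))
    lost_plastic_genes: np.ndarray = field(default_factory=lambda: np.array([], int))
    founder_freq: np.ndarray | None = None
    # true_freq[(line, environment, generation)] -> (n_loci, n_replicates)
    true_freq: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Wright-Fisher trajectories


def _selection_update(p: np.ndarray, s: float, favour_alt: bool) -> np.ndarray:
    """Deterministic multiplicative-fitness update before drift."""
    if s == 0:
        return p
    if favour_alt:
        return p * (1 + s) / (1 + p * s)
    q = 1.0 - p
    q = q * (1 + s) / (1 + q * s)
    return 1.0 - q


def _wf_generation(p, ne, rng):
    return rng.binomial(2 * ne, p) / (2.0 * ne)


def simulate_allele_trajectories(config: SimulationConfig, rng=None,
                                 p0: np.ndarray | None = None):
    """Evolve founder frequencies through burn-in and transplant.

    Returns (true_freq, truth) where ``true_freq[(line, env, gen)]`` holds the
    (n_loci, 4) frequencies at the end of each transplant generation. Selected
    loci are favoured (alt allele) in the OWA line during burn-in only; OWA
    replicates transplanted to ambient see reverse selection (favouring the
    ancestral ref allele) during the transplant generations; AM-line cultures
    are neutral throughout.
    """
    rng = rng if rng is not None else stage_rng(config.seed, "allele_trajectories")
    L, R = config.n_loci, 4
    if p0 is None:
        p0 = rng.uniform(0.05, 0.95, size=L)
    n_sel = int(round(config.prop_selected * L))
    selected = rng.choice(L, size=n_sel, replace=False)
    selected.sort()
    sel_mask = np.zeros(L, dtype=bool)
    sel_mask[selected] = True

    # burn-in: per line, 4 replicate cultures
    line_freq = {}
    for line in LINES:
        p = np.tile(p0[:, None], (1, R))
        for _ in range(config.n_burnin_gens):
            if line == "OWA" and config.s_selected > 0:
                p[sel_mask] = _selection_update(p[sel_mask], config.s_selected, True)
            p = _wf_generation(p, config.ne, rng)
        line_freq[line] = p

    # transplant: each culture is split into home and away sub-cultures
    true_freq = {}
    state = {(line, env): line_freq[line].copy() for line in LINES for env in ("AM", "OWA")}
    for gen in GENERATIONS[: config.n_transplant_gens]:
        for line in LINES:
            for env in ("AM", "OWA"):
                p = state[(line, env)]
                if line == "OWA" and env == "AM" and config.reverse_s > 0:
                    p[sel_mask] = _selection_update(p[sel_mask], config.reverse_s, False)
                p = _wf_generation(p, config.ne, rng)
                state[(line, env)] = p
                true_freq[(line, env, gen)] = p.copy()
    if not all(np.isfinite(v).all() for v in true_freq.values()):
        raise RuntimeError("non-finite allele frequency (internal error)")

    truth = TruthTable(selected_loci=selected, founder_freq=p0, true_freq=true_freq)
    return true_freq, truth


# ---------------------------------------------------------------------------
# pooled read counts


def simulate_pool_counts(true_freq: np.ndarray, config: SimulationConfig,
                         rng=None, design: SampleDesign | None = None,
                         sites: pd.DataFrame | None = None) -> AlleleCountTable:
    """Binomial pool + read sampling of true frequencies.

    ``true_freq`` is (n_sites, n_samples). Per site and sample: the pool of
    ``pool_size`` diploids contributes 2*pool_size chromosomes drawn
    binomially from the true frequency; depth is negative-binomial with mean
    ``mean_coverage``; alt reads are binomial at the realized pool frequency.
    """
    true_freq = np.asarray(true_freq, dtype=float)
    if ((true_freq < 0) | (true_freq > 1)).any():
        raise ValueError("frequencies outside [0, 1]")
    rng = rng if rng is not None else stage_rng(config.seed, "pool_counts")
    n_sites, n_samples = true_freq.shape
    chrom = 2 * config.pool_size
    pool_freq = rng.binomial(chrom, true_freq) / float(chrom)
    if config.allele_bias:
        # optional allele-biased expression: alt reads over/under-represented
        w = np.exp2(config.allele_bias)
        pool_freq = pool_freq * w / (pool_freq * w + (1 - pool_freq))
    k = config.coverage_dispersion
    depth = rng.negative_binomial(k, k / (k + config.mean_coverage),
                                  size=(n_sites, n_samples))
    alt = rng.binomial(depth, pool_freq)
    ref = depth - alt
    if design is None:
        design = SampleDesign.full_design()
    if sites is None:
        sites = default_site_table(n_sites)
    return AlleleCountTable(sites, ref, alt, design)


def default_site_table(n_sites: int, sites_per_gene: int = 4,
                       gene_length: int = 300) -> pd.DataFrame:
    """Place sites on transcript-derived contigs (one contig per gene).

    Sites are evenly spread so 100-bp windows typically hold 1-2 sites,
    mimicking transcriptomic variant density.
    """
    contigs, positions = [], []
    spacing = max(gene_length // (sites_per_gene + 1), 1)
    for i in range(n_sites):
        g, k = divmod(i, sites_per_gene)
        contigs.append(f"gene{g + 1:05d}")
        positions.append((k + 1) * spacing + (g * 7) % spacing)
    return pd.DataFrame({
        "contig": contigs, "pos": positions,
        "ref_allele": "A", "alt_allele": "T",
    })


def assemble_count_table(true_freq: dict, config: SimulationConfig,
                         design: SampleDesign, rng=None) -> AlleleCountTable:
    """Arrange per-cell true frequencies into design order and sample reads."""
    rng = rng if rng is not None else stage_rng(config.seed, "pool_counts")
    freq = np.empty((config.n_loci, design.n_samples))
    for j, row in design.table.iterrows():
        cell = true_freq[(row["line"], row["environment"], row["generation"])]
        freq[:, j] = cell[:, row["replicate"] - 1]
    sites = default_site_table(config.n_loci)
    return simulate_pool_counts(freq, config, rng=rng, design=design, sites=sites)


# ---------------------------------------------------------------------------
# expression


def simulate_expression(config: SimulationConfig, design: SampleDesign,
                        rng=None, truth: TruthTable | None = None) -> ExpressionMatrix:
    """Negative-binomial counts under the line/environment/assimilation model.

    Per gene the log2 mean is baseline + effect_genetic*[line==OWA] for
    genetic genes + effect_plastic*[environment==OWA] for plastic genes. In
    the OWA line, the assimilated (lost) subset of plastic genes expresses
    the induced state constitutively -- the plastic effect applies in both
    environments, so those genes no longer respond to transplant but do
    diverge between the home lines (the signature of genetic assimilation).
    Effect signs are random per gene.
    """
    rng = rng if rng is not None else stage_rng(config.seed, "expression")
    G, S = config.n_genes, design.n_samples
    n_gen = int(round(config.prop_genetic_genes * G))
    n_pla = int(round(config.prop_plastic_genes * G))
    perm = rng.permutation(G)
    genetic = np.sort(perm[:n_gen])
    plastic = np.sort(perm[n_gen:n_gen + n_pla])
    n_lost = int(round(config.prop_plastic_lost_in_owa * n_pla))
    lost = np.sort(rng.choice(plastic, size=n_lost, replace=False))

    base_log2 = rng.uniform(3.0, 10.0, size=G)
    sign_g = rng.choice([-1.0, 1.0], size=G)
    sign_p = rng.choice([-1.0, 1.0], size=G)
    is_owa_line = (design.table["line"] == "OWA").to_numpy()
    is_owa_env = (design.table["environment"] == "OWA").to_numpy()
    loss = np.zeros(G)
    loss[lost] = 1.0

    log2_mu = np.tile(base_log2[:, None], (1, S))
    gmask = np.zeros(G, dtype=bool)
    gmask[genetic] = True
    pmask = np.zeros(G, dtype=bool)
    pmask[plastic] = True
    eff_g = np.where(gmask, sign_g * config.effect_genetic, 0.0)
    eff_p = np.where(pmask, sign_p * config.effect_plastic, 0.0)
    log2_mu += eff_g[:, None] * is_owa_line[None, :]
    # AM line (and non-assimilated OWA genes): respond to the OWA environment;
    # assimilated OWA genes: constitutive induction in both environments
    env_term = is_owa_env[None, :].astype(float)
    owa_term = (loss[:, None] + (1.0 - loss)[:, None] * env_term)
    plastic_term = np.where(is_owa_line[None, :], owa_term, env_term)
    log2_mu += eff_p[:, None] * plastic_term

    depth_factor = np.exp(rng.normal(0.0, 0.15, size=S))
    mu = np.exp2(log2_mu) * depth_factor[None, :]
    k = config.nb_dispersion
    counts = rng.negative_binomial(k, k / (k + mu))
    gene_ids = pd.Index([f"gene{i + 1:05d}" for i in range(G)])

    if truth is not None:
        truth.genetic_genes = genetic
        truth.plastic_genes_am = plastic
        truth.plastic_genes_owa = np.setdiff1d(plastic, lost)
        truth.lost_plastic_genes = lost
    return ExpressionMatrix(gene_ids, counts, design)


# ---------------------------------------------------------------------------
# life history


_TREATMENT_LH = {
    # (daily survival, EPR eggs/day, hatching success) under replete food
    "AM_AM": (0.97, 15.0, 0.85),
    "AM_OWA": (0.95, 11.0, 0.75),
    "OWA_AM": (0.94, 10.0, 0.70),
    "OWA_OWA": (0.96, 13.0, 0.80),
}
_FOOD_LH = {
    # multiplier on (survival, EPR, HS)
    "replete": (1.0, 1.0, 1.0),
    "limited": (0.97, 0.55, 0.85),
    "starved": (0.3, 0.0, 0.0),  # unfed nauplii die within days
}


def life_history_rates(treatment: str, food: str):
    s, epr, hs = _TREATMENT_LH[treatment]
    ms, mepr, mhs = _FOOD_LH[food]
    return s * ms, epr * mepr, hs * mhs


def simulate_life_history(config: SimulationConfig, rng=None):
    """Daily binomial survival chains and Poisson mate-pair egg counts.

    Returns (survivorship, matepairs) DataFrames in long form matching the
    life-history CSV schemas. Starved beakers collapse before maturity, as in
    the assays this emulates.
    """
    rng = rng if rng is not None else stage_rng(config.seed, "life_history")
    surv_rows, pair_rows = [], []
    for treatment in TREATMENTS:
        for food in FOOD_LEVELS:
            p_day, epr_mean, hs_mean = life_history_rates(treatment, food)
            for b in range(1, config.n_beakers + 1):
                alive = config.n_start
                l_series = [alive]
                for _ in range(1, config.n_days + 1):
                    alive = rng.binomial(alive, p_day)
                    l_series.append(alive)
                final = l_series[-1]
                females = rng.binomial(final, config.prop_female)
                males = final - females
                for day, l in enumerate(l_series):
                    surv_rows.append({
                        "beaker_id": f"{treatment}_{food}_b{b}",
                        "treatment": treatment, "food": food, "day": day,
                        "alive": l, "n_females": females, "n_males": males,
                        "first_adult_day": config.maturity_day,
                    })
            for pid in range(1, config.n_pairs + 1):
                eggs = int(rng.poisson(epr_mean * config.egg_days))
                hatched = rng.binomial(eggs, hs_mean) if eggs else 0
                pair_rows.append({
                    "pair_id": f"{treatment}_{food}_p{pid}",
                    "treatment": treatment, "food": food,
                    "e_unhatched": eggs - hatched, "e_hatched": hatched,
                    "days": config.egg_days,
                    "male_alive": bool(rng.random() < p_day ** config.egg_days),
                    "female_alive": bool(rng.random() < p_day ** config.egg_days),
                })
    return pd.DataFrame(surv_rows), pd.DataFrame(pair_rows)


# ---------------------------------------------------------------------------
# GO map and full fixture


def simulate_go_map(config: SimulationConfig, truth: TruthTable, rng=None,
                    n_categories: int = 40, mean_category_size: int = 30) -> pd.DataFrame:
    """Random gene->category map with planted enriched categories.

    Categories GO:SEL0001/GO:PLA0001 collect genes that carry selected loci or
    lost-plasticity genes, so rank-based enrichment has true positives.
    """
    rng = rng if rng is not None else stage_rng(config.seed, "go_map")
    rows = []
    for c in range(1, n_categories + 1):
        size = max(5, rng.poisson(mean_category_size))
        genes = rng.choice(config.n_genes, size=min(size, config.n_genes), replace=False)
        rows += [{"gene_id": f"gene{g + 1:05d}", "category_id": f"GO:{c:07d}"}
                 for g in genes]
    sel_genes = np.unique(truth.selected_loci // 4)  # sites_per_gene in site table
    rows += [{"gene_id": f"gene{g + 1:05d}", "category_id": "GO:SEL0001"}
             for g in sel_genes[:60]]
    rows += [{"gene_id": f"gene{g + 1:05d}", "category_id": "GO:PLA0001"}
             for g in truth.lost_plastic_genes[:60]]
    return pd.DataFrame(rows).drop_duplicates()


def generate_fixture_dir(config: SimulationConfig, outdir) -> TruthTable:
    """Write the full synthetic input set (sync, TSVs, CSVs, truth tables)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = SampleDesign.full_design()
    true_freq, truth = simulate_allele_trajectories(config)
    table = assemble_count_table(true_freq, config, design)
    expr = simulate_expression(config, design, truth=truth)
    surv, pairs = simulate_life_history(config)
    go = simulate_go_map(config, truth)

    design.write(outdir / "design.tsv")
    write_sync(table, outdir / "counts.sync")
    expr.write(outdir / "expression.tsv")
    go.to_csv(outdir / "go_map.tsv", sep="\t", index=False)
    surv.to_csv(outdir / "survivorship.csv", index=False)
    pairs.to_csv(outdir / "matepairs.csv", index=False)
    pd.DataFrame({"locus_index": truth.selected_loci}).to_csv(
        outdir / "truth_selected_loci.tsv", sep="\t", index=False)
    pd.DataFrame({
        "gene_index": np.concatenate([truth.genetic_genes, truth.plastic_genes_am,
                                      truth.lost_plastic_genes]),
        "class": (["genetic"] * len(truth.genetic_genes)
                  + ["plastic"] * len(truth.plastic_genes_am)
                  + ["lost_plastic"] * len(truth.lost_plastic_genes)),
    }).to_csv(outdir / "truth_gene_classes.tsv", sep="\t", index=False)
    return truth
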