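"""Domain containers and the text formats the pipeline reads and writes.

Pooled allele counts travel as PoPoolation-style sync records (tab-separated,
1-based positions, per-sample ``A:T:C:G:N:del`` count fields); expression is a
gene x sample TSV count matrix; the sample design is a TSV with one row per
pooled library. All tables are UTF-8 TSV with a header row.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import ENVIRONMENTS, GENERATIONS, LINES, RunConfig

SYNC_BASES = ("A", "T", "C", "G")  # sync field order is A:T:C:G:N:del
_BASE_ORDER = {"A": 0, "C": 1, "G": 2, "T": 3}  # tie-break order for alleles


class SyncParseError(ValueError):
    pass


@dataclass
class SampleDesign:
    """The factorial layout: line x environment x generation x replicate.

    The full reciprocal-transplant design has 48 samples
    (2 lines x 2 environments x 3 generations x 4 replicates).
    """

    table: pd.DataFrame  # sample_id, line, environment, generation, replicate

    REQUIRED = ("sample_id", "line", "environment", "generation", "replicate")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"design missing columns: {missing}")
        t = self.table
        if t["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in design")
        bad_line = set(t["line"]) - set(LINES)
        bad_env = set(t["environment"]) - set(ENVIRONMENTS)
        if bad_line or bad_env:
            raise ValueError(f"unknown line/environment labels: {bad_line | bad_env}")
        key = t[["line", "environment", "generation", "replicate"]]
        if key.duplicated().any():
            raise ValueError("duplicate (line, environment, generation, replicate) cell")
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def n_samples(self) -> int:
        return len(self.table)

    def mask(self, line=None, environment=None, generation=None, replicate=None) -> np.ndarray:
        m = np.ones(len(self.table), dtype=bool)
        for col, val in (("line", line), ("environment", environment),
                         ("generation", generation), ("replicate", replicate)):
            if val is not None:
                m &= (self.table[col] == val).to_numpy()
        return m

    def indices(self, **kwargs) -> np.ndarray:
        return np.flatnonzero(self.mask(**kwargs))

    def subset(self, sample_ids: Sequence[str]) -> "SampleDesign":
        sub = self.table.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return SampleDesign(sub)

    @classmethod
    def full_design(cls) -> "SampleDesign":
        rows = [
            {"sample_id": f"{ln}_{env}_{gen}_rep{rep}", "line": ln, "environment": env,
             "generation": gen, "replicate": rep}
            for gen in GENERATIONS for ln in LINES for env in ENVIRONMENTS
            for rep in (1, 2, 3, 4)
        ]
        return cls(pd.DataFrame(rows))

    @classmethod
    def read(cls, path) -> "SampleDesign":
        t = pd.read_csv(path, sep="\t", dtype={"replicate": int})
        return cls(t)

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class AlleleCountTable:
    """Biallelic read counts per site per pooled sample."""

    sites: pd.DataFrame  # contig, pos (1-based), ref_allele, alt_allele
    ref_counts: np.ndarray  # (n_sites, n_samples) int
    alt_counts: np.ndarray
    design: SampleDesign

    def __post_init__(self) -> None:
        n_sites, n_samples = self.ref_counts.shape
        if self.alt_counts.shape != (n_sites, n_samples):
            raise ValueError("ref/alt count shape mismatch")
        if len(self.sites) != n_sites:
            raise ValueError("site table does not match count matrix")
        if n_samples != self.design.n_samples:
            raise ValueError("count matrix does not match design")
        if (self.sites["ref_allele"] == self.sites["alt_allele"]).any():
            raise ValueError("ref_allele == alt_allele at some site")
        if (self.ref_counts < 0).any() or (self.alt_counts < 0).any():
            raise ValueError("negative allele counts")
        by = self.sites.sort_values(["contig", "pos"], kind="stable")
        if by.duplicated(["contig", "pos"]).any():
            raise ValueError("duplicate site coordinates")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def depth(self) -> np.ndarray:
        return self.ref_counts + self.alt_counts

    def allele_frequencies(self) -> np.ndarray:
        """Alt-allele read frequencies; NaN where a sample has zero depth."""
        d = self.depth.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(d > 0, self.alt_counts / d, np.nan)

    def subset_sites(self, index: np.ndarray) -> "AlleleCountTable":
        return AlleleCountTable(
            self.sites.iloc[index].reset_index(drop=True),
            self.ref_counts[index], self.alt_counts[index], self.design,
        )


@dataclass
class ExpressionMatrix:
    """Gene x sample integer counts plus normalization state."""

    gene_ids: pd.Index
    counts: np.ndarray  # (n_genes, n_samples) int
    design: SampleDesign
    size_factors: np.ndarray | None = None
    transformed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gene_ids = pd.Index(self.gene_ids)
        if self.gene_ids.duplicated().any():
            raise ValueError("duplicate gene ids")
        if self.counts.shape != (len(self.gene_ids), self.design.n_samples):
            raise ValueError("count matrix shape does not match genes x samples")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @classmethod
    def read(cls, path, design: SampleDesign) -> "ExpressionMatrix":
        t = pd.read_csv(path, sep="\t", index_col=0)
        if t.shape[0] == 0:
            raise ValueError(f"no genes in expression file {path}")
        missing = set(design.sample_ids) - set(t.columns)
        if missing:
            raise ValueError(f"expression matrix missing samples: {sorted(missing)}")
        t = t[design.sample_ids]
        return cls(t.index, t.to_numpy(dtype=np.int64), design)

    def write(self, path) -> None:
        pd.DataFrame(self.counts, index=self.gene_ids,
                     columns=self.design.sample_ids).to_csv(
            path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# sync parsing / writing


def parse_sync_line(line_text: str, sample_count: int):
    """Parse one sync record into (contig, pos, ref, per-sample base counts).

    Per-sample counts are dicts holding the bases with non-zero reads; the
    biallelic reduction happens downstream, not here.
    """
    parts = line_text.rstrip("\n").split("\t")
    if len(parts) != 3 + sample_count:
        raise SyncParseError(
            f"expected {3 + sample_count} tab-separated fields, got "
            f"{len(parts)}: {line_text!r}")
    contig, pos_s, ref = parts[0], parts[1], parts[2]
    try:
        pos = int(pos_s)
    except ValueError:
        raise SyncParseError(f"non-integer position in {line_text!r}") from None
    samples = []
    for fld in parts[3:]:
        nums = fld.split(":")
        if len(nums) != 6:
            raise SyncParseError(f"count field {fld!r} is not A:T:C:G:N:del")
        try:
            vals = [int(x) for x in nums]
        except ValueError:
            raise SyncParseError(f"non-integer count in field {fld!r}") from None
        if any(v < 0 for v in vals):
            raise SyncParseError(f"negative count in field {fld!r}")
        samples.append({b: v for b, v in zip(SYNC_BASES, vals[:4]) if v > 0})
    return contig, pos, ref, samples


def _pick_biallelic(per_sample: list[dict], ref: str) -> tuple[str, str]:
    """Two highest-total bases; ties by A<C<G<T; sync ref preferred as ref."""
    totals = {b: 0 for b in "ACGT"}
    for d in per_sample:
        for b, v in d.items():
            totals[b] += v
    ranked = sorted(totals, key=lambda b: (-totals[b], _BASE_ORDER[b]))
    top2 = ranked[:2]
    if ref in top2:
        alt = top2[0] if top2[1] == ref else top2[1]
        return ref, alt
    return top2[0], top2[1]


def read_sync(path, design: SampleDesign) -> AlleleCountTable:
    """Read a sync file into a biallelic :class:`AlleleCountTable`."""
    n = design.n_samples
    recs, ref_rows, alt_rows = [], [], []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            contig, pos, ref, samples = parse_sync_line(line, n)
            ra, aa = _pick_biallelic(samples, ref)
            recs.append((contig, pos, ra, aa))
            ref_rows.append([d.get(ra, 0) for d in samples])
            alt_rows.append([d.get(aa, 0) for d in samples])
    if not recs:
        raise ValueError(f"no sites in sync file {path}")
    sites = pd.DataFrame(recs, columns=["contig", "pos", "ref_allele", "alt_allele"])
    return AlleleCountTable(sites, np.asarray(ref_rows, dtype=np.int64),
                            np.asarray(alt_rows, dtype=np.int64), design)


def write_sync(table: AlleleCountTable, path) -> None:
    sites = table.sites
    with open(path, "w") as fh:
        for i in range(table.n_sites):
            contig, pos = sites.iloc[i]["contig"], sites.iloc[i]["pos"]
            ra, aa = sites.iloc[i]["ref_allele"], sites.iloc[i]["alt_allele"]
            fields = []
            for j in range(table.design.n_samples):
                counts = {b: 0 for b in SYNC_BASES}
                counts[ra] = int(table.ref_counts[i, j])
                counts[aa] = int(table.alt_counts[i, j])
                fields.append(":".join(str(counts[b]) for b in SYNC_BASES) + ":0:0")
            fh.write(f"{contig}\t{pos}\t{ra}\t" + "\t".join(fields) + "\n")


def load_experiment(counts_path, expression_path, design_path,
                    config: RunConfig | None = None):
    """Load and cross-validate the three core inputs.

    Sample order of both matrices is harmonized to design order.
    """
    config = config or RunConfig()
    design = SampleDesign.read(design_path)
    counts = read_sync(counts_path, design)
    expr = ExpressionMatrix.read(expression_path, design)
    return counts, expr, design, config
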