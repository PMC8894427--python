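"""Run configuration and deterministic seed derivation.

One top-level seed governs every stochastic stage; each stage derives its own
child seed from (seed, stage name) so that stages can be re-run in isolation
and still reproduce the full-pipeline output bit-exactly.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field, fields

import numpy as np

LINES = ("AM", "OWA")
ENVIRONMENTS = ("AM", "OWA")
GENERATIONS = ("F1", "F2", "F3")
REPLICATES = (1, 2, 3, 4)


@dataclass
class RunConfig:
    """Analysis-wide constants.

    alpha : family-wise error rate for the Bonferroni allele-divergence
        threshold.
    n_generations_tested : number of per-generation CMH scans entering the
        Bonferroni correction (the intersection is over these scans).
    window_size : nucleotide-diversity window width in bp.
    pool_size : diploid individuals per RNA pool.
    de_alpha : BH-adjusted p-value cut-off for differential expression.
    mcmc_draws : retained post-burn-in Gibbs draws for discriminant-shift
        inference; the reporting floor for P_MCMC is 1/mcmc_draws.
    """

    alpha: float = 0.05
    n_generations_tested: int = 3
    window_size: int = 100
    pool_size: int = 20
    de_alpha: float = 0.05
    mcmc_draws: int = 2500
    n_pcs_expression: int = 4
    n_pcs_allele: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha", "de_alpha"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        if self.mcmc_draws < 1:
            raise ValueError("mcmc_draws must be >= 1")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Read a flat ``key = value`` (or ``key: value``) text config."""
        kwargs = {}
        valid = {f.name: f.type for f in fields(cls)}
        with open(path) as fh:
            for raw in fh:
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                for sep in ("=", ":", "\t"):
                    if sep in line:
                        key, _, val = line.partition(sep)
                        break
                else:
                    raise ValueError(f"cannot parse config line: {raw!r}")
                key, val = key.strip(), val.strip()
                if key not in valid:
                    raise ValueError(f"unknown config key: {key}")
                caster = float if "float" in str(valid[key]) else int
                kwargs[key] = caster(val)
        return cls(**kwargs)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)}\n")


def child_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed in [0, 2**31)."""
    return (int(seed) ^ zlib.crc32(stage.encode("utf-8"))) % (2**31)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(child_seed(seed, stage))
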