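import numpy as np
import pandas as pd
import pytest

from transplantomics import (RunConfig, SampleDesign, SimulationConfig,
                             generate_fixture_dir, run_pipeline)


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(n_loci=800, n_genes=600, seed=11)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, sim_config):
    d = tmp_path_factory.mktemp("synthetic")
    truth = generate_fixture_dir(sim_config, d)
    return d, truth


@pytest.fixture(scope="session")
def pipeline_output(tmp_path_factory, fixture_dir):
    d, truth = fixture_dir
    out = tmp_path_factory.mktemp("results")
    manifest = run_pipeline(RunConfig(seed=11, mcmc_draws=500), d, out)
    return out, manifest


@pytest.fixture
def mini_design():
    """8 samples: 2 lines x 2 environments x 2 replicates, one generation."""
    rows = [
        {"sample_id": f"{ln}_{env}_F1_rep{r}", "line": ln, "environment": env,
         "generation": "F1", "replicate": r}
        for ln in ("AM", "OWA") for env in ("AM", "OWA") for r in (1, 2)
    ]
    return SampleDesign(pd.DataFrame(rows))


@pytest.fixture
def pair_design():
    """8 samples in two cells of 4 replicates: AM home vs AM transplanted."""
    rows = [
        {"sample_id": f"AM_{env}_F1_rep{r}", "line": "AM", "environment": env,
         "generation": "F1", "replicate": r}
        for env in ("AM", "OWA") for r in (1, 2, 3, 4)
    ]
    return SampleDesign(pd.DataFrame(rows))


def make_de_frame(gene_ids, padj, contrast, generation="F1"):
    """Minimal differential-expression table for classification tests."""
    padj = np.asarray(padj, dtype=float)
    return pd.DataFrame({
        "gene_id": gene_ids, "lfc": np.zeros(len(padj)), "p": padj,
        "padj": padj, "converged": True, "contrast": contrast,
        "generation": generation,
    })
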