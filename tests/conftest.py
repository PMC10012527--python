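"""Shared fixtures: one default synthetic dataset per session, plus the
intermediate products of the preprocessing chain."""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from fibrorhythm import preprocess as pp
from fibrorhythm import simulate as sim
from fibrorhythm.config import RunConfig, SyntheticConfig

warnings.filterwarnings("ignore", category=UserWarning)


def make_adata(counts, coords=None, condition=None, cells=None, genes=None):
    """Small AnnData builder for hand-constructed examples."""
    counts = np.asarray(counts)
    n, g = counts.shape
    cells = cells if cells is not None else [f"c{i}" for i in range(n)]
    genes = genes if genes is not None else [f"g{j}" for j in range(g)]
    obs = pd.DataFrame(index=pd.Index(cells, name="cell_id"))
    obs["condition"] = condition if condition is not None else "wt"
    adata = ad.AnnData(X=sp.csr_matrix(counts.astype(np.int64)), obs=obs,
                       var=pd.DataFrame(index=pd.Index(genes, name="gene_id")))
    if coords is not None:
        adata.obsm["X_umap"] = np.asarray(coords, dtype=float)
    return adata


@pytest.fixture(scope="session")
def default_config() -> SyntheticConfig:
    return SyntheticConfig(seed=1)


@pytest.fixture(scope="session")
def sc_data(default_config):
    return sim.gen_sc_dataset(default_config)


@pytest.fixture(scope="session")
def filtered(sc_data):
    adata, _ = sc_data
    return pp.filter_cells(adata)


@pytest.fixture(scope="session")
def meg_table(filtered):
    adata, _ = filtered
    return pp.find_megs(adata, seed=1)


@pytest.fixture(scope="session")
def merged_partition(filtered, meg_table):
    adata, _ = filtered
    meg_genes = sorted(meg_table.loc[meg_table["is_meg"], "gene"])
    dist = pp.meg_distance_matrix(adata, meg_genes)
    return pp.merge_fine_clusters(adata, adata.obs["fine_cluster"], dist)


@pytest.fixture(scope="session")
def timecourse(default_config):
    return sim.gen_timecourse(default_config)


@pytest.fixture(scope="session")
def genome_bundle(default_config):
    return sim.gen_genome(default_config)


@pytest.fixture(scope="session")
def motif_matrix(genome_bundle):
    from fibrorhythm import motifs as mo
    genome, _ = genome_bundle
    return mo.build_motif_gene_matrix(genome.sequences, genome.acrs,
                                      genome.genes,
                                      chrom_sizes=genome.chrom_sizes)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full end-to-end pipeline run at the default study conditions."""
    from fibrorhythm.pipeline import run_all
    out = tmp_path_factory.mktemp("run_default")
    cfg = RunConfig(seed=1, out_dir=str(out))
    summary = run_all(cfg)
    return summary, out
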