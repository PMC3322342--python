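import dataclasses

import numpy as np
import pandas as pd
import pytest

import nichexpress as nx
from nichexpress.config import POPULATIONS


@pytest.fixture(scope="session")
def small_config():
    cfg = nx.RunConfig()
    cfg.atlas = dataclasses.replace(cfg.atlas, n_genes=400, seed=7)
    return cfg


@pytest.fixture(scope="session")
def small_atlas(small_config):
    return nx.build_atlas(small_config.atlas)


@pytest.fixture(scope="session")
def mixtures():
    return nx.default_mixtures()


@pytest.fixture()
def tiny_atlas():
    """Hand-built three-gene atlas for arithmetic checks."""
    expr = pd.DataFrame(
        {pop: [10.0, 30.0, 0.0] for pop in POPULATIONS},
        index=pd.Index(["gA", "gB", "gC"], name="gene_id"),
    )
    expr.loc["gA", "female_gsc"] = 10.0
    expr.loc["gB", "female_gsc"] = 30.0
    expr.loc["gA", "kc_reference"] = 30.0
    expr.loc["gC", :] = 0.0
    truth = pd.Series(
        ["housekeeping", "housekeeping", "low_expressed"],
        index=expr.index,
        name="truth_class",
    )
    return nx.PopulationAtlas(expr, truth, ("housekeeping", "low_expressed"))


def make_de_table(genes, M, p_adj, mean_group1=None, mean_group2=None):
    """Minimal DE table with the pipeline schema."""
    n = len(genes)
    return pd.DataFrame(
        {
            "M": M,
            "A": np.full(n, 9.0),
            "t_mod": np.sign(M) * 5.0,
            "p": np.asarray(p_adj) / 2.0,
            "p_adj": p_adj,
            "mean_group1": np.full(n, 9.0) if mean_group1 is None else mean_group1,
            "mean_group2": np.full(n, 9.0) if mean_group2 is None else mean_group2,
        },
        index=pd.Index(genes, name="gene_id"),
    )
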