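"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pytest

import npnets
from npnets.synthetic import (
    SynthConfig,
    generate_dataset,
    generate_np_gene_table,
    generate_taxonomy,
)


@pytest.fixture(scope="session")
def np_annotation():
    """The shipped cortical NP gene annotation table."""
    return npnets.load_np_gene_annotation()


@pytest.fixture(scope="session")
def small_cfg():
    return SynthConfig(n_types=12, n_subclasses=4, n_cells_per_area=400,
                       n_genes_background=120, n_genes_np_like=30, seed=11)


@pytest.fixture(scope="session")
def small_taxonomy(small_cfg):
    return generate_taxonomy(small_cfg)


@pytest.fixture(scope="session")
def small_np_table(small_cfg):
    return generate_np_gene_table(small_cfg)


@pytest.fixture(scope="session")
def small_dataset(small_cfg, small_taxonomy, small_np_table):
    """(cpm, counts, annotation) for a 12-type, 800-cell dataset."""
    return generate_dataset(small_taxonomy, small_np_table, small_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
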