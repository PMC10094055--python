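import logging

import pytest

from epi_impute import SyntheticDesign, generate, run_pipeline

logging.getLogger("epi_impute").setLevel(logging.ERROR)


SMALL = dict(
    n_cell_types=3,
    cells_per_type=30,
    n_genes=150,
    markers_per_type_pos=5,
    markers_per_type_neg=5,
    genes_per_chrom=75,
)


@pytest.fixture(scope="session")
def small_design():
    return SyntheticDesign(seed=42, **SMALL)


@pytest.fixture(scope="session")
def small_dataset(small_design):
    return generate(small_design)


@pytest.fixture(scope="session")
def small_result(small_dataset):
    ds = small_dataset
    return run_pipeline(
        ds.expression, ds.fragments, ds.elements, ds.blacklist,
        ds.rna_annotation, ds.atac_annotation,
    )
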