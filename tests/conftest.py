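from importlib import resources

import pytest

from knotopt import peptides


@pytest.fixture(scope="session")
def reference_variants() -> dict[str, peptides.PeptideVariant]:
    """The packaged round-summary variants, keyed by name."""
    return peptides.load_reference_variants()


@pytest.fixture(scope="session")
def wt(reference_variants) -> peptides.PeptideVariant:
    return reference_variants["WT PTx2"]


@pytest.fixture(scope="session")
def cell_table_text() -> str:
    return resources.files("knotopt.data").joinpath("drg_oxaliplatin_cells.csv").read_text()


@pytest.fixture(scope="session")
def resfile_text() -> str:
    return resources.files("knotopt.data").joinpath("design_round2.resfile").read_text()


@pytest.fixture(scope="session")
def ic50_table_text() -> str:
    return resources.files("knotopt.data").joinpath("nav_ic50_selectivity.csv").read_text()


@pytest.fixture(scope="session")
def potency_table_text() -> str:
    return resources.files("knotopt.data").joinpath("potency_ranking.csv").read_text()
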