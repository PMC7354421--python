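import numpy as np
import pytest

from tasprof.catalog import Catalog, GeneRecord
from tasprof.simulate import SimDesign, make_synthetic_catalog


def make_record(gene_id, seq, genus="Bifidobacterium", species="B. longum",
                strain="NCC2705", family="MazEF"):
    return GeneRecord(
        gene_id=gene_id, genus=genus, species=species, strain=strain,
        tas_family=family, sequence=seq,
    )


@pytest.fixture
def toy_catalog():
    """Two genera, mixed families, with a duplicated sequence pair."""
    return Catalog([
        make_record("g1", "ATGCATGCAT", strain="st1"),
        make_record("g2", "ATGCATGCAT", strain="st2"),
        make_record("g3", "ATGAATGCAT", strain="st3", family="RelBE"),
        make_record("g4", "CCCCCCCCCC", genus="Escherichia", species="E. coli",
                    strain="K12", family="MazEF"),
    ])


@pytest.fixture(scope="session")
def default_design():
    return SimDesign(seed=11)


@pytest.fixture(scope="session")
def synthetic_catalog(default_design):
    rng = np.random.default_rng(default_design.seed)
    return make_synthetic_catalog(default_design, rng)
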