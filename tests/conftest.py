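import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import panelscreen as ps

settings.register_profile(
    "default", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def toy_cds_model():
    """Single-exon gene with CDS ATG GCA TGA on the plus strand.

    Exon spans genomic [10, 19); coding positions c.1..c.9 sit at 1-based
    genomic 11..19.
    """
    model = ps.GeneModel(
        gene="TOY",
        transcript="TX_TOY",
        chrom="chrT",
        strand="+",
        exon_starts=(10,),
        exon_ends=(19,),
        cds_start=10,
        cds_end=19,
    )
    return model, "ATGGCATGA"


@pytest.fixture(scope="session")
def three_exon_model():
    """Plus-strand 3-exon transcript with UTRs for coordinate tests.

    Exons [100,200), [1100,1200), [2100,2200); CDS [150,2150): 5'UTR is the
    first 50 exonic bases, 3'UTR the last 50.
    """
    return ps.GeneModel(
        gene="TRI",
        transcript="TX_TRI",
        chrom="chrT",
        strand="+",
        exon_starts=(100, 1100, 2100),
        exon_ends=(200, 1200, 2200),
        cds_start=150,
        cds_end=2150,
    )


@pytest.fixture(scope="session")
def small_panel():
    """A reduced synthetic capture panel shared across tests."""
    spec = ps.CohortSpec(seed=11, n_samples=2, n_genes=4, n_background_variants=0)
    return spec, ps.make_panel(spec)


@pytest.fixture(scope="session")
def default_panel():
    """The full 15-disease-gene panel with a fixed design seed."""
    spec = ps.CohortSpec(seed=0, panel_seed=1234, n_background_variants=0)
    return spec, ps.make_panel(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
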