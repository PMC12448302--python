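import numpy as np
import pandas as pd
import pytest

from hadalvirome.synthetic import (
    ScenarioConfig,
    generate_community,
    generate_virus_host_genomes,
    make_coding_contig,
    plant_variants,
    generate_pileup,
)


@pytest.fixture(scope="session")
def vh_fixture():
    """One seeded virus-host fixture shared by the linkage tests."""
    return generate_virus_host_genomes(seed=5)


@pytest.fixture(scope="session")
def small_community():
    cfg = ScenarioConfig(seed=1, n_samples=8, n_taxa=40, regime="well_mixed")
    return generate_community(cfg)


@pytest.fixture(scope="session")
def pileup_case():
    contig = make_coding_contig(seed=3)
    variants = plant_variants(seed=4, contig=contig, n_variants=30)
    pileup = generate_pileup(seed=5, contig=contig, variants=variants,
                             mean_coverage=100, error_rate=0.0)
    return contig, variants, pileup


@pytest.fixture
def toy_table():
    return pd.DataFrame(
        {"s1": [1.0, 0.0, 3.0], "s2": [1.0, 2.0, 3.0]},
        index=["a", "b", "c"],
    )
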