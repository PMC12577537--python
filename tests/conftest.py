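import pandas as pd
import pytest

from ugiqc.chem_enum import (
    DESCRIPTOR_NAMES,
    BuildingBlock,
    compute_descriptors,
    enumerate_library,
    normalize_01,
)
from ugiqc.synthetic_data import (
    SimulationConfig,
    gen_building_blocks,
    simulate_campaign,
    write_campaign,
)


@pytest.fixture
def formaldehyde():
    return BuildingBlock(id="ald_form", role="aldehyde", smiles="C=O")


@pytest.fixture
def benzaldehyde():
    return BuildingBlock(id="ald_benz", role="aldehyde", smiles="O=Cc1ccccc1")


@pytest.fixture
def methyl_isocyanide():
    return BuildingBlock(id="iso_me", role="isocyanide", smiles="[C-]#[N+]C")


@pytest.fixture
def tbutyl_isocyanide():
    return BuildingBlock(id="iso_tbu", role="isocyanide", smiles="[C-]#[N+]C(C)(C)C")


@pytest.fixture(scope="session")
def library_1000():
    """A fixed 40x25 product matrix with its normalized descriptor table."""
    config = SimulationConfig(seed=0, n_aldehydes=40, n_isocyanides=25)
    aldehydes, isocyanides = gen_building_blocks(config)
    products = enumerate_library(aldehydes, isocyanides)
    desc = pd.DataFrame(
        [compute_descriptors(p.smiles).as_dict() for p in products],
        index=[p.id for p in products],
    )
    X = normalize_01(desc[list(DESCRIPTOR_NAMES)])
    return products, X


@pytest.fixture(scope="session")
def small_campaign():
    config = SimulationConfig(
        seed=7, n_aldehydes=10, n_isocyanides=10, n_uplc_subset=30
    )
    return simulate_campaign(config)


@pytest.fixture(scope="session")
def small_campaign_dir(small_campaign, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("campaign")
    write_campaign(small_campaign, outdir)
    return outdir
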