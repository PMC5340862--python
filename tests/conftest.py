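import pytest

from consortium_coupling.core_model import (
    Design,
    GeneRecord,
    GeneTable,
    Species,
    SteadyStateCondition,
)
from consortium_coupling.synthetic_data import TruthConfig, default_design


@pytest.fixture(scope="session")
def small_truth() -> TruthConfig:
    """A scaled-down ground-truth config for fast unit tests."""
    return TruthConfig(
        n_genes_cyano=300,
        n_genes_het=200,
        planted_responsive={
            ("binary", "irradiance", "cyanobacterium"): 40,
            ("binary", "pO2", "cyanobacterium"): 20,
            ("binary", "irradiance", "heterotroph"): 30,
            ("binary", "pO2", "heterotroph"): 15,
            ("axenic", "irradiance", "cyanobacterium"): 50,
            ("axenic", "pO2", "cyanobacterium"): 25,
        },
    )


@pytest.fixture(scope="session")
def binary_design() -> Design:
    return default_design("binary")


@pytest.fixture
def toy_gene_table() -> GeneTable:
    return GeneTable(
        [
            GeneRecord("cyA", Species.CYANOBACTERIUM, 300, frozenset({"photosynthesis"})),
            GeneRecord("cyB", Species.CYANOBACTERIUM, 600, frozenset({"photosynthesis", "transport"})),
            GeneRecord("cyC", Species.CYANOBACTERIUM, 900, frozenset()),
            GeneRecord("heA", Species.HETEROTROPH, 450, frozenset({"transport"})),
        ]
    )


@pytest.fixture
def toy_design() -> Design:
    conditions = [
        SteadyStateCondition("LL-LO", 197.0, 0.0, 2),
        SteadyStateCondition("ML-LO", 1190.0, 0.0, 2),
        SteadyStateCondition("HL-LO", 1995.0, 0.0, 2),
        SteadyStateCondition("HL-MO", 1995.0, 0.30, 2),
        SteadyStateCondition("HL-HO", 1995.0, 0.59, 2),
    ]
    sample_map = {
        f"S_{c.label}_r{r}": c.label for c in conditions for r in (1, 2)
    }
    return Design(conditions, sample_map)
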