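import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from ribocalc.cell import CellModel, kinetic_constants
from ribocalc.trna import (
    WalkerSpace,
    build_trna_inventory,
    codon_times_table,
    load_trna_table,
)


@pytest.fixture(scope="session")
def cell():
    return CellModel()


@pytest.fixture(scope="session")
def inventory(cell):
    return build_trna_inventory(load_trna_table(), cell)


@pytest.fixture(scope="session")
def space(cell):
    return WalkerSpace(cell.cytoplasm_volume, 5.9e-9)


@pytest.fixture(scope="session")
def codon_table(inventory, space):
    """Per-codon kinetics for the packaged yeast inventory at 30 C."""
    return codon_times_table(inventory, kinetic_constants(30), space)


@pytest.fixture(scope="session")
def codon_times(codon_table):
    return {c: k.time for c, k in codon_table.items()}
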