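import pytest

from methref import ConvertedIndexSet, Parameters, build_converted_set
from methref import simulate as sim


@pytest.fixture(scope="session")
def params():
    return Parameters()


@pytest.fixture(scope="session")
def panel():
    """One seeded synthetic assembly panel shared across the suite."""
    return sim.generate_assembly_panel(sim.PanelConfig(seed=1))


@pytest.fixture(scope="session")
def manifest(panel):
    """60-probe manifest (20 planted per class) with its truth table."""
    return sim.generate_probe_manifest(panel, sim.ManifestConfig(seed=2))


@pytest.fixture(scope="session")
def index_set(panel, params):
    return ConvertedIndexSet(build_converted_set(panel.base), params)


@pytest.fixture(scope="session")
def meth_dataset():
    return sim.generate_methylation_dataset(sim.MethylationConfig(seed=3))
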