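import warnings

import pytest

from struct2pk.distribution import ParameterSet
from struct2pk.physio import PhysiologyTable, TissueComposition
from struct2pk.synthio import SynthConfig, _base_structures, generate_library

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def phys() -> PhysiologyTable:
    return PhysiologyTable.default_rat()


@pytest.fixture(scope="session")
def comp() -> TissueComposition:
    return TissueComposition.default_rat()


@pytest.fixture(scope="session")
def base_smiles() -> list[str]:
    """The first 100 shipped drug-like structures."""
    return _base_structures()[:100]


@pytest.fixture(scope="session")
def tiny_library():
    """A small deterministic synthetic library shared across tests."""
    return generate_library(SynthConfig(n_compounds=60, seed=202))


@pytest.fixture()
def lipophilic_base() -> ParameterSet:
    return ParameterSet(
        fu=0.1, logp=3.5, mw=400.0, pka_base=9.5, cl_invivo=15.0, clint_microsomal=20.0
    )


@pytest.fixture()
def neutral_params() -> ParameterSet:
    return ParameterSet(fu=0.3, logp=2.0, mw=300.0, cl_invivo=12.0, clint_microsomal=10.0)
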