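import pytest

from minicoi.io import load_primer_table
from minicoi.sim import SimSpec, make_reference_panel


@pytest.fixture(scope="session")
def primers():
    return load_primer_table()


@pytest.fixture(scope="session")
def small_panel():
    """Six-species reference panel shared by QC/OTU tests."""
    return make_reference_panel(SimSpec(seed=7, n_species=6, n_samples=4,
                                        reads_per_sample=40))
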