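import pytest

from bbassign import shift_db, simgen
from bbassign.formats import ProteinSequence, SS
from bbassign.simgen import GeneratorParams


@pytest.fixture(scope="session")
def tables():
    return shift_db.load_default_tables()


@pytest.fixture(scope="session")
def default_sequence():
    return simgen.DEFAULT_SEQUENCE


@pytest.fixture(scope="session")
def clean_dataset(tables):
    """Noise-free, complete synthetic dataset (fixed seed)."""
    params = GeneratorParams(noise_hn=0.0, noise_n=0.0, noise_c=0.0,
                             retention=1.0, seed=11)
    return simgen.generate_dataset(params=params, tables=tables)


@pytest.fixture(scope="session")
def noisy_dataset(tables):
    """Default-noise, complete synthetic dataset (fixed seed)."""
    return simgen.generate_dataset(params=GeneratorParams(seed=7),
                                   tables=tables)


@pytest.fixture(scope="session")
def noisy_run(noisy_dataset, tables):
    return simgen.run_pipeline(noisy_dataset, tables=tables)


@pytest.fixture(scope="session")
def toy_sequence():
    # MET ALA GLY LEU SER GLU LYS ALA PHE ASP
    return ProteinSequence("MAGLSEKAFD")


@pytest.fixture(scope="session")
def toy_ss():
    return tuple([SS.COIL] * 10)
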