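import numpy as np
import pytest

from chopdrop import AlignmentParams, ProteomeSpec, build_database, generate_proteome

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def aln500():
    """Alignment parameters at zero resolution: G equals the 500 Da floor."""
    return AlignmentParams(G=500.0)


@pytest.fixture(scope="session")
def small_proteome():
    records, truth = generate_proteome(ProteomeSpec(n_proteins=30, seed=11))
    return records, truth


@pytest.fixture(scope="session")
def small_db(small_proteome):
    records, _ = small_proteome
    return build_database(records)


@pytest.fixture(scope="session")
def study_proteome():
    """The fixed 500-protein synthetic proteome used for accuracy studies."""
    records, truth = generate_proteome(ProteomeSpec(n_proteins=500, seed=20395))
    return records, truth


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(RESIDUES), size=length))


def random_fingerprint_pair(rng: np.random.Generator, max_len: int = 6):
    """Two random fingerprints with weights in the detectable range."""
    nx = rng.integers(0, max_len + 1)
    ny = rng.integers(0, max_len + 1)
    x = rng.uniform(500.0, 1600.0, size=nx)
    y = rng.uniform(500.0, 1600.0, size=ny)
    return x, y
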