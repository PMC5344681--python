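import numpy as np
import pytest

from adprscan.io import read_fasta
from adprscan.masses import ModifiedPeptide, get_species
from adprscan.simulate import NoiseModel


@pytest.fixture(scope="session")
def adpr():
    return get_species("ADPr")


@pytest.fixture(scope="session")
def demo_proteins():
    from importlib import resources

    path = resources.files("adprscan").joinpath("data", "demo_proteins.fasta")
    return read_fasta(str(path))


@pytest.fixture
def zero_noise():
    return NoiseModel.zero(seed=0)


@pytest.fixture
def adpr_peptide(adpr):
    """A tryptic demo peptide carrying ADPr on its serine."""
    return ModifiedPeptide("DWSAEQIR", placements={3: adpr})


def random_serine_peptide(rng: np.random.Generator, min_len=8, max_len=25) -> tuple[str, int]:
    """A random peptide with >= 2 serines; returns (sequence, true site index)."""
    alphabet = list("ACDEFGHIKLMNPQRTVWY")  # serines inserted explicitly
    n = int(rng.integers(min_len, max_len + 1))
    seq = [alphabet[i] for i in rng.integers(0, len(alphabet), n)]
    pos = rng.choice(n, size=2, replace=False)
    for p in pos:
        seq[p] = "S"
    true = int(rng.choice(pos)) + 1
    return "".join(seq), true
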