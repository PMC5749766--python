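import numpy as np
import pytest

from panmeta.synthetic_data import ALPHABET, PlantedPangenomeSpec, generate_pangenome


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(ALPHABET), size=length))


def mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Substitute n_subs distinct positions with a different residue."""
    seq = list(seq)
    for pos in rng.choice(len(seq), size=n_subs, replace=False):
        choices = [c for c in ALPHABET if c != seq[pos]]
        seq[pos] = choices[int(rng.integers(0, 19))]
    return "".join(seq)


@pytest.fixture(scope="session")
def small_pangenome():
    """6 strains, 10 core / 15 dispensable / 2 unique, low divergence."""
    spec = PlantedPangenomeSpec(
        n_strains=6,
        n_core=10,
        n_dispensable=15,
        n_unique_per_strain=2,
        protein_length_mean=100,
        protein_length_jitter=20,
        divergence=0.02,
        seed=101,
    )
    return generate_pangenome(spec)
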