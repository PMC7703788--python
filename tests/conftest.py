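import numpy as np
import pytest
from hypothesis import settings as _hsettings

_hsettings.register_profile("derandomized", derandomize=True, deadline=None)
_hsettings.load_profile("derandomized")

from contactlens import (
    ChainRecipe,
    ContactMap,
    MSA,
    contacts_from_distance,
    gen_chain,
)


def random_msa(rng: np.random.Generator, n: int, L: int) -> MSA:
    """A fully random alignment with gaps, X's, and a clean query row."""
    alphabet = list("ACDEFGHIKLMNPQRSTVWYX-")
    query = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=L))
    rows = [query]
    for _ in range(n - 1):
        rows.append("".join(rng.choice(alphabet, size=L)))
    return MSA(
        query_id="q",
        query_seq=query,
        rows=rows,
        row_ids=[f"r{i}" for i in range(n)],
    )


def random_contact_map(rng: np.random.Generator, L: int, threshold: float = 8.0) -> ContactMap:
    m = rng.random((L, L))
    m = np.triu(m, k=1)
    m = m + m.T
    return ContactMap(prob=m, threshold_angstrom=threshold)


@pytest.fixture
def rng():
    return np.random.default_rng(20230917)


@pytest.fixture
def toy_chain():
    """A 40-residue self-avoiding walk and its native distance matrix."""
    coords, dm = gen_chain(ChainRecipe(L=40, mode="random-walk", seed=7))
    return coords, dm


@pytest.fixture
def toy_native(toy_chain):
    _, dm = toy_chain
    return dm


@pytest.fixture
def toy_truth(toy_native):
    return contacts_from_distance(toy_native)
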