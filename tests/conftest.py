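import numpy as np
import pytest

from animalgmrf.pedigree import Pedigree, pedigree_from_parents


@pytest.fixture
def trio() -> Pedigree:
    """Two unrelated founders and their offspring."""
    return pedigree_from_parents(["1", "2", "3"], [None, None, "1"], [None, None, "2"])


@pytest.fixture
def founders_factory():
    def make(n: int) -> Pedigree:
        ids = [f"f{i}" for i in range(n)]
        return pedigree_from_parents(ids, [None] * n, [None] * n)

    return make


def random_pedigree(rng: np.random.Generator, n: int, n_founders: int | None = None) -> Pedigree:
    """Random acyclic pedigree: each non-founder draws parents among earlier ids."""
    if n_founders is None:
        n_founders = max(2, n // 5)
    sires, dams = [], []
    for i in range(n):
        if i < n_founders:
            sires.append(None)
            dams.append(None)
        else:
            sires.append(str(rng.integers(0, i)))
            dams.append(str(rng.integers(0, i)))
    return pedigree_from_parents([str(i) for i in range(n)], sires, dams)


@pytest.fixture
def random_pedigree_factory():
    return random_pedigree
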