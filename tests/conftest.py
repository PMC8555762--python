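import pytest

from dmrsq import load_item_bank, random_sort
from dmrsq.qsort import DEFAULT_DISTRIBUTION


@pytest.fixture(scope="session")
def bank():
    return load_item_bank()


@pytest.fixture(scope="session")
def dist():
    return DEFAULT_DISTRIBUTION


@pytest.fixture
def valid_sort():
    """A fixed uniformly random valid sort."""
    return random_sort(20240101)


def make_vignette_sort(vignette_items, seed=7):
    """A valid sort with the 14 vignette items in ranks 6-7 (6 at rank 7,
    8 at rank 6; the split is arbitrary) and the rest filled from a seeded
    shuffle of the remaining items."""
    import numpy as np

    items = list(vignette_items)
    assert len(items) == 14
    rest = [i for i in range(1, 151) if i not in items]
    rng = np.random.default_rng(seed)
    rng.shuffle(rest)
    assignment = {}
    for i in items[:6]:
        assignment[i] = 7
    for i in items[6:]:
        assignment[i] = 6
    caps = {1: 60, 2: 30, 3: 20, 4: 16, 5: 10}
    k = 0
    for rank, cap in caps.items():
        for _ in range(cap):
            assignment[rest[k]] = rank
            k += 1
    from dmrsq.qsort import QSort

    return QSort(assignment=assignment)
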