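import numpy as np
import pytest

from coopbarrier.cooperation import CoverInstance, ILPInstance


@pytest.fixture
def demo_cover() -> CoverInstance:
    """Small instance on which greedy (size 3) is beaten by exact (size 2):
    S1={3,4,5,6}, S2={1,3,5}, S3={2,4,6}."""
    return CoverInstance(
        6, [frozenset({3, 4, 5, 6}), frozenset({1, 3, 5}), frozenset({2, 4, 6})]
    )


@pytest.fixture
def cyclic_ilp() -> ILPInstance:
    """3-variable cyclic instance: LP optimum 1.5 at u=(1/2,1/2,1/2), ILP 2."""
    return ILPInstance(
        a=[[1, 1, 0], [0, 1, 1], [1, 0, 1]], r=[1, 1, 1], h=[1, 1, 1]
    )


def random_cover_instance(rng: np.random.Generator, max_m: int = 12, max_n: int = 8) -> CoverInstance:
    """Seeded random cover instance with every element covered."""
    m = int(rng.integers(3, max_m + 1))
    n = int(rng.integers(2, max_n + 1))
    sets = []
    for _ in range(n):
        size = int(rng.integers(1, m + 1))
        sets.append(set((rng.choice(m, size=size, replace=False) + 1).tolist()))
    covered = set().union(*sets)
    for e in range(1, m + 1):
        if e not in covered:
            sets[int(rng.integers(n))].add(e)
    return CoverInstance(m, [frozenset(s) for s in sets])
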