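import numpy as np
import pytest

from refmirna import CtTable, SimSpec, simulate_ct


def make_table(ct, candidates=None, groups=("G1", "G2"), condition="test"):
    """Small helper: CtTable from a 2-D array, samples split evenly in two groups."""
    ct = np.asarray(ct, dtype=float)
    k, n = ct.shape
    candidates = candidates or [chr(ord("A") + i) for i in range(k)]
    samples = [f"s{j+1}" for j in range(n)]
    half = n // 2
    group_of = {s: (groups[0] if j < half else groups[1]) for j, s in enumerate(samples)}
    return CtTable(candidates, samples, ct, group_of, condition)


def random_table(rng, k=7, n=10, low=18.0, high=30.0):
    """Uniform random Ct table with two equal groups."""
    return make_table(rng.uniform(low, high, size=(k, n)))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_abc():
    """Three candidates over four samples: A and B differ by a constant,
    C wobbles around A (differences 0, -1, 1, -1)."""
    return make_table(
        [[20, 21, 22, 23], [25, 26, 27, 28], [20, 22, 21, 24]],
        candidates=["A", "B", "C"],
    )


@pytest.fixture
def synthetic_table():
    table, truth = simulate_ct(SimSpec(seed=42))
    return table, truth
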