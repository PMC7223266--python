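import random

import pytest

from graphbwt.fixtures import FixtureSpec, fixture_f1, gen_fixture
from graphbwt.graph import reverse_path


def random_spec(rng: random.Random, seed: int, **overrides) -> FixtureSpec:
    """A fixture spec with sizes drawn inside the study bounds
    (<= 40 graph ids, <= 30 paths, path length <= 60)."""
    params = dict(
        seed=seed,
        max_nodes=rng.randint(5, 40),
        path_count=rng.randint(1, 30),
        max_path_length=rng.randint(3, 60),
        recomb_rate=rng.choice([0.0, 0.05, 0.2]),
        cycles=rng.random() < 0.3,
        bubble_density=rng.random(),
    )
    params.update(overrides)
    return FixtureSpec(**params)


def indexed_sequences(paths, both_orientations):
    """The sequence list an index over ``paths`` stores."""
    seqs = []
    for p in paths:
        seqs.append(tuple(p))
        if both_orientations:
            seqs.append(reverse_path(p))
    return seqs


@pytest.fixture
def f1():
    return fixture_f1()


@pytest.fixture
def f1_graph(f1):
    return f1[0]


@pytest.fixture
def f1_paths(f1):
    return f1[1]
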