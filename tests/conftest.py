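import numpy as np
import pytest

import wormnet as wn


@pytest.fixture
def two_neuron_connectome():
    """A -> gains 5 when B fires; B -> gains 1 when A fires."""
    edges = [
        wn.Edge(pre="B", post="A", kind="chemical", weight=5.0),
        wn.Edge(pre="A", post="B", kind="chemical", weight=1.0),
    ]
    return wn.connectome_from_edges(edges)


@pytest.fixture
def planted_small():
    """Two planted groups of 3 at periods 32 and 17 (h=30, drives 1 and 2)."""
    spec = wn.PlantedSpec(
        group_sizes=[3, 3], drive_per_group=[1.0, 2.0], threshold=30.0
    )
    conn, proto, periods = wn.generate_planted_frequency_network(spec, duration=256)
    return spec, conn, proto, periods


def random_connectome(rng: np.random.Generator, n_max: int = 6):
    """Small random simple digraph with signed integer weights."""
    n = int(rng.integers(2, n_max + 1))
    names = [f"N{k}" for k in range(n)]
    edges = []
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < 0.4:
                w = float(rng.integers(1, 11)) * (1 if rng.random() < 0.8 else -1)
                edges.append(
                    wn.Edge(pre=names[j], post=names[i], kind="chemical", weight=w)
                )
    if not edges:
        edges = [wn.Edge(pre=names[0], post=names[1], kind="chemical", weight=1.0)]
    return wn.connectome_from_edges(edges)


def scalar_step_oracle(values, W, h, external):
    """Naive one-neuron-at-a-time re-implementation of the update rule."""
    n = len(values)
    nxt = np.empty(n)
    for i in range(n):
        if values[i] > h:
            nxt[i] = 0.0
        else:
            acc = values[i] + external[i]
            for j in range(n):
                if values[j] > h:
                    acc += W[i, j]
            nxt[i] = acc
    return nxt
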