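import numpy as np
import pytest
import scipy.sparse as sp

import hyperfill as hf
from hyperfill.gem_io import GemModel, merge_pool
from hyperfill.model import ModelConfig, init_params
from hyperfill.training import TrainConfig, train


def empty_pool(draft: GemModel) -> GemModel:
    return GemModel(
        metabolites=list(draft.metabolites), reactions=[], H=sp.csc_matrix((draft.n, 0))
    )


@pytest.fixture(scope="session")
def small_synth():
    """Small planted hypergraph with holdout and decoys (seeded)."""
    return hf.generate(
        hf.SynthConfig(
            n_metabolites=60,
            n_reactions=80,
            n_communities=3,
            holdout_fraction=0.1,
            n_decoys=20,
            seed=7,
        )
    )


@pytest.fixture(scope="session")
def small_universe(small_synth):
    return small_synth.to_universe()


@pytest.fixture(scope="session")
def toy_params():
    """Reference parameters at full width for per-edge operation tests."""
    rng = np.random.default_rng(42)
    return init_params(rng, m_features=30, cfg=ModelConfig())


@pytest.fixture(scope="session")
def trained_small(small_universe):
    """One fully trained small model shared by scoring-level tests."""
    cfg = TrainConfig(epochs=30, negatives_per_positive=4, seed=5, embed_dim=64, mlp_hidden=32)
    return train(small_universe, cfg), cfg


def random_edges(rng, n_edges, n_vertices, max_side=4, allow_empty_side=False):
    edges = []
    for _ in range(n_edges):
        lo = 0 if allow_empty_side else 1
        k = int(rng.integers(lo, max_side + 1))
        l = int(rng.integers(lo if k > 0 else 1, max_side + 1))
        if k + l == 0:
            k = 1
        verts = rng.choice(n_vertices, size=k + l, replace=False)
        edges.append(hf.Hyperedge(substrates=tuple(verts[:k]), products=tuple(verts[k:])))
    return edges
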