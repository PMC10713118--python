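"""Shared fixtures: synthetic references and trained models.

Heavy objects (the default-size reference and its trained model) are
session-scoped so the whole suite trains each model once.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import census as cs

warnings.filterwarnings("ignore", message=".*zero-centering.*")


@pytest.fixture(scope="session")
def default_ref():
    """Default-size synthetic reference: 8 types x 200 cells x 2000 genes."""
    ref, tree, marker_map = cs.generate(cs.GeneratorSpec(seed=1))
    return ref, tree, marker_map


@pytest.fixture(scope="session")
def split(default_ref):
    """Seeded 70/30 train/test split of the default reference."""
    ref, tree, _ = default_ref
    rng = np.random.default_rng(7)
    idx = rng.permutation(ref.matrix.n_cells)
    n_tr = int(0.7 * len(idx))
    train = ref.subset_cells(np.sort(idx[:n_tr]))
    test = ref.subset_cells(np.sort(idx[n_tr:]))
    return train, test


@pytest.fixture(scope="session")
def model(split):
    """Full hierarchical model trained on the 70% split."""
    train, _ = split
    return cs.train_census(train, cs.RunConfig(seed=11))


@pytest.fixture(scope="session")
def holdout_result(model, split):
    """Annotation of the held-out 30% with the session model."""
    _, test = split
    return cs.annotate(model, test.matrix, cs.RunConfig(seed=11))


@pytest.fixture(scope="session")
def tiny_ref():
    """Small 4-type reference for fast unit tests."""
    spec = cs.GeneratorSpec(
        labels=("alpha", "beta", "gamma", "delta"),
        n_cells_per_type=40,
        n_genes=300,
        markers_per_branch=10,
        seed=3,
    )
    return cs.generate(spec)


@pytest.fixture(scope="session")
def tiny_model(tiny_ref):
    ref, _, _ = tiny_ref
    cfg = cs.RunConfig(seed=5)
    cfg.booster_params.update(n_estimators=20)
    return cs.train_census(ref, cfg)


def dummy_embedding(n_cells: int) -> cs.EmbeddingClusters:
    """Placeholder embedding for runs with stabilization disabled."""
    return cs.EmbeddingClusters(
        coords=np.zeros((n_cells, 2)), fine_cluster=np.zeros(n_cells, dtype=int)
    )
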