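"""Shared fixtures.

Heavy, session-scoped fixtures build the full-scale seed-0 study once
(training the encoder on the two extreme groups takes ~30 s); unit
tests use much smaller cohorts.  The *scaled evaluation profile* keeps
the generator's scientific settings (density, attenuation, noise,
progression means) at their defaults while shrinking node and subject
counts so cross-validation protocols finish in minutes.
"""

from __future__ import annotations

import numpy as np
import pytest

import connstage as cs

# scaled evaluation profile for cross-validation protocols
SCALED_COHORT = cs.CohortConfig(n_per_group=(8, 12, 6), n_nodes=50, seed=0)


def random_binary_graph(rng: np.random.Generator, n: int,
                        p: float = 0.4) -> np.ndarray:
    a = (rng.random((n, n)) < p).astype(float)
    a = np.triu(a, 1)
    return a + a.T


@pytest.fixture(scope="session")
def default_cohort():
    """Full-scale synthetic cohort (24/46/18 subjects, 148 nodes, seed 0)."""
    return cs.generate_cohort(cs.CohortConfig())


@pytest.fixture(scope="session")
def default_study(default_cohort):
    """Full-scale study state: trained extreme-group model, manifold,
    and coordinates of all subjects."""
    cfg = cs.StudyConfig()
    graphs = [cs.binarize(c) for c in default_cohort]
    model, extreme_graphs = cs.train_extreme_model(graphs, cfg)
    emb_extremes = cs.embed_dataset(extreme_graphs, model)
    pca = cs.fit_pca(emb_extremes, k=2, anchor_label="G2")
    emb_all = cs.embed_dataset(graphs, model)
    coords = cs.project_table(pca, emb_all)
    return dict(cfg=cfg, cohort=default_cohort, graphs=graphs, model=model,
                emb_extremes=emb_extremes, pca=pca, coords=coords)


@pytest.fixture(scope="session")
def scaled_graphs():
    """Binarized scaled-profile cohort for cross-validation tests."""
    return [cs.binarize(c) for c in cs.generate_cohort(SCALED_COHORT)]


def make_toy_task(n_per_class: int = 4, n_nodes: int = 12):
    """Trivially separable toy dataset: empty vs complete graphs."""
    graphs, labels = [], []
    for i in range(n_per_class):
        empty = np.zeros((n_nodes, n_nodes))
        full = np.ones((n_nodes, n_nodes)) - np.eye(n_nodes)
        graphs.append(cs.BinarizedGraph(empty, np.eye(n_nodes),
                                        subject_id=f"empty_{i}", group="G0"))
        graphs.append(cs.BinarizedGraph(full, np.eye(n_nodes),
                                        subject_id=f"full_{i}", group="G2"))
        labels += ["G0", "G2"]
    return graphs, labels


@pytest.fixture(scope="session")
def toy_task():
    return make_toy_task(n_per_class=10, n_nodes=20)


@pytest.fixture(scope="session")
def toy_task_small():
    return make_toy_task(n_per_class=4, n_nodes=12)
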