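"""Shared fixtures.

The expensive objects — the default 6 x 20,000-gene synthetic cohort, the
full hierarchical model and its leave-one-out fold models — are built once
per session and shared by the model, validation and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from chromacc.gene_labeling import assign_accessibility
from chromacc.hierarchical_model import TrainingConfig, fit_hierarchical
from chromacc.synthetic_data import SimulationParams, simulate_training_set

#: Desk-scale training configuration used throughout the suite: fewer
#: bottom-layer trees and boosting rounds than the full-scale defaults so
#: the whole suite runs on one CPU in minutes.
DESK_CONFIG = TrainingConfig(n_lb_trees=150, boost_rounds=30, seed=7)


@pytest.fixture(scope="session")
def sim_params() -> SimulationParams:
    return SimulationParams()


@pytest.fixture(scope="session")
def cohort(sim_params):
    """Six synthetic cell types sharing one annotation (default conditions)."""
    return simulate_training_set(sim_params, 6, seed=1)


@pytest.fixture(scope="session")
def training_samples(cohort):
    """(expression, hotspot-derived labels) pairs, the model's training input."""
    return [(s.expression, assign_accessibility(s.hotspots, s.genes)) for s in cohort]


@pytest.fixture(scope="session")
def full_model(training_samples):
    return fit_hierarchical(training_samples, DESK_CONFIG)


@pytest.fixture(scope="session")
def fold_models(training_samples):
    """Leave-one-sample-out models, fold i trained without sample i."""
    return [
        fit_hierarchical(
            [s for j, s in enumerate(training_samples) if j != i], DESK_CONFIG
        )
        for i in range(len(training_samples))
    ]


# ---------------------------------------------------------------------------
# Small toy helpers
# ---------------------------------------------------------------------------


@pytest.fixture()
def separable_profile():
    """200 genes, open iff FPKM > 1: a perfectly separable 1-D toy."""
    rng = np.random.default_rng(42)
    low = rng.uniform(0.0, 0.9, size=100)
    high = rng.uniform(1.1, 10.0, size=100)
    e = np.concatenate([low, high])
    ids = [f"g{i}" for i in range(200)]
    expression = pd.Series(e, index=ids)
    labels = e > 1.0
    return expression, labels


def make_tiny_training_set(n_genes=400, n_samples=3, seed=0, **overrides):
    """A small cohort + labels for structural tests."""
    params = SimulationParams(n_genes=n_genes, n_chromosomes=2, **overrides)
    samples = simulate_training_set(params, n_samples, seed=seed)
    training = [
        (s.expression, assign_accessibility(s.hotspots, s.genes)) for s in samples
    ]
    return params, samples, training


TINY_CONFIG = TrainingConfig(
    n_lb_trees=25, subsample_size=200, boost_rounds=8, seed=3
)
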