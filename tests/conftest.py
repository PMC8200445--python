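"""Shared fixtures: tiny hand-built datasets and a reusable synthetic group."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from coexmeta.config import PipelineConfig
from coexmeta.io import ExpressionDataset
from coexmeta.preprocess import preprocess_group
from coexmeta.simulate import SimulationSpec, simulate_group


def make_dataset(X, n_pairs=None, dataset_id="D1", condition="other",
                 genes=None) -> ExpressionDataset:
    """Build a paired dataset from a genes x samples array.

    Samples are ordered (pre, post) per subject, matching the simulator.
    """
    X = np.asarray(X, dtype=float)
    n_genes, n_samples = X.shape
    assert n_samples % 2 == 0
    n_pairs = n_samples // 2 if n_pairs is None else n_pairs
    genes = genes or [f"G{i + 1:03d}" for i in range(n_genes)]
    subjects = [f"{dataset_id}_S{j + 1}" for j in range(n_pairs)]
    sheet = pd.DataFrame({
        "sample_id": [f"{s}_{tp}" for s in subjects for tp in ("pre", "post")],
        "subject_id": np.repeat(subjects, 2),
        "timepoint": ["pre", "post"] * n_pairs,
    })
    return ExpressionDataset(dataset_id=dataset_id, condition=condition,
                             genes=genes, X=X, samples=sheet)


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig(seed=17)


@pytest.fixture(scope="session")
def small_group(config):
    """Three preprocessed datasets with two planted 80-gene modules
    (600 genes, 15 pairs), shared across tests that need a real network."""
    spec = SimulationSpec(n_genes=600, module_sizes=(80, 80),
                          n_pairs=15, seed=41)
    datasets, truth = simulate_group(config, spec)
    processed, _ = preprocess_group(datasets)
    return processed, truth
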