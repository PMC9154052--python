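"""Shared fixtures.

The expensive desk-scale simulations (100 repertoires × 2,000 sequences)
are session-scoped so the parameter-recovery datasets and their nested-CV
results are computed once and shared between the tests that inspect them.
"""

from __future__ import annotations

import numpy as np
import pytest

import airrbench as ab

#: master seed for the desk-scale study fixtures, fixed once
STUDY_SEED = 20250925

#: the parameter-recovery cell: witness count 10 per 2,000-sequence
#: repertoire (rate 0.5%), 100 repertoires, three ungapped 4-mers
RECOVERY_CELL = ab.ExperimentCell(
    witness_rate=0.5, n_examples=100, repertoire_size=2000, n_motifs=3, motif_size=4
)

NULL_CELL = ab.ExperimentCell(
    witness_rate=0.0, n_examples=100, repertoire_size=2000, n_motifs=3, motif_size=4
)


def _seeds(tag: str, n: int) -> list[int]:
    entropy = [STUDY_SEED, sum(map(ord, tag))]
    state = np.random.SeedSequence(entropy).generate_state(n, dtype=np.uint64)
    return [int(s & 0x7FFFFFFF) for s in state]


@pytest.fixture(scope="session")
def recovery_runs():
    """Three recovery-cell replications: dataset, encoding, nested CV."""
    runs = []
    for seed in _seeds("recovery", 3):
        dataset = ab.simulate_cell_dataset(RECOVERY_CELL, seed=seed)
        encoded = ab.encode_dataset(dataset, 4)
        result = ab.nested_cv(
            encoded, ab.TrainingConfig(seed=seed), y=dataset.labels, return_models=True
        )
        runs.append({"dataset": dataset, "encoded": encoded, "cv": result, "seed": seed})
    return runs


@pytest.fixture(scope="session")
def null_runs():
    """Three no-signal replications of the same setup."""
    runs = []
    for seed in _seeds("null", 3):
        dataset = ab.simulate_cell_dataset(NULL_CELL, seed=seed)
        encoded = ab.encode_dataset(dataset, 4)
        result = ab.nested_cv(encoded, ab.TrainingConfig(seed=seed), y=dataset.labels)
        runs.append({"dataset": dataset, "encoded": encoded, "cv": result, "seed": seed})
    return runs


@pytest.fixture
def small_model():
    """Sequence model with a short, fast length distribution."""
    return ab.SequenceModel(
        length_distribution=ab.LengthDistribution.default(mean=12.0, sd=1.5, min_length=10, max_length=14)
    )
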