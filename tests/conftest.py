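"""Shared fixtures: small ground-truth systems with known properties."""

import numpy as np
import pytest

from msmbind.synthetic import (
    GroundTruthSpec,
    build_ground_truth_model,
    default_ground_truth_spec,
)


@pytest.fixture(scope="session")
def preset_model():
    """The seven-conformation default preset (hub topology, one bound-only set)."""
    return build_ground_truth_model(default_ground_truth_spec(seed=0))


@pytest.fixture(scope="session")
def two_state_spec():
    """Single conformation, bound/unbound, equal weights."""
    return GroundTruthSpec(
        n_conformations=1,
        substates_per_conformation=[["bound", "unbound"]],
        conformational_exchange_weight=1e-3,
        binding_exchange_weight=0.1,
        substate_stationary_weights=[[1.0, 1.0]],
    )


@pytest.fixture(scope="session")
def ten_state_model():
    """Five conformations x (bound, unbound): a 10-state reversible truth."""
    spec = GroundTruthSpec(
        n_conformations=5,
        substates_per_conformation=[["bound", "unbound"]] * 5,
        conformational_exchange_weight=2e-3,
        binding_exchange_weight=0.15,
        substate_stationary_weights=[[1.0, 2.0], [3.0, 1.0], [1.5, 1.5], [2.0, 0.5], [1.0, 1.0]],
    )
    return build_ground_truth_model(spec)


def random_reversible_matrix(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Random reversible transition matrix and its stationary distribution."""
    S = rng.random((n, n)) + 0.1
    S = S + S.T
    row = S.sum(axis=1)
    return S / row[:, None], row / row.sum()
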