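import logging

import numpy as np
import pytest

from mirtempo import AnalysisConfig, CountMatrix
from mirtempo.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture(autouse=True)
def _quiet_qc_logs(caplog):
    # replicate exclusions and degenerate-variance decisions are logged by
    # design; keep test output readable
    logging.getLogger("mirtempo").setLevel(logging.ERROR)


@pytest.fixture
def small_matrix() -> CountMatrix:
    """3 features x 3 time points x 2 replicates with well-correlated reps."""
    counts = np.array(
        [
            [[10, 12], [20, 22], [30, 29]],
            [[5, 6], [4, 5], [3, 4]],
            [[100, 98], [110, 112], [90, 91]],
        ],
        dtype=float,
    )
    return CountMatrix(
        feature_names=["miR-a", "miR-b", "miR-c"],
        counts=counts,
        n_timepoints=3,
        n_replicates=2,
    )


@pytest.fixture
def config3x2() -> AnalysisConfig:
    return AnalysisConfig(n_replicates=2, n_timepoints=3)


@pytest.fixture
def null_dataset():
    """All-null synthetic matrix: 200 features, 4 time points, 2 replicates."""
    spec = SyntheticSpec(
        n_features=200, n_timepoints=4, n_replicates=2,
        frac_linear=0.0, frac_transient=0.0, seed=7,
    )
    return generate_dataset(spec)
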