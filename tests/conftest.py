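import numpy as np
import pytest

import topomark as tm
from topomark.core_io import RoiMatrix


@pytest.fixture(scope="session")
def registry():
    return tm.load_registry()


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic cohort shared across read-only tests."""
    return tm.simulate_cohort(tm.SyntheticConfig(seed=1))


def make_matrix(values, modality="tau", prefix="r"):
    """Small RoiMatrix from a raw array (values must be positive SUVR)."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return RoiMatrix(
        subject_ids=tuple(f"s{i:03d}" for i in range(n)),
        modality=modality,
        values=values,
        region_ids=tuple(f"{prefix}{j:02d}" for j in range(m)),
    )


@pytest.fixture
def make_roi_matrix():
    return make_matrix
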