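import numpy as np
import pandas as pd
import pytest

from cantare.dataset_io import OmicsDataset
from cantare.simulate import demo_spec, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted-signal cohort shared by read-only tests."""
    spec = demo_spec(seed=7, scale=0.08)
    dataset, truth = simulate(spec)
    return dataset, truth, spec


@pytest.fixture
def tiny_dataset():
    """A hand-sized two-ome dataset (8 samples, 3 + 4 analytes)."""
    rng = np.random.default_rng(11)
    ids = [f"S{i}" for i in range(8)]
    mb = pd.DataFrame(
        rng.uniform(0, 0.1, size=(8, 3)),
        index=ids,
        columns=["mb_a", "mb_b", "mb_c"],
    )
    met = pd.DataFrame(
        rng.lognormal(5, 1, size=(8, 4)),
        index=ids,
        columns=["met_w", "met_x", "met_y", "met_z"],
    )
    covs = pd.DataFrame(
        {"age": rng.uniform(20, 70, 8), "calprotectin": rng.lognormal(4, 1, 8)},
        index=ids,
    )
    group = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    return OmicsDataset(
        sample_ids=ids, group=group, covariates=covs, omes={"mb": mb, "met": met}
    )
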