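import numpy as np
import pytest

from mrnome import SummaryDataset


def make_dataset(beta_exposure, se_exposure, beta_outcome, se_outcome, ids=None):
    beta_exposure = np.asarray(beta_exposure, dtype=float)
    n = beta_exposure.shape[0]
    if ids is None:
        ids = [f"rs{i + 1}" for i in range(n)]
    return SummaryDataset(
        variant_id=np.array(ids, dtype=object),
        beta_exposure=beta_exposure,
        se_exposure=np.asarray(se_exposure, dtype=float),
        beta_outcome=np.asarray(beta_outcome, dtype=float),
        se_outcome=np.asarray(se_outcome, dtype=float),
    )


@pytest.fixture
def dataset_factory():
    return make_dataset


@pytest.fixture
def random_dataset():
    """A moderately sized random but reproducible dataset."""
    rng = np.random.default_rng(20160914)
    n = 8
    return make_dataset(
        beta_exposure=rng.uniform(0.1, 0.7, n),
        se_exposure=rng.uniform(0.02, 0.06, n),
        beta_outcome=rng.normal(0.3, 0.2, n),
        se_outcome=rng.uniform(0.04, 0.12, n),
    )
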