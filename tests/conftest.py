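import numpy as np
import pytest

from mclmm import MultiContextData


def random_instance(rng, n=6, t=3, c=2, missing=0.3, sigma_g2=0.4, sigma_e2=0.2):
    """Random multi-context dataset with a valid missingness pattern."""
    if c > 1:
        covs = np.column_stack([np.ones(n), rng.normal(size=(n, c - 1))])
    else:
        covs = np.ones((n, 1))
    g = rng.normal(scale=np.sqrt(sigma_g2), size=(n, 1))
    y = g + rng.normal(scale=np.sqrt(sigma_e2), size=(n, t))
    if missing > 0:
        mask = rng.random((n, t)) < missing
        for i in range(n):  # every individual keeps >= 1 context
            if mask[i].all():
                mask[i, rng.integers(t)] = False
        for j in range(t):  # every context keeps >= 1 observation
            if mask[:, j].all():
                mask[rng.integers(n), j] = False
        y = np.where(mask, np.nan, y)
    return MultiContextData(responses=y, covariates=covs)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
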