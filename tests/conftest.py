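import numpy as np
import pandas as pd
import pytest

from alffpipe.pipeline import cohort_to_features
from alffpipe.synthetic import SyntheticConfig, generate_cohort


def make_config(**kw) -> SyntheticConfig:
    """Small, fast cohort defaults for unit/integration tests."""
    defaults = dict(
        n_subjects=10,
        n_regions=40,
        volume_dims=(10, 10, 6),
        n_volumes=96,
        planted_regions=tuple(range(1, 6)),
        effect_size=1.5,
        seed=7,
    )
    defaults.update(kw)
    return SyntheticConfig(**defaults)


@pytest.fixture(scope="session")
def strong_cohort():
    """Shared small cohort with a clear planted effect."""
    return generate_cohort(make_config())


@pytest.fixture(scope="session")
def strong_features(strong_cohort):
    return cohort_to_features(strong_cohort)


def make_paired_features(n_subjects, n_regions, effect, planted, rng):
    """Paired +-1-labelled Gaussian features without the imaging stack.

    Subject random intercepts induce the pre/post correlation; ``planted``
    columns get a ``effect``-sd post-condition shift.
    """
    sids = np.repeat(np.arange(1, n_subjects + 1), 2)
    labels = np.tile([-1, 1], n_subjects)
    X = rng.normal(size=(2 * n_subjects, n_regions))
    X += np.repeat(rng.normal(scale=1.0, size=(n_subjects, 1)), 2, axis=0)
    for j in planted:
        X[labels == 1, j - 1] += effect
    values = pd.DataFrame(X, columns=list(range(1, n_regions + 1)))
    return values, labels, sids
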