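import numpy as np
import pytest

import metalsite as m


@pytest.fixture(scope="session")
def study_dataset():
    """Small synthetic study at the default conditions (3σ PSSM signal)."""
    return m.generate_dataset(m.FixtureSpec(n_chains=12, seed=11))


@pytest.fixture(scope="session")
def study_features(study_dataset):
    return study_dataset.assemble()


@pytest.fixture(scope="session")
def trained_cascade():
    """A cascade trained on 12 chains with a fast forest; returns
    (dataset, feature matrices, model)."""
    ds = m.generate_dataset(m.FixtureSpec(n_chains=12, seed=21))
    fms = ds.assemble()
    model = m.train_cascade(
        ds.chains, fms, seed=21, factory=m.rf_factory(m.RFParams(n_trees=80))
    )
    return ds, fms, model


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
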