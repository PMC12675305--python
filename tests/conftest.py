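import logging

import numpy as np
import pytest

from pgdas import model, popgraph, synthdata

logging.disable(logging.WARNING)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact planted two-biotype cohort used across the suite."""
    cfg = synthdata.SynthConfig(n_subjects=60, n_rois=15, seed=7)
    return synthdata.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_graph(small_cohort):
    return popgraph.build_population_graph(small_cohort.features(),
                                           small_cohort.phenotypes)


@pytest.fixture(scope="session")
def fast_train():
    """A light training configuration sized for the small fixture cohort."""
    return model.TrainConfig(ae_hidden=(64, 32), embed_dim=16,
                             pretrain_epochs=15, max_epochs=50, seed=3)


@pytest.fixture(scope="session")
def small_state(small_graph, fast_train):
    return model.fit(small_graph, fast_train)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
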