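import dataclasses

import numpy as np
import pandas as pd
import pytest

from trisomics.matrix import OmicsMatrix
from trisomics.pipeline import analyze_cohort
from trisomics.sim import (CellConfig, CovariateEffects, MetabConfig, PanelConfig,
                           SimConfig, simulate_cohort)

SESSION_SEED = 0


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort shared across the suite."""
    return simulate_cohort(seed=SESSION_SEED)


@pytest.fixture(scope="session")
def analysis(cohort):
    """Full pipeline result on the default cohort (100 consensus resamples)."""
    return analyze_cohort(cohort, max_k=6, n_iter=100, p_item=0.8, seed=SESSION_SEED)


def noise_free_config(**overrides) -> SimConfig:
    """Config with every stochastic term silenced; planted effects remain."""
    base = dict(
        noise_sd=0.0,
        latent_loading=0.0,
        subtype_profile_sd=0.0,
        dosage_gene_sd=0.0,
        effect_jitter=0.0,
        covariate_effects=CovariateEffects(0.0, 0.0, 0.0),
        panel_config=dataclasses.replace(PanelConfig(), msd_noise_sd=0.0,
                                         soma_noise_sd=0.0),
        metab_config=dataclasses.replace(MetabConfig(), noise_sd=0.0, zero_rate=0.0,
                                         sample_scale_sd=0.0),
        cell_config=dataclasses.replace(CellConfig(), noise_sd=0.0, cbc_noise_sd=0.0),
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture
def tiny_matrix():
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0], [5.0, 5.0, 5.0, 5.0]],
        index=["f1", "f2", "f3"], columns=["s1", "s2", "s3", "s4"])
    return OmicsMatrix(values, "toy", "units")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
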