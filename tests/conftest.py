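import numpy as np
import pandas as pd
import pytest

from skinyouth import SimulationConfig, simulate_study
from skinyouth.matrix import ExpressionMatrix


@pytest.fixture(scope="session")
def default_study():
    """One simulated study at the default (study-scale) conditions."""
    return simulate_study(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def strong_phenotype_config():
    """Generator settings with a strong latent-youthfulness signal:
    wide latent delta spread relative to clinician rating noise."""
    return dict(rater_sd=1.5, delta_noise_base=3.0, delta_noise_age=0.25)


def make_matrix(values: np.ndarray, stage: str = "log2") -> ExpressionMatrix:
    g, s = values.shape
    return ExpressionMatrix(
        pd.DataFrame(
            values,
            index=[f"g{i}" for i in range(g)],
            columns=[f"s{j}" for j in range(s)],
        ),
        stage=stage,
    )
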