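import numpy as np
import pandas as pd
import pytest

from tucr.preprocess import ExpressionMatrix
from tucr.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture
def small_config() -> SyntheticConfig:
    """A desk-scale experiment: 12 UCRs x 2 strands over 4 systems."""
    return SyntheticConfig(
        n_ucrs=12,
        n_groups=4,
        samples_per_group=3,
        noise_sd_log2=0.3,
        absent_rate=0.0,
        seed=11,
    )


@pytest.fixture
def small_dataset(small_config):
    return generate_dataset(small_config)


def random_matrix(n_probes: int, n_samples: int, seed: int) -> ExpressionMatrix:
    rng = np.random.default_rng(seed)
    values = pd.DataFrame(
        rng.lognormal(5.0, 1.0, size=(n_probes, n_samples)),
        index=[f"uc.{i + 1}-plus" for i in range(n_probes)],
        columns=[f"s{j + 1}" for j in range(n_samples)],
    )
    return ExpressionMatrix(values, "linear")
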