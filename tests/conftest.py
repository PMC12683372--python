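import numpy as np
import pandas as pd
import pytest

import shellbed as sb


@pytest.fixture(scope="session")
def small_seascape() -> sb.Seascape:
    return sb.generate_seascape(nrows=60, ncols=60, seed=11)


@pytest.fixture(scope="session")
def species_truths(small_seascape):
    params = sb.default_species_params()
    return {sp: sb.generate_truth(small_seascape, p, seed=100 + i)
            for i, (sp, p) in enumerate(params.items())}


@pytest.fixture(scope="session")
def survey(small_seascape, species_truths) -> pd.DataFrame:
    design = sb.default_design(n_sites=400, seed=7, seascape=small_seascape)
    return sb.sample_sites(small_seascape, species_truths, design)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def fast_grid() -> dict:
    """Single-point boosting grid used where tuning is not under test."""
    return {"learning_rate": [0.1], "n_estimators": [100],
            "min_samples_leaf": [10]}
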