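import numpy as np
import pandas as pd
import pytest

from childhte import EffectSpec, SimConfig, generate_dataset


@pytest.fixture(scope="session")
def small_confounded():
    """A small confounded cohort with constant effect 0.5 (seeded)."""
    cfg = SimConfig(n_total=1200, seed=11, effect_spec=EffectSpec(tau0=0.5))
    ds, truth = generate_dataset(cfg)
    return ds, truth


@pytest.fixture()
def toy_covariates():
    rng = np.random.default_rng(5)
    n = 40
    return pd.DataFrame(
        {
            "x1": rng.normal(size=n),
            "x2": rng.normal(size=n),
        }
    )
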