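import numpy as np
import pandas as pd
import pytest

from sweptrial import GeneratorConfig, default_design, generate_trial


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def trial_data(design):
    """One moderate synthetic trial reused across read-only tests."""
    cfg = GeneratorConfig(
        design=design, seed=20210701, cluster_size_mean_per_period=450.0
    )
    return generate_trial(cfg)


@pytest.fixture(scope="session")
def toy_gee_data():
    """Printed 3-cluster, 12-row dataset for hand-checkable GEE fits."""
    # every period x arm cell is covered by two clusters, so the
    # cluster leverages stay below one and the Mancl-DeRouen
    # correction is well defined
    df = pd.DataFrame(
        {
            "cluster": ["A"] * 4 + ["B"] * 4 + ["C"] * 4,
            "period": [1, 1, 2, 2] * 3,
            "treatment": [0, 0, 1, 1, 0, 1, 0, 1, 1, 1, 0, 0],
            "y": [1, 0, 1, 1, 0, 1, 1, 0, 1, 0, 0, 1],
        }
    )
    X = pd.DataFrame(
        {
            "treatment": df["treatment"].astype(float),
            "period_2": (df["period"] == 2).astype(float),
        }
    )
    return df, X


@pytest.fixture(scope="session")
def small_trial_config(design):
    """Analysis-cohort generator sized for repeated simulation."""
    return GeneratorConfig.uniform_cohort(
        design=design,
        baseline_p=0.40,
        intervention_rr=0.85,
        icc=0.02,
        cac=0.90,
        cluster_size_mean_per_period=60.0,
        cluster_size_cv=0.30,
        seed=0,
    )
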