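import numpy as np
import pandas as pd
import pytest

from methylestimand import MethylationMatrix, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def beta_grid():
    """Dense Beta grid away from the boundary for transform properties."""
    return np.linspace(1e-6, 1 - 1e-6, 10_001)


@pytest.fixture()
def two_group_meta():
    """Minimal balanced 6-sample metadata table."""
    return pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(6)],
            "group": ["Placebo"] * 3 + ["Treatment"] * 3,
            "age": [48.0, 52.0, 50.0, 49.0, 51.0, 50.0],
            "sex": [0, 1, 0, 1, 0, 1],
        }
    )


@pytest.fixture()
def constant_matrix(two_group_meta):
    """Beta matrix with constant within-group values 0.2 / 0.3."""
    values = pd.DataFrame(
        [[0.2, 0.2, 0.2, 0.3, 0.3, 0.3], [0.45, 0.45, 0.45, 0.55, 0.55, 0.55]],
        index=["cg1", "cg2"],
        columns=two_group_meta["sample_id"],
    )
    return MethylationMatrix(values, "beta")


@pytest.fixture(scope="session")
def confounded_cohort():
    """One mid-size confounded cohort shared across estimator tests."""
    cfg = SimulationConfig(
        n_per_group=2000,
        beta0_placebo=0.101,
        delta_beta=0.10,
        confounder_fraction=0.20,
        n_cpg=20,
        seed=11,
    )
    matrix, meta, truth = simulate_cohort(cfg)
    return cfg, matrix, meta, truth
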