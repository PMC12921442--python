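import numpy as np
import pandas as pd
import pytest

from dhgomics.matrix import IntensityMatrix
from dhgomics.simulate import SimulationConfig, generate_cohort


def make_matrix(values, groups, feature_ids=None, sample_ids=None,
                cohort="discovery"):
    """Build an IntensityMatrix from a 2-D array and group labels."""
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    feature_ids = feature_ids or [f"F{i}" for i in range(n_feat)]
    sample_ids = sample_ids or [f"S{j}" for j in range(n_samp)]
    samples = pd.DataFrame({"group": list(groups), "cohort": cohort},
                           index=pd.Index(sample_ids, name="sample_id"))
    return IntensityMatrix(
        pd.DataFrame(values, index=feature_ids, columns=sample_ids), samples)


def gaussian_two_group(rng, n_feat=40, n_per_group=10, n_informative=0,
                       effect=0.0, noise_sd=0.5):
    """Small log-scale two-group matrix (linear intensities) for model tests."""
    n = 2 * n_per_group
    base = rng.uniform(12, 20, size=n_feat)
    logv = base[:, None] + rng.normal(0, noise_sd, size=(n_feat, n))
    logv[:n_informative, :n_per_group] += effect
    groups = ["case"] * n_per_group + ["control"] * n_per_group
    return make_matrix(2.0 ** logv, groups)


@pytest.fixture(scope="session")
def cohort_effect2():
    """The reference simulated discovery cohort (defaults, strong effect)."""
    cfg = SimulationConfig(seed=1)
    met, prot, truth = generate_cohort(cfg)
    return cfg, met, prot, truth
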