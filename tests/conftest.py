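import numpy as np
import pandas as pd
import pytest

from txpod import DoseResponseSet, RunConfig, SimConfig, simulate_platform_study


@pytest.fixture(scope="session")
def doses20() -> np.ndarray:
    """Per-sample doses for a 4-group design with n = 5."""
    return np.repeat([0.0, 2.0, 4.0, 8.0], 5)


@pytest.fixture(scope="session")
def small_microarray():
    """A small uncompressed microarray-like study with ground truth."""
    cfg = SimConfig(n_genes=200, frac_responders=0.5, noise_sd=0.25,
                    compression_factor=1.0, n_per_dose=(5, 5, 5, 5), seed=101)
    return simulate_platform_study(cfg, "microarray")


@pytest.fixture(scope="session")
def small_rnaseq():
    cfg = SimConfig(n_genes=300, frac_responders=0.3, noise_sd=0.25, seed=202)
    return simulate_platform_study(cfg, "rnaseq")


@pytest.fixture()
def tiny_dset() -> DoseResponseSet:
    """3 genes x 8 samples, 4 dose groups of n = 2."""
    cols = [f"s{i}" for i in range(8)]
    doses = pd.Series([0, 0, 2, 2, 4, 4, 8, 8], index=cols, dtype=float)
    vals = pd.DataFrame(
        [[1.0, 1.2, 1.9, 2.1, 3.0, 3.2, 4.9, 5.1],
         [5.0, 5.0, 5.0, 5.0, 5.0, 5.0, 5.0, 5.0],
         [2.0, 2.2, 1.0, 1.2, 0.5, 0.4, 0.1, 0.2]],
        index=["GA", "GB", "GC"], columns=cols)
    return DoseResponseSet("microarray", vals, doses, "log2_intensity")


@pytest.fixture(scope="session")
def default_cfg() -> RunConfig:
    return RunConfig()
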