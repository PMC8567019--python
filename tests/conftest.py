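import numpy as np
import pandas as pd
import pytest

from methcd8 import (
    AnalysisConfig,
    CohortDesign,
    MethylationMatrix,
    generate_cohort,
    generate_manifest,
)


@pytest.fixture(scope="session")
def small_design():
    return CohortDesign(n_probes=1500, seed=11)


@pytest.fixture(scope="session")
def small_manifest(small_design):
    return generate_manifest(small_design)


@pytest.fixture(scope="session")
def small_cohort(small_design, small_manifest):
    """Default-condition synthetic cohort (9 HC / 10 Pso / 7 PsA)."""
    return generate_cohort(small_design, small_manifest)


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


def random_matrix(n_probes=50, n_samples=10, seed=0, prefix="s"):
    """Plain uniform beta matrix for unit tests."""
    rng = np.random.default_rng(seed)
    beta = pd.DataFrame(
        rng.uniform(0.02, 0.98, size=(n_probes, n_samples)),
        index=[f"cg{i:05d}" for i in range(n_probes)],
        columns=[f"{prefix}{j}" for j in range(n_samples)],
    )
    return MethylationMatrix(beta)
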