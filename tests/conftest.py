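import numpy as np
import pandas as pd
import pytest

from methmix import BetaMatrix, CovariateTable, SimulationConfig, simulate_mixture


def make_beta(values, prefix_c="cg", prefix_s="S"):
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    return BetaMatrix(values, [f"{prefix_c}{j}" for j in range(m)],
                      [f"{prefix_s}{i}" for i in range(n)])


def anchored_instance(seed, m=300, K=3, n=60, alpha=0.3, n_anchor_per_type=20):
    """Noiseless separable Y = M Omega' with pure anchor CpGs and
    sparse-Dirichlet proportions (rows sum to one, draws approach the
    simplex vertices, which pins down the exact factorization)."""
    rng = np.random.default_rng(seed)
    M = rng.uniform(0, 1, (m, K))
    for j in range(n_anchor_per_type * K):
        k = j % K
        M[j] = 0.0
        M[j, k] = 1.0
    W = rng.dirichlet([alpha] * K, size=n)
    return make_beta(M @ W.T), M, W


@pytest.fixture(scope="session")
def small_truth():
    """One modest simulated mixture reused across tests."""
    return simulate_mixture(SimulationConfig(m=500, n=40, seed=11))


@pytest.fixture(scope="session")
def mediated_truth():
    """Mixture whose binary covariate acts only through cell composition."""
    return simulate_mixture(SimulationConfig(covariate_effect=1.5, seed=0))


def covariate_table(truth, extra=None):
    df = pd.DataFrame(index=truth.Y.specimen_ids)
    if truth.covariate is not None:
        df["group"] = truth.covariate.astype(float)
    if extra:
        for k, v in extra.items():
            df[k] = v
    return CovariateTable(df)
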