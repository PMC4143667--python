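import numpy as np
import pytest

from bivarlmm import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Default 141-subject, 3-exam cohort with one causal SNP."""
    return simulate_cohort(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def small_cohort():
    """Small cohort (40 subjects) for fast model fits."""
    return simulate_cohort(SimulationConfig(n_subjects=40, seed=7))


@pytest.fixture(scope="session")
def tiny_cohort():
    """8-subject cohort for oracle comparisons on dense matrices."""
    return simulate_cohort(SimulationConfig(n_subjects=8, seed=3))


def dense_reml_loglik(design, vc):
    """Independent dense-formula REML oracle.

    Assembles the full block-diagonal V and evaluates
    -1/2 [ (N-p) log 2pi + log|V| + log|X'V^-1 X| + y'Py ]
    with P = V^-1 - V^-1 X (X'V^-1X)^-1 X'V^-1, entirely via dense numpy
    calls (a separate code path from the batched engine).
    """
    import scipy.linalg

    from bivarlmm.reml import marginal_covariance

    blocks, Xs, ys = [], [], []
    for g in design.groups:
        for b in range(g.n_subjects):
            blocks.append(
                marginal_covariance(vc, g.Z[b], g.time[b], g.trait[b], g.visit[b])
            )
            Xs.append(g.X[b])
            ys.append(g.Y[b])
    V = scipy.linalg.block_diag(*blocks)
    X = np.vstack(Xs)
    y = np.concatenate(ys)
    n, p = X.shape
    Vinv = np.linalg.inv(V)
    A = X.T @ Vinv @ X
    P = Vinv - Vinv @ X @ np.linalg.inv(A) @ X.T @ Vinv
    _, ld_v = np.linalg.slogdet(V)
    _, ld_a = np.linalg.slogdet(A)
    return -0.5 * (ld_v + ld_a + y @ P @ y + (n - p) * np.log(2 * np.pi))
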