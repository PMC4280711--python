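import numpy as np
import pytest

from savrex import SimulationConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-gene cohort at default design scale, shared across tests."""
    cfg = SimulationConfig(n_genes=300, seed=7)
    matrix, samples, truth = generate_cohort(cfg)
    return cfg, matrix, samples, truth


def brute_force_bh(p):
    """O(m^2) step-up definition: q_i = min_{p_(j) >= p_i} m p_(j) / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranks = np.empty(m, dtype=int)
    ranks[order] = np.arange(1, m + 1)
    vals = m * p / ranks
    cand = np.where(p[None, :] >= p[:, None], vals[None, :], np.inf)
    return np.minimum(cand.min(axis=1), 1.0)


def textbook_pearson(x, y):
    """Pearson r from the defining sums, independent of scipy."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))
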