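import numpy as np
import pandas as pd
import pytest

from mirmaster import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort with planted structure, cheap enough for unit tests."""
    cfg = SimulationConfig(
        n_samples=100, n_squamous=25, n_mirnas=12, n_genes=300,
        targets_per_master=20, n_signature_genes=20, seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """The full-scale default cohort (149 samples / 31 squamous, seed 1)."""
    return generate_cohort(SimulationConfig(seed=1))


def rank_rows(mat: np.ndarray) -> np.ndarray:
    """Average ranks along rows (helper for vectorized Spearman)."""
    from scipy.stats import rankdata

    return rankdata(mat, axis=1)


def spearman_pairs(a: pd.DataFrame, b: pd.DataFrame, pairs) -> np.ndarray:
    """Spearman rho for a list of (row-of-a, row-of-b) pairs, vectorized."""
    ra = rank_rows(a.to_numpy(float))
    rb = rank_rows(b.to_numpy(float))
    ia = {k: i for i, k in enumerate(a.index)}
    ib = {k: i for i, k in enumerate(b.index)}
    out = np.empty(len(pairs))
    for k, (x, y) in enumerate(pairs):
        u = ra[ia[x]] - ra[ia[x]].mean()
        v = rb[ib[y]] - rb[ib[y]].mean()
        out[k] = (u @ v) / np.sqrt((u @ u) * (v @ v))
    return out
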