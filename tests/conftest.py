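import numpy as np
import pytest

from connalign import (
    CohortSpec,
    Connectome,
    SubjectData,
    generate_cohort,
    grid_adjacency,
)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Noiseless 6-region cohort (two path-graph hemispheres), 3 subjects."""
    spec = CohortSpec(
        n_subjects=3, grid_rows=1, grid_cols=3,
        sc_noise_sd=0.0, fc_noise_sd=0.0, n_planted_swaps=1, seed=7,
    )
    subjects, adjacency, planted = generate_cohort(spec)
    return spec, subjects, adjacency, planted


@pytest.fixture(scope="session")
def small_cohort():
    """Noisy 20-region cohort (two 2x5 grid hemispheres), 4 subjects."""
    spec = CohortSpec(
        n_subjects=4, grid_rows=2, grid_cols=5,
        sc_noise_sd=0.05, fc_noise_sd=0.05, n_planted_swaps=3, seed=3,
    )
    subjects, adjacency, planted = generate_cohort(spec)
    return spec, subjects, adjacency, planted


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_symmetric(n, rng, scale=1.0):
    """Random symmetric non-negative matrix with zero diagonal."""
    m = rng.uniform(0, scale, size=(n, n))
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 0.0)
    return m


def random_correlation(n, rng, n_factors=None, idio=0.5):
    """Random factor-model correlation matrix (PSD by construction)."""
    k = n_factors or max(2, n // 2)
    loadings = rng.standard_normal((n, k))
    cov = loadings @ loadings.T + idio * np.eye(n)
    d = np.sqrt(np.diag(cov))
    c = cov / np.outer(d, d)
    c = (c + c.T) / 2.0
    np.fill_diagonal(c, 1.0)
    return c


@pytest.fixture
def subject_pair(rng):
    """Two random 6-region subjects sharing structure plus noise."""
    def build(seed_offset=0):
        local = np.random.default_rng(100 + seed_offset)
        sc = random_symmetric(6, local, scale=2.0)
        fc = random_correlation(6, local)
        sid = f"s{seed_offset}"
        return SubjectData(
            sc=Connectome(sc, "SC", subject_id=sid),
            fc=[Connectome(fc, "FC", subject_id=sid)],
            subject_id=sid,
        )

    return build(0), build(1)
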