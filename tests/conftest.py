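import numpy as np
import pytest

from mindsubtypes import mindnet, synthcohort


@pytest.fixture(scope="session")
def planted_cohort():
    """Desk-scale cohort with strong planted subtype effects."""
    cfg = synthcohort.CohortConfig(
        n_hc=30, n_sub1=15, n_sub2=15, n_regions=40, n_vertices=120,
        effect_sub1=0.8, effect_sub2=0.8, seed=7)
    return synthcohort.generate_cohort(cfg)


@pytest.fixture(scope="session")
def planted_strengths(planted_cohort):
    """Regional MIND strengths (Gaussian estimator) for the planted cohort."""
    return np.array([
        mindnet.regional_strength(mindnet.mind_matrix(planted_cohort.features[i]))
        for i in range(planted_cohort.n_subjects)])


def exact_moment_cloud(n: int, mean, cov, seed: int = 0) -> np.ndarray:
    """Gaussian-like sample whose sample mean and covariance (ddof=1) are exact."""
    rng = np.random.default_rng(seed)
    d = len(mean)
    z = rng.standard_normal((n, d))
    z -= z.mean(axis=0)
    c = np.cov(z.T, bias=False)
    z = z @ np.linalg.inv(np.linalg.cholesky(c)).T
    return np.asarray(mean) + z @ np.linalg.cholesky(np.asarray(cov)).T
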