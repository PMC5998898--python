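import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_bundle():
    """A reusable synthetic 5-basin bundle with moderately informative features."""
    from ramamix import synthetic
    return synthetic.generate_protein_set(40, (40, 80), noise=0.5, seed=11)


@pytest.fixture(scope="session")
def fitted_clusters(small_bundle):
    from ramamix import clustering
    import numpy as np
    phi = np.concatenate([p.phi[p.pair_mask()] for p in small_bundle])
    psi = np.concatenate([p.psi[p.pair_mask()] for p in small_bundle])
    return clustering.fit(phi, psi, K=5, seed=0)
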