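import pytest

from plastdrift.census import census_matrix
from plastdrift.simulate import default_scenario, simulate_bundle

BUNDLE_SEED = 11


@pytest.fixture(scope="session")
def bundle():
    """One synthetic study bundle shared across tests (seed fixed)."""
    cfg = default_scenario(seed=BUNDLE_SEED, marker=(9, 3, 30))
    reference, genomes, manifest = simulate_bundle(cfg)
    return reference, genomes, manifest


@pytest.fixture(scope="session")
def bundle_census(bundle):
    reference, genomes, _ = bundle
    return census_matrix(list(genomes.values()), reference)
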