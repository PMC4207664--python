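import numpy as np
import pytest

import vcqtl as v


@pytest.fixture(scope="session")
def full_map():
    """The default 164-marker, 7-linkage-group map."""
    return v.default_map()


@pytest.fixture(scope="session")
def ril_panel(full_map):
    """One simulated RIL panel with threshold-model phenotypes.

    Returns (genotypes, standardized phenotypes, model, focal marker).
    Session-scoped: read-only in tests.
    """
    focal = v.default_focal_marker(full_map)
    model = v.default_model(full_map, focal)
    geno = v.simulate_ril_genotypes(v.RILDesign(full_map), seed=20260101)
    phen = v.simulate_threshold_phenotypes(geno, model, focal, seed=20260102)
    return geno, v.standardize(phen), model, focal


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
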