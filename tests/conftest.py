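import numpy as np
import pytest

import niptscreen as ns
from niptscreen.pipeline import build_panels
from niptscreen.synthetic_cohort import CohortConfig, GenomeBaseline

DEPTH = 8_000_000


@pytest.fixture(scope="session")
def cmap():
    return ns.ChromosomeMap.grch37()


@pytest.fixture(scope="session")
def baseline(cmap):
    return GenomeBaseline.from_map(cmap)


@pytest.fixture(scope="session")
def config():
    return CohortConfig()


@pytest.fixture(scope="session")
def panels(config, baseline):
    """Sex-stratified chromosome-level panels, 100 euploid pregnancies each."""
    rng = np.random.default_rng(20_210)
    return build_panels(config, baseline, rng, n_ref=100, depth=DEPTH)


@pytest.fixture(scope="session")
def bin_panels(config, baseline):
    """Panels carrying bin-resolution moments, for CNV-scan tests."""
    rng = np.random.default_rng(20_211)
    return build_panels(config, baseline, rng, n_ref=100, depth=DEPTH, bins=True)
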