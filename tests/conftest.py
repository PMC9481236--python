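import pytest

from crsexome.config import CohortConfig, RunConfig
from crsexome.cohort import generate_cohort
from crsexome.workflow import analyze_cohort


@pytest.fixture(scope="session")
def default_config() -> RunConfig:
    cfg = RunConfig()
    cfg.cohort.seed = 1
    return cfg


@pytest.fixture(scope="session")
def bundle(default_config):
    """The default synthetic cohort (seed 1), generated once per session."""
    return generate_cohort(default_config.cohort)


@pytest.fixture(scope="session")
def analysis(default_config, bundle):
    """Full pipeline result on the default cohort."""
    return analyze_cohort(default_config, bundle=bundle)


@pytest.fixture(scope="session")
def small_cohort_config() -> CohortConfig:
    """A light cohort for I/O-heavy tests: few decoys, full patient set."""
    return CohortConfig(decoy_variants_per_proband=4, seed=7)
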