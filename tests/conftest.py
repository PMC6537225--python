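import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("ci")

import ttrscreen as t


@pytest.fixture(scope="session")
def catalog():
    """The bundled 15-variant TTR catalogue at default settings."""
    return t.default_catalog()


@pytest.fixture(scope="session")
def table1():
    """The 42-sample reference cohort fixture."""
    return t.load_table1()


@pytest.fixture(scope="session")
def simulated_cohort(table1):
    """The 42-genotype cohort simulated at default config, master seed 1."""
    return t.generate_cohort(t.SimulationConfig(), t.table1_genotypes(), seed=1)


@pytest.fixture(scope="session")
def cohort_screen_results(simulated_cohort, catalog):
    """Screen results for every simulated cohort spectrum."""
    return [t.screen_spectrum(spec, catalog) for spec, _ in simulated_cohort]
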