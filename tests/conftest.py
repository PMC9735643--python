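import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_101)


@pytest.fixture(scope="session")
def default_population():
    """One default synthetic cohort shared across tests (expensive-ish)."""
    from rrspanel.synth import SyntheticPopulationConfig, simulate_population

    return simulate_population(SyntheticPopulationConfig(seed=11))


@pytest.fixture(scope="session")
def filtered_population(default_population):
    from rrspanel.filters import FilterConfig, run_filter_cascade

    gm, truth = default_population
    filtered, log = run_filter_cascade(gm, FilterConfig())
    return filtered, truth, log


def make_genotype_matrix(dosages, positions=None, contigs=None, quals=None,
                         depths=None, varieties=None):
    """Small hand-built GenotypeMatrix for unit tests."""
    from rrspanel.genotypes import GenotypeMatrix

    dosages = np.asarray(dosages, dtype=np.int8)
    n_ind, n_loci = dosages.shape
    if depths is None:
        depths = np.full_like(dosages, 30, dtype=np.int32)
    if positions is None:
        positions = np.arange(1, n_loci + 1) * 100
    if contigs is None:
        contigs = np.array(["chr1"] * n_loci, dtype=object)
    if quals is None:
        quals = np.full(n_loci, 100.0)
    return GenotypeMatrix(
        dosages=dosages,
        depths=np.asarray(depths, dtype=np.int32),
        quals=np.asarray(quals, dtype=float),
        contigs=np.asarray(contigs, dtype=object),
        positions=np.asarray(positions, dtype=np.int64),
        ref=np.array(["A"] * n_loci, dtype=object),
        alt=np.array(["G"] * n_loci, dtype=object),
        individuals=[f"ind{i}" for i in range(n_ind)],
        varieties=list(varieties) if varieties is not None else None,
    )
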