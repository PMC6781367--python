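import warnings

import pytest

import methylaging as ma

# Desk-scale study used by unit tests: small enough to simulate in ~1 s,
# large enough that every stage has material to work with.
SMALL_SCALE = dict(
    n_chrom=1,
    chrom_length=1_200_000,
    n_genes=300,
    n_cpg=20_000,
    n_islands=40,
    n_planted_dmrs=10,
    n_planted_degs=60,
    coverage_mean=8,
)


@pytest.fixture(scope="session")
def small_params() -> ma.SimulationParams:
    return ma.SimulationParams(seed=11, **SMALL_SCALE)


@pytest.fixture(scope="session")
def small_study(small_params):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ma.simulate_all(small_params)


@pytest.fixture(scope="session")
def small_degs(small_study):
    return ma.call_degs(small_study.counts)
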