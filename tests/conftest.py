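import numpy as np
import pytest

from aneuqtl import (
    GeneticEffects,
    ParentalDuplicationRates,
    PopGenParams,
    reference_scenario,
    simulate_sample,
)


@pytest.fixture(scope="session")
def ref_pop() -> PopGenParams:
    return PopGenParams(p=0.6, D1=0.08, D2=0.06)


@pytest.fixture(scope="session")
def ref_rates() -> ParentalDuplicationRates:
    return ParentalDuplicationRates(u=0.3, v=0.4)


@pytest.fixture(scope="session")
def ref_effects() -> GeneticEffects:
    return GeneticEffects(
        mu=0.0, a=0.8, d=0.5, d_prime=0.4, lam=0.5,
        I_a_lam=0.4, I_d_lam=0.5, I_dprime_lam=0.3,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """One modest simulated cohort under the benchmark scenario."""
    return simulate_sample(reference_scenario(n=400, h2=0.2, seed=20240))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
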