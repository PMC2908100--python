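"""Generative model for triploid genotype/configuration/phenotype data.

Subjects are drawn as a multinomial over the four triploid genotypes with
frequencies given by the (p, D1, D2) closure; each subject's latent
parental configuration is Bernoulli with maternal probability u (genotypes
AAA, AAa) or v (Aaa, aaa); the phenotype is the cell mean mu_kj plus
Gaussian noise whose variance is anchored by a broad-sense heritability:

    sigma2 = Vg * (1 - H2) / H2,

where Vg is the variance of the cell means over the eight (genotype,
configuration) cells.  The reference scenario used throughout the study
harness is p = 0.6, D1 = 0.08, D2 = 0.06, u = 0.3, v = 0.4 and effects
(a, d, d', lam, I_a, I_d, I_d') = (0.8, 0.5, 0.4, 0.5, 0.4, 0.5, 0.3)
with mu = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .model_core import (
    ConfigurationModel,
    GeneticEffects,
    ParentalDuplicationRates,
    configuration_weights,
    effects_to_means,
    genetic_variance,
)
from .mixture_em import PhenotypeSample
from .popgen import PopGenParams, genotype_freqs

__all__ = [
    "SimulationScenario",
    "SimulatedSample",
    "reference_scenario",
    "simulate_sample",
    "simulate_null_sample",
]


@dataclass(frozen=True)
class SimulationScenario:
    """Full description of one simulated study condition."""

    pop: PopGenParams
    rates: ParentalDuplicationRates
    effects: GeneticEffects
    h2: float
    n: int
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 < self.h2 < 1.0:
            raise ValueError(f"heritability must lie in (0, 1), got {self.h2}")
        if self.n < 1:
            raise ValueError(f"sample size must be >= 1, got {self.n}")
        genotype_freqs(self.pop)  # validates the frequency region


@dataclass(frozen=True)
class SimulatedSample:
    """A simulated cohort with its latent configuration labels."""

    sample: PhenotypeSample
    latent: np.ndarray  # per-subject configuration j in {1, 2}; 1 = maternal
    sigma2_used: float


def reference_scenario(n: int = 400, h2: float = 0.2, seed: int = 0) -> SimulationScenario:
    """The benchmark generating condition used in the simulation study."""
    return SimulationScenario(
        pop=PopGenParams(p=0.6, D1=0.08, D2=0.06),
        rates=ParentalDuplicationRates(u=0.3, v=0.4),
        effects=GeneticEffects(
            mu=0.0, a=0.8, d=0.5, d_prime=0.4, lam=0.5,
            I_a_lam=0.4, I_d_lam=0.5, I_dprime_lam=0.3,
        ),
        h2=h2,
        n=n,
        seed=seed,
    )


def _draw(
    scenario: SimulationScenario,
    means: np.ndarray,
    sigma2: float,
) -> SimulatedSample:
    rng = np.random.default_rng(scenario.seed)
    freqs = genotype_freqs(scenario.pop)
    k = rng.choice(4, size=scenario.n, p=freqs) + 1
    maternal_prob = configuration_weights(scenario.rates)[k - 1, 0]
    j = np.where(rng.random(scenario.n) < maternal_prob, 1, 2)
    mu = means[k - 1, j - 1]
    y = mu + rng.normal(0.0, np.sqrt(sigma2), size=scenario.n)
    return SimulatedSample(PhenotypeSample(k, y), latent=j, sigma2_used=sigma2)


def scenario_sigma2(scenario: SimulationScenario) -> float:
    """Residual variance implied by the scenario's heritability."""
    means = effects_to_means(scenario.effects)
    vg = genetic_variance(scenario.pop, scenario.rates, means)
    if vg <= 0.0:
        raise ValueError(
            "genetic variance is zero: heritability is undefined for a "
            "scenario with no mean differences"
        )
    return vg * (1.0 - scenario.h2) / scenario.h2


def simulate_sample(scenario: SimulationScenario) -> SimulatedSample:
    """Draw one cohort under the scenario's generating model.

    Fully reproducible from ``scenario.seed``.
    """
    means = effects_to_means(scenario.effects)
    return _draw(scenario, means, scenario_sigma2(scenario))


def simulate_null_sample(
    scenario: SimulationScenario, null: str = "no_effect"
) -> SimulatedSample:
    """Draw a cohort under a null restriction of the scenario.

    ``no_effect`` flattens all eight cell means to the overall mean (no
    genetic control at all); ``no_imprinting`` zeroes lam and the three
    imprinting interactions, so the two configurations of each genotype
    share a mean.  The residual variance stays anchored at the alternative
    scenario's value, making null and power runs directly comparable.
    """
    sigma2 = scenario_sigma2(scenario)
    if null == "no_effect":
        null_effects = GeneticEffects(mu=scenario.effects.mu)
    elif null == "no_imprinting":
        null_effects = replace(
            scenario.effects, lam=0.0, I_a_lam=0.0, I_d_lam=0.0, I_dprime_lam=0.0
        )
    else:
        raise ValueError(
            f"unknown null {null!r}; expected 'no_effect' or 'no_imprinting'"
        )
    means = effects_to_means(null_effects)
    return _draw(scenario, means, sigma2)
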