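"""Quantitative-genetic coding of triploid genotypes and parental configurations.

Each triploid genotype (AAA, AAa, Aaa, aaa) hides two parent-of-origin
configurations, depending on whether the duplicated allele came from the
mother or the father.  The eight (genotype, configuration) cells carry
genotypic values ``mu_kj`` that decompose into eight orthogonal-by-design
quantitative-genetic effects:

==============  =====================================================
``mu``          overall mean
``a``           additive effect (AAA vs aaa contrast)
``d``           dominance of the AA pair over the single a (AAa)
``d_prime``     dominance of the single A over the aa pair (Aaa)
``lam``         genomic imprinting effect (maternal minus paternal
                configuration, half-difference)
``I_a_lam``     additive x imprinting interaction
``I_d_lam``     d dominance x imprinting interaction
``I_dprime_lam``  d' dominance x imprinting interaction
==============  =====================================================

The map from effects to cell means is linear and invertible::

    mu_11 = mu + a  + lam + I_a_lam        mu_12 = mu + a  - lam - I_a_lam
    mu_21 = mu + d  + lam + I_d_lam        mu_22 = mu + d  - lam - I_d_lam
    mu_31 = mu + d' + lam + I_d'_lam       mu_32 = mu + d' - lam - I_d'_lam
    mu_41 = mu - a  + lam                  mu_42 = mu - a  - lam

(j = 1 is the maternal-duplication configuration throughout).  The aaa
half-difference identifies ``lam`` alone, which anchors the three
interaction terms.  ``means_to_effects`` is the exact inverse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .popgen import PopGenParams, genotype_freqs

__all__ = [
    "GENOTYPE_LABELS",
    "EFFECT_NAMES",
    "DESIGN_MATRIX",
    "TriploidGenotype",
    "Configuration",
    "ParentalDuplicationRates",
    "GeneticEffects",
    "ConfigurationModel",
    "configuration_weights",
    "effects_to_means",
    "means_to_effects",
    "genetic_variance",
]

GENOTYPE_LABELS = ("AAA", "AAa", "Aaa", "aaa")
EFFECT_NAMES = ("mu", "a", "d", "d_prime", "lam", "I_a_lam", "I_d_lam", "I_dprime_lam")

# Rows: cell means in order (mu_11, mu_12, mu_21, mu_22, mu_31, mu_32, mu_41,
# mu_42); columns: effects in EFFECT_NAMES order.
DESIGN_MATRIX = np.array(
    [
        [1, 1, 0, 0, 1, 1, 0, 0],
        [1, 1, 0, 0, -1, -1, 0, 0],
        [1, 0, 1, 0, 1, 0, 1, 0],
        [1, 0, 1, 0, -1, 0, -1, 0],
        [1, 0, 0, 1, 1, 0, 0, 1],
        [1, 0, 0, 1, -1, 0, 0, -1],
        [1, -1, 0, 0, 1, 0, 0, 0],
        [1, -1, 0, 0, -1, 0, 0, 0],
    ],
    dtype=float,
)

_DESIGN_INV = np.linalg.inv(DESIGN_MATRIX)


@dataclass(frozen=True)
class TriploidGenotype:
    """A triploid genotype class, indexed k = 1..4 for AAA, AAa, Aaa, aaa."""

    k: int

    def __post_init__(self) -> None:
        if self.k not in (1, 2, 3, 4):
            raise ValueError(f"genotype index k={self.k} not in {{1, 2, 3, 4}}")

    @property
    def copies_A(self) -> int:
        return 4 - self.k

    @property
    def label(self) -> str:
        return GENOTYPE_LABELS[self.k - 1]


@dataclass(frozen=True)
class Configuration:
    """Parent-of-origin configuration: j=1 maternal duplication, j=2 paternal."""

    j: int

    def __post_init__(self) -> None:
        if self.j not in (1, 2):
            raise ValueError(f"configuration index j={self.j} not in {{1, 2}}")


@dataclass(frozen=True)
class ParentalDuplicationRates:
    """Probabilities that the duplicated allele is of maternal origin.

    ``u`` applies to duplications of allele A (genotypes AAA, AAa) and
    ``v`` to duplications of allele a (genotypes Aaa, aaa).
    """

    u: float
    v: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.u <= 1.0 and 0.0 <= self.v <= 1.0):
            raise ValueError(f"duplication rates must lie in [0, 1]: {self}")


@dataclass(frozen=True)
class GeneticEffects:
    """The eight-component quantitative-genetic decomposition (trait units)."""

    mu: float = 0.0
    a: float = 0.0
    d: float = 0.0
    d_prime: float = 0.0
    lam: float = 0.0
    I_a_lam: float = 0.0
    I_d_lam: float = 0.0
    I_dprime_lam: float = 0.0

    def __post_init__(self) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"all effect components must be finite: {self}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in EFFECT_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "GeneticEffects":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (8,):
            raise ValueError(f"expected 8 effect components, got shape {arr.shape}")
        return cls(**dict(zip(EFFECT_NAMES, arr.tolist())))


@dataclass(frozen=True)
class ConfigurationModel:
    """Cell means ``mu_kj`` (4x2) and the shared residual variance ``sigma2``."""

    means: np.ndarray
    sigma2: float

    def __post_init__(self) -> None:
        means = np.asarray(self.means, dtype=float)
        if means.shape != (4, 2):
            raise ValueError(f"means must be a 4x2 table, got shape {means.shape}")
        if not np.all(np.isfinite(means)):
            raise ValueError("all configuration means must be finite")
        if not self.sigma2 > 0.0:
            raise ValueError(f"residual variance must be positive, got {self.sigma2}")
        object.__setattr__(self, "means", means)


def configuration_weights(rates: ParentalDuplicationRates) -> np.ndarray:
    """4x2 mixture weights of the maternal/paternal configurations per genotype.

    Genotypes AAA and AAa arise from a duplication of allele A, so their
    maternal weight is ``u``; Aaa and aaa arise from duplicating a, with
    maternal weight ``v``.  Each row sums to one.
    """
    u, v = rates.u, rates.v
    return np.array([[u, 1 - u], [u, 1 - u], [v, 1 - v], [v, 1 - v]], dtype=float)


def effects_to_means(effects: GeneticEffects) -> np.ndarray:
    """Apply the effect design to produce the 4x2 table of cell means."""
    return (DESIGN_MATRIX @ effects.as_array()).reshape(4, 2)


def means_to_effects(means: np.ndarray) -> GeneticEffects:
    """Invert the design: recover the eight genetic effects from cell means.

    Closed form: ``mu`` and ``a`` come from the AAA/aaa pair sums, ``d`` and
    ``d_prime`` from the heterozygote pair means, ``lam`` from the aaa
    half-difference, and each interaction from its genotype's
    half-difference after removing ``lam``.
    """
    means = np.asarray(means, dtype=float)
    if means.shape != (4, 2):
        raise ValueError(f"means must be a 4x2 table, got shape {means.shape}")
    return GeneticEffects.from_array(_DESIGN_INV @ means.ravel())


def genetic_variance(
    pop: PopGenParams,
    rates: ParentalDuplicationRates,
    means: np.ndarray,
) -> float:
    """Variance of the genotypic value over the eight (genotype, configuration)
    cells, weighted by ``w_kj = P_k * pi_kj``.

    This is the genetic variance used to anchor the residual variance at a
    target heritability: ``sigma2 = Vg * (1 - H2) / H2``.
    """
    means = np.asarray(means, dtype=float)
    weights = genotype_freqs(pop)[:, None] * configuration_weights(rates)
    mean = float(np.sum(weights * means))
    return max(float(np.sum(weights * means**2) - mean**2), 0.0)
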