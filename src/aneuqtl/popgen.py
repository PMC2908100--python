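"""Population genetics of a chromosome-duplicated (triploid) locus.

In a cancer sample in which one parental copy of a chromosomal segment has
been duplicated, every subject carries three alleles at a biallelic locus,
so the observable genotypes are AAA, AAa, Aaa and aaa.  Even when the
ancestral diploid population was at Hardy-Weinberg equilibrium (HWE), the
duplication process itself generally drives the triploid population away
from equilibrium.  This module provides

* the three-parameter genotype-frequency model ``(p, D1, D2)``, where ``p``
  is the A-allele frequency and ``D1``/``D2`` are the Hardy-Weinberg
  disequilibrium (HWD) coefficients attached to the AAA and aaa classes;
* closed-form and EM maximum-likelihood estimation of those parameters from
  the four genotype counts;
* the forward diploid-to-triploid duplication model showing how HWD arises.

The frequency closure is::

    P1 = p^3        + D1
    P2 = 3 p^2 q  - 2 D1 +   D2
    P3 = 3 p q^2  +   D1 - 2 D2
    P4 = q^3               +   D2

which is the unique extension of the AAA/aaa definitions that preserves
both the sum-to-one constraint and allele-counting consistency
``(3 P1 + 2 P2 + P3) / 3 = p``.  With three free parameters for three
multinomial degrees of freedom the model is saturated, so the EM and the
closed-form estimators share the same fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PopGenParams",
    "GenotypeCounts",
    "DiploidDuplicationModel",
    "PopGenEstimate",
    "genotype_freqs",
    "estimate_genotype_freqs",
    "estimate_popgen",
    "duplicate_population",
]

_FREQ_TOL = 1e-9


@dataclass(frozen=True)
class PopGenParams:
    """Allele frequency and HWD coefficients of a triploid locus.

    Parameters
    ----------
    p : float
        Frequency of allele A, in [0, 1].
    D1 : float
        HWD coefficient of the triple-A genotype: ``P(AAA) - p**3``.
    D2 : float
        HWD coefficient of the triple-a genotype: ``P(aaa) - q**3``.
    """

    p: float
    D1: float = 0.0
    D2: float = 0.0

    @property
    def q(self) -> float:
        return 1.0 - self.p

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"allele frequency p={self.p} outside [0, 1]")
        freqs = _freqs_from(self.p, self.D1, self.D2)
        if np.any(freqs < -_FREQ_TOL) or np.any(freqs > 1.0 + _FREQ_TOL):
            raise ValueError(
                f"(p={self.p}, D1={self.D1}, D2={self.D2}) implies genotype "
                f"frequencies {freqs.round(6).tolist()} outside [0, 1]"
            )


@dataclass(frozen=True)
class GenotypeCounts:
    """Observed subjects per triploid genotype (AAA, AAa, Aaa, aaa)."""

    n1: int
    n2: int
    n3: int
    n4: int

    @property
    def n(self) -> int:
        return self.n1 + self.n2 + self.n3 + self.n4

    def __post_init__(self) -> None:
        for nk in (self.n1, self.n2, self.n3, self.n4):
            if nk < 0 or nk != int(nk):
                raise ValueError(f"counts must be nonnegative integers, got {self}")

    def as_array(self) -> np.ndarray:
        return np.array([self.n1, self.n2, self.n3, self.n4], dtype=float)


@dataclass(frozen=True)
class DiploidDuplicationModel:
    """Per-allele duplication proportions in the diploid source population.

    ``g`` is the proportion of AA diploids whose A is duplicated (AA -> AAA)
    and, for heterozygotes, the proportion becoming AAa; ``h`` plays the
    same role for allele a (aa -> aaa, Aa -> Aaa).  When ``g + h <= 1`` the
    remaining heterozygotes stay diploid; for ``g + h > 1`` the two rates
    are read as relative duplication propensities, which still defines the
    conditional genotype distribution of the pure-triploid sample.
    """

    g: float
    h: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.g <= 1.0 and 0.0 <= self.h <= 1.0):
            raise ValueError(f"duplication proportions must lie in [0, 1]: {self}")


@dataclass(frozen=True)
class PopGenEstimate:
    """Result of :func:`estimate_popgen`."""

    params: PopGenParams
    method: str
    clipped: bool = False
    n_iter: int = 0
    converged: bool = True
    trace: tuple = field(default_factory=tuple, repr=False)


def _freqs_from(p: float, D1: float, D2: float) -> np.ndarray:
    q = 1.0 - p
    return np.array(
        [
            p**3 + D1,
            3.0 * p**2 * q - 2.0 * D1 + D2,
            3.0 * p * q**2 + D1 - 2.0 * D2,
            q**3 + D2,
        ]
    )


def genotype_freqs(pop: PopGenParams) -> np.ndarray:
    """Genotype frequencies ``(P1, P2, P3, P4)`` for AAA, AAa, Aaa, aaa.

    Always sums to one; the triploid-sample allele frequency identity
    ``(3 P1 + 2 P2 + P3) / 3 == p`` holds by construction.
    """
    freqs = _freqs_from(pop.p, pop.D1, pop.D2)
    if np.any(freqs < -_FREQ_TOL) or np.any(freqs > 1.0 + _FREQ_TOL):
        raise ValueError(f"invalid genotype frequencies {freqs.tolist()} from {pop}")
    return np.clip(freqs, 0.0, 1.0)


def estimate_genotype_freqs(counts: GenotypeCounts) -> np.ndarray:
    """Multinomial MLE of the four genotype frequencies, ``n_k / n``."""
    if counts.n == 0:
        raise ValueError("cannot estimate genotype frequencies from zero subjects")
    return counts.as_array() / counts.n


def _closed_form(counts: GenotypeCounts) -> tuple[float, float, float]:
    n = counts.n
    p_hat = (3 * counts.n1 + 2 * counts.n2 + counts.n3) / (3.0 * n)
    q_hat = 1.0 - p_hat
    D1_hat = counts.n1 / n - p_hat**3
    D2_hat = counts.n4 / n - q_hat**3
    return p_hat, D1_hat, D2_hat


def _clip_to_valid(p: float, D1: float, D2: float) -> tuple[float, float, float, bool]:
    """Project (p, D1, D2) onto the region of valid genotype frequencies."""
    p_c = float(np.clip(p, 0.0, 1.0))
    freqs = np.clip(_freqs_from(p_c, D1, D2), 0.0, 1.0)
    freqs = freqs / freqs.sum() if freqs.sum() > 0 else np.full(4, 0.25)
    q_c = 1.0 - p_c
    D1_c = float(freqs[0] - p_c**3)
    D2_c = float(freqs[3] - q_c**3)
    clipped = (
        abs(p_c - p) > _FREQ_TOL
        or abs(D1_c - D1) > _FREQ_TOL
        or abs(D2_c - D2) > _FREQ_TOL
    )
    return p_c, D1_c, D2_c, clipped


def estimate_popgen(
    counts: GenotypeCounts,
    method: str = "closed_form",
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> PopGenEstimate:
    """Maximum-likelihood estimation of ``(p, D1, D2)`` from genotype counts.

    ``closed_form`` uses allele counting, ``p_hat = (3 n1 + 2 n2 + n3)/(3n)``,
    with ``D1_hat = n1/n - p_hat**3`` and ``D2_hat = n4/n - q_hat**3``.  The
    ``em`` method iterates the allele-proportion E-step (the share of A
    alleles contributed by each genotype class) and the frequency M-step
    until the parameter vector is stable; because the model is saturated it
    reaches the closed-form solution, and the two must agree within ``tol``.
    """
    if counts.n == 0:
        raise ValueError("cannot estimate from zero subjects")
    if method == "closed_form":
        p, D1, D2 = _closed_form(counts)
        p, D1, D2, clipped = _clip_to_valid(p, D1, D2)
        return PopGenEstimate(PopGenParams(p, D1, D2), "closed_form", clipped)
    if method != "em":
        raise ValueError(f"unknown method {method!r}; expected 'closed_form' or 'em'")

    nk = counts.as_array()
    n = counts.n
    # A-allele share of each genotype's three chromosomes: 1, 2/3, 1/3, 0.
    share_A = np.array([3.0, 2.0, 1.0, 0.0]) / 3.0
    p, D1, D2 = 0.5, 0.0, 0.0
    trace = [(p, D1, D2)]
    converged = False
    for it in range(1, max_iter + 1):
        # E-step: expected number of A alleles carried by each genotype class.
        exp_A = nk * share_A
        # M-step: refresh the allele frequency and the HWD coefficients.
        p_new = exp_A.sum() / n
        D1_new = nk[0] / n - p_new**3
        D2_new = nk[3] / n - (1.0 - p_new) ** 3
        delta = max(abs(p_new - p), abs(D1_new - D1), abs(D2_new - D2))
        p, D1, D2 = p_new, D1_new, D2_new
        trace.append((p, D1, D2))
        if delta < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"popgen EM failed to converge in {max_iter} iterations; "
            f"trace tail: {trace[-3:]}"
        )
    p, D1, D2, clipped = _clip_to_valid(p, D1, D2)
    return PopGenEstimate(
        PopGenParams(p, D1, D2), "em", clipped, n_iter=it, converged=True,
        trace=tuple(trace),
    )


def duplicate_population(p: float, dup: DiploidDuplicationModel) -> np.ndarray:
    """Triploid genotype frequencies produced by duplicating an HWE diploid pool.

    Of the diploids, AA becomes AAA with probability ``g``, aa becomes aaa
    with probability ``h``, and Aa becomes AAa (probability ``g``) or Aaa
    (probability ``h``).  Conditioning on the duplicated (triploid) fraction
    gives the genotype distribution of a pure-triploid cancer sample.  For
    generic ``(p, g, h)`` the result carries nonzero HWD even though the
    source population was at equilibrium.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"allele frequency p={p} outside [0, 1]")
    if dup.g == 0.0 and dup.h == 0.0:
        raise ValueError("g = h = 0 produces no triploids")
    q = 1.0 - p
    raw = np.array(
        [
            dup.g * p**2,
            2.0 * p * q * dup.g,
            2.0 * p * q * dup.h,
            dup.h * q**2,
        ]
    )
    return raw / raw.sum()
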