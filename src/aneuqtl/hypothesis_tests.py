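"""Likelihood-ratio tests for the triploid-locus model.

Five test families:

* joint Hardy-Weinberg disequilibrium, H0: D1 = D2 = 0 (chi2, df = 2);
* single-coefficient HWD, H0: D1 = 0 (constraint P1 = p^3) or D2 = 0
  (constraint P4 = q^3), profiling the remaining parameters (df = 1);
* overall association, H0: all eight cell means equal (chi2 df = 7 by
  default, with a permutation calibration because the duplication rates
  are unidentified under the null);
* individual or joint genetic effects, H0: a chosen subset of
  {a, d, d', lam, I_a, I_d, I_d'} is zero (df = subset size);
* parent-specific duplication rate, H0: u (or v) equals 0.5 (no parental
  bias; interior null, chi2 df = 1) or 1.0 (boundary null; 50:50 mixture
  of a point mass at zero and chi2_1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy import optimize, stats

from .mixture_em import (
    FitConstraints,
    MixtureFit,
    PhenotypeSample,
    fit_mixture,
)
from .model_core import EFFECT_NAMES
from .popgen import GenotypeCounts, _closed_form, _freqs_from

__all__ = [
    "TestResult",
    "lrt_hwd_joint",
    "lrt_hwd_single",
    "lrt_association",
    "lrt_effects",
    "lrt_duplication",
    "TESTABLE_EFFECTS",
]

TESTABLE_EFFECTS = tuple(name for name in EFFECT_NAMES if name != "mu")

_STAT_SLACK = 1e-6


@dataclass(frozen=True)
class TestResult:
    """Outcome of one likelihood-ratio test."""

    name: str
    statistic: float
    df: int
    p_value: float
    calibration: str
    null_loglik: float
    alt_loglik: float
    details: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.statistic < -_STAT_SLACK:
            raise ValueError(
                f"negative LRT statistic {self.statistic} beyond numerical slack"
            )
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _multinomial_loglik(nk: np.ndarray, freqs: np.ndarray) -> float:
    """Multinomial kernel log-likelihood with the 0*log(0) = 0 convention."""
    mask = nk > 0
    if np.any(freqs[mask] <= 0):
        return -np.inf
    return float(np.sum(nk[mask] * np.log(freqs[mask])))


def lrt_hwd_joint(counts: GenotypeCounts) -> TestResult:
    """Test H0: D1 = D2 = 0 against the saturated genotype-frequency model."""
    if counts.n == 0:
        raise ValueError("no subjects")
    nk = counts.as_array()
    n = counts.n
    l_alt = _multinomial_loglik(nk, nk / n)
    p0, _, _ = _closed_form(counts)
    q0 = 1.0 - p0
    hwe = np.array([p0**3, 3 * p0**2 * q0, 3 * p0 * q0**2, q0**3])
    l_null = _multinomial_loglik(nk, hwe)
    stat = max(2.0 * (l_alt - l_null), 0.0)
    return TestResult(
        name="hwd_joint",
        statistic=stat,
        df=2,
        p_value=float(stats.chi2.sf(stat, 2)),
        calibration="chi2",
        null_loglik=l_null,
        alt_loglik=l_alt,
        details={"p_null": p0},
    )


def _profile_single_null(counts: GenotypeCounts, which: str) -> tuple[float, dict]:
    """Maximise the multinomial likelihood with D1 = 0 (or D2 = 0)."""
    nk = counts.as_array()
    p0, D1_0, D2_0 = _closed_form(counts)

    def neg_loglik(theta: np.ndarray) -> float:
        p, d = theta
        if not 1e-9 < p < 1 - 1e-9:
            return 1e12
        if which == "D1":
            freqs = _freqs_from(p, 0.0, d)
        else:
            freqs = _freqs_from(p, d, 0.0)
        if np.any(freqs <= 0) or np.any(freqs >= 1):
            return 1e12
        return -_multinomial_loglik(nk, freqs)

    free0 = D2_0 if which == "D1" else D1_0
    best = None
    for x0 in ((p0, free0), (p0, 0.0), (0.5, 0.0)):
        res = optimize.minimize(
            neg_loglik, x0=np.array(x0), method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    if not np.isfinite(best.fun) or best.fun >= 1e11:
        raise RuntimeError(f"null-profile optimisation failed: {best}")
    info = {"p_null": float(best.x[0]), "free_coeff": float(best.x[1])}
    return -float(best.fun), info


def lrt_hwd_single(counts: GenotypeCounts, which: str) -> TestResult:
    """Test a single HWD coefficient: H0 fixes P1 = p^3 (D1) or P4 = q^3 (D2)."""
    if which not in ("D1", "D2"):
        raise ValueError(f"which must be 'D1' or 'D2', got {which!r}")
    if counts.n == 0:
        raise ValueError("no subjects")
    nk = counts.as_array()
    l_alt = _multinomial_loglik(nk, nk / counts.n)
    l_null, info = _profile_single_null(counts, which)
    stat = max(2.0 * (l_alt - l_null), 0.0)
    return TestResult(
        name=f"hwd_{which}",
        statistic=stat,
        df=1,
        p_value=float(stats.chi2.sf(stat, 1)),
        calibration="chi2",
        null_loglik=l_null,
        alt_loglik=l_alt,
        details=info,
    )


_NO_EFFECT = FitConstraints(fixed_effects={name: 0.0 for name in TESTABLE_EFFECTS})


def _fit_pair(
    sample: PhenotypeSample,
    null_constraints: FitConstraints,
    seed: int | None,
    fit_kwargs: dict,
    alt_fit: MixtureFit | None,
) -> tuple[MixtureFit, MixtureFit, float]:
    if alt_fit is None:
        alt_fit = fit_mixture(sample, seed=seed, **fit_kwargs)
    # Seed the null fit with the alternative solution projected onto the
    # constraint set, in addition to its own starts: keeps the null optimum
    # from lagging the alternative's basin.
    null_fit = fit_mixture(
        sample,
        constraints=null_constraints,
        seed=seed,
        initial=(alt_fit.rates, alt_fit.config_model),
        **fit_kwargs,
    )
    stat = 2.0 * (alt_fit.loglik - null_fit.loglik)
    if stat < -_STAT_SLACK:
        # Alternative stuck in a worse optimum than the null: restart the
        # alternative from the null solution (always feasible).
        alt_fit = fit_mixture(
            sample, seed=seed,
            initial=(null_fit.rates, null_fit.config_model),
            **fit_kwargs,
        )
        stat = 2.0 * (alt_fit.loglik - null_fit.loglik)
    return alt_fit, null_fit, max(stat, 0.0)


def _fit_summary(fit: MixtureFit) -> dict:
    return {
        "u": fit.rates.u,
        "v": fit.rates.v,
        "sigma2": fit.config_model.sigma2,
        "effects": dict(zip(EFFECT_NAMES, fit.effects.as_array().tolist())),
        "loglik": fit.loglik,
        "converged": fit.converged,
    }


def lrt_association(
    sample: PhenotypeSample,
    calibration: str = "chi2",
    n_perm: int = 500,
    seed: int | None = 0,
    alt_fit: MixtureFit | None = None,
    **fit_kwargs,
) -> TestResult:
    """Overall association test: H0 is a single phenotype mean for all cells.

    Under the null the duplication rates drop out of the likelihood, so the
    chi2 reference with df = 7 (eight means collapsing to one) is not exact;
    ``calibration='permutation'`` re-computes the statistic on phenotype
    shuffles for an honest finite-sample reference.
    """
    alt_fit, null_fit, stat = _fit_pair(sample, _NO_EFFECT, seed, fit_kwargs, alt_fit)
    details = {"alt": _fit_summary(alt_fit), "null": _fit_summary(null_fit)}
    if calibration == "chi2":
        p_value = float(stats.chi2.sf(stat, 7))
    elif calibration == "permutation":
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_perm):
            perm = PhenotypeSample(sample.genotype_k, rng.permutation(sample.y))
            _, _, stat_p = _fit_pair(perm, _NO_EFFECT, seed, fit_kwargs, None)
            exceed += stat_p >= stat
        p_value = (1.0 + exceed) / (1.0 + n_perm)
        details["n_perm"] = n_perm
    else:
        raise ValueError(f"unknown calibration {calibration!r}")
    return TestResult(
        name="association",
        statistic=stat,
        df=7,
        p_value=p_value,
        calibration=calibration,
        null_loglik=null_fit.loglik,
        alt_loglik=alt_fit.loglik,
        details=details,
    )


def lrt_effects(
    sample: PhenotypeSample,
    which: Iterable[str],
    seed: int | None = 0,
    alt_fit: MixtureFit | None = None,
    **fit_kwargs,
) -> TestResult:
    """Test that the named genetic effects are zero, jointly.

    ``which`` is a nonempty subset of {a, d, d_prime, lam, I_a_lam,
    I_d_lam, I_dprime_lam}; the null fit pins those coordinates to zero in
    the constrained M-step.  The statistic is referred to chi2 with
    df = len(which).
    """
    which = tuple(which)
    if not which:
        raise ValueError("'which' must name at least one effect")
    for name in which:
        if name not in TESTABLE_EFFECTS:
            raise ValueError(
                f"cannot test {name!r}; choose from {TESTABLE_EFFECTS}"
            )
    constraints = FitConstraints(fixed_effects={name: 0.0 for name in which})
    alt_fit, null_fit, stat = _fit_pair(sample, constraints, seed, fit_kwargs, alt_fit)
    df = len(which)
    return TestResult(
        name="effects_" + "+".join(which),
        statistic=stat,
        df=df,
        p_value=float(stats.chi2.sf(stat, df)),
        calibration="chi2",
        null_loglik=null_fit.loglik,
        alt_loglik=alt_fit.loglik,
        details={"alt": _fit_summary(alt_fit), "null": _fit_summary(null_fit)},
    )


def lrt_duplication(
    sample: PhenotypeSample,
    which: str,
    null_value: float = 0.5,
    seed: int | None = 0,
    alt_fit: MixtureFit | None = None,
    **fit_kwargs,
) -> TestResult:
    """Test a parent-specific duplication rate against a fixed null value.

    ``null_value=0.5`` tests for absence of parental bias (interior null,
    chi2 df = 1).  ``null_value=1.0`` (or 0.0) is a boundary null: the
    statistic is referred to the 50:50 mixture of a point mass at zero and
    chi2 with 1 df.
    """
    if which not in ("u", "v"):
        raise ValueError(f"which must be 'u' or 'v', got {which!r}")
    constraints = (
        FitConstraints(fixed_u=null_value)
        if which == "u"
        else FitConstraints(fixed_v=null_value)
    )
    alt_fit, null_fit, stat = _fit_pair(sample, constraints, seed, fit_kwargs, alt_fit)
    boundary = null_value in (0.0, 1.0)
    if boundary:
        p_value = 0.5 * float(stats.chi2.sf(stat, 1)) if stat > 0 else 1.0
        calibration = "chi2_boundary_mixture"
    else:
        p_value = float(stats.chi2.sf(stat, 1))
        calibration = "chi2"
    return TestResult(
        name=f"duplication_{which}={null_value}",
        statistic=stat,
        df=1,
        p_value=p_value,
        calibration=calibration,
        null_loglik=null_fit.loglik,
        alt_loglik=alt_fit.loglik,
        details={"alt": _fit_summary(alt_fit), "null": _fit_summary(null_fit)},
    )
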