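"""Finite normal-mixture likelihood for parent-of-origin effects, and its EM.

Each subject's triploid genotype k is observed, but not the parental
configuration j behind it, so the phenotype density within genotype k is a
two-component normal mixture with means ``mu_k1, mu_k2``, a shared variance
``sigma2`` and weights tied across genotypes through the parental
duplication rates: ``(u, 1-u)`` for AAA and AAa, ``(v, 1-v)`` for Aaa and
aaa.  The log-likelihood is

    sum_i log[ pi_{k(i)1} phi(y_i; mu_{k(i)1}, s2) + pi_{k(i)2} phi(y_i; mu_{k(i)2}, s2) ]

and is maximised by EM: the E-step computes each subject's posterior
configuration probabilities, the M-step refreshes (u, v), the cell means
and sigma2 by posterior-weighted averages.  Constrained fits (for
likelihood-ratio nulls) replace the per-cell mean update with a
posterior-weighted least-squares solve in effect space where the
constrained effects are pinned to their null values; the duplication rates
can likewise be held fixed.

Identifiability note: the likelihood is invariant under the simultaneous
relabelling (u, v, mu_k1, mu_k2) -> (1-u, 1-v, mu_k2, mu_k1), which flips
the sign of the imprinting effect and its interactions but leaves mu, a, d,
d' and every likelihood ratio unchanged.  The default initialisation
assigns the maternal component the larger starting mean in every stratum,
which selects the lam >= 0 basin whenever the data prefer one; at u ~ v ~
0.5 the residual ambiguity is flagged with a warning rather than resolved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .model_core import (
    DESIGN_MATRIX,
    EFFECT_NAMES,
    ConfigurationModel,
    GeneticEffects,
    ParentalDuplicationRates,
    configuration_weights,
    means_to_effects,
)
from .popgen import GenotypeCounts

__all__ = [
    "PhenotypeSample",
    "FitConstraints",
    "MixtureFit",
    "loglik",
    "e_step",
    "m_step",
    "fit_mixture",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class PhenotypeSample:
    """Aligned per-subject genotype classes (k = 1..4) and phenotype values."""

    genotype_k: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        k = np.asarray(self.genotype_k, dtype=int)
        y = np.asarray(self.y, dtype=float)
        if k.ndim != 1 or y.ndim != 1 or k.shape != y.shape:
            raise ValueError("genotype_k and y must be 1-D arrays of equal length")
        if k.size < 1:
            raise ValueError("sample must contain at least one subject")
        if not np.all((k >= 1) & (k <= 4)):
            raise ValueError("genotype classes must lie in {1, 2, 3, 4}")
        if not np.all(np.isfinite(y)):
            raise ValueError("phenotype values must be finite")
        object.__setattr__(self, "genotype_k", k)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return self.y.size

    def counts(self) -> GenotypeCounts:
        c = np.bincount(self.genotype_k, minlength=5)[1:5]
        return GenotypeCounts(*c.tolist())


@dataclass(frozen=True)
class FitConstraints:
    """Linear constraints for likelihood-ratio null fits.

    ``fixed_effects`` pins named effect coordinates (see
    ``model_core.EFFECT_NAMES``) to given values; ``fixed_u``/``fixed_v``
    hold a duplication rate at its null value.
    """

    fixed_effects: Mapping[str, float] = field(default_factory=dict)
    fixed_u: float | None = None
    fixed_v: float | None = None

    def __post_init__(self) -> None:
        for name in self.fixed_effects:
            if name not in EFFECT_NAMES:
                raise ValueError(
                    f"unknown effect {name!r}; expected one of {EFFECT_NAMES}"
                )
        for val, lbl in ((self.fixed_u, "u"), (self.fixed_v, "v")):
            if val is not None and not 0.0 <= val <= 1.0:
                raise ValueError(f"fixed {lbl}={val} outside [0, 1]")

    @property
    def fixed_mask(self) -> np.ndarray:
        return np.array([name in self.fixed_effects for name in EFFECT_NAMES])

    @property
    def fixed_values(self) -> np.ndarray:
        return np.array(
            [self.fixed_effects.get(name, 0.0) for name in EFFECT_NAMES]
        )

    def project(
        self, rates: ParentalDuplicationRates, model: ConfigurationModel
    ) -> tuple[ParentalDuplicationRates, ConfigurationModel]:
        """Project a parameter state onto the constraint set (effect
        coordinates overwritten, rates replaced by their fixed values)."""
        beta = means_to_effects(model.means).as_array()
        mask = self.fixed_mask
        beta[mask] = self.fixed_values[mask]
        means = (DESIGN_MATRIX @ beta).reshape(4, 2)
        u = self.fixed_u if self.fixed_u is not None else rates.u
        v = self.fixed_v if self.fixed_v is not None else rates.v
        return ParentalDuplicationRates(u, v), ConfigurationModel(means, model.sigma2)


@dataclass(frozen=True)
class MixtureFit:
    """A converged (or best-iterate) maximum-likelihood mixture fit."""

    rates: ParentalDuplicationRates
    config_model: ConfigurationModel
    effects: GeneticEffects
    loglik: float
    trace: np.ndarray
    converged: bool
    n_iter: int
    n_starts_used: int
    empty_strata: tuple[int, ...] = ()


def _log_components(
    sample: PhenotypeSample,
    rates: ParentalDuplicationRates,
    config_model: ConfigurationModel,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject log of (weight * normal density) for both configurations."""
    idx = sample.genotype_k - 1
    pi = configuration_weights(rates)[idx]  # (n, 2)
    mu = config_model.means[idx]  # (n, 2)
    s2 = config_model.sigma2
    log_phi = -0.5 * (_LOG_2PI + np.log(s2)) - (sample.y[:, None] - mu) ** 2 / (2.0 * s2)
    with np.errstate(divide="ignore"):
        log_w = np.log(pi)
    comp = log_w + log_phi
    lse = np.logaddexp(comp[:, 0], comp[:, 1])
    return comp, lse


def loglik(
    sample: PhenotypeSample,
    rates: ParentalDuplicationRates,
    config_model: ConfigurationModel,
) -> float:
    """Observed-data log-likelihood of the 4-stratum two-component mixture."""
    _, lse = _log_components(sample, rates, config_model)
    return float(lse.sum())


def e_step(
    sample: PhenotypeSample,
    rates: ParentalDuplicationRates,
    config_model: ConfigurationModel,
) -> np.ndarray:
    """Posterior probability matrix (n x 2) of the maternal/paternal
    configuration for each subject; rows sum to one.

    Computed in log space, so simultaneous underflow of both component
    densities cannot occur; if a row still fails to normalise (both
    component weights zero) the prior weights are substituted.
    """
    comp, lse = _log_components(sample, rates, config_model)
    with np.errstate(invalid="ignore"):
        omega = np.exp(comp - lse[:, None])
    bad = ~np.isfinite(omega).all(axis=1)
    if np.any(bad):
        idx = sample.genotype_k[bad] - 1
        omega[bad] = configuration_weights(rates)[idx]
        warnings.warn(
            f"{int(bad.sum())} subjects had vanishing component mass; "
            "prior configuration weights substituted",
            RuntimeWarning,
            stacklevel=2,
        )
    return omega


def _solve_constrained_means(
    W: np.ndarray,
    S: np.ndarray,
    old_means: np.ndarray,
    constraints: FitConstraints | None,
) -> np.ndarray:
    """M-step mean update: per-cell weighted averages, or the posterior-
    weighted least-squares solution in effect space under constraints."""
    if constraints is None or not constraints.fixed_effects:
        with np.errstate(invalid="ignore", divide="ignore"):
            means = S / W
        return np.where(W > 1e-12, means, old_means)
    fixed = constraints.fixed_mask
    free = ~fixed
    beta_fixed = constraints.fixed_values
    w = W.ravel()
    s = S.ravel()
    offset = DESIGN_MATRIX[:, fixed] @ beta_fixed[fixed]
    sw = np.sqrt(w)
    A = sw[:, None] * DESIGN_MATRIX[:, free]
    with np.errstate(invalid="ignore", divide="ignore"):
        target = np.where(w > 1e-12, s / np.maximum(w, 1e-300), offset)
    b = sw * (target - offset)
    beta_free, *_ = np.linalg.lstsq(A, b, rcond=None)
    beta = beta_fixed.copy()
    beta[free] = beta_free
    return (DESIGN_MATRIX @ beta).reshape(4, 2)


def m_step(
    sample: PhenotypeSample,
    posterior: np.ndarray,
    constraints: FitConstraints | None = None,
    old_model: ConfigurationModel | None = None,
    sigma2_floor: float = 0.0,
) -> tuple[ParentalDuplicationRates, ConfigurationModel]:
    """Posterior-weighted parameter update.

    ``u`` is the mean maternal posterior over the AAA/AAa strata, ``v`` over
    Aaa/aaa; cell means are posterior-weighted phenotype averages (or the
    constrained effect-space least-squares solution); ``sigma2`` pools the
    weighted squared residuals over all subjects and both configurations.
    """
    omega = np.asarray(posterior, dtype=float)
    if omega.shape != (sample.n, 2):
        raise ValueError(f"posterior must be (n, 2); got {omega.shape}")
    k = sample.genotype_k
    idx = k - 1
    in_A = k <= 2
    nA, na = int(in_A.sum()), int((~in_A).sum())

    if constraints is not None and constraints.fixed_u is not None:
        u = constraints.fixed_u
    else:
        u = float(omega[in_A, 0].sum() / nA) if nA else 0.5
    if constraints is not None and constraints.fixed_v is not None:
        v = constraints.fixed_v
    else:
        v = float(omega[~in_A, 0].sum() / na) if na else 0.5

    W = np.empty((4, 2))
    S = np.empty((4, 2))
    for j in (0, 1):
        W[:, j] = np.bincount(idx, weights=omega[:, j], minlength=4)
        S[:, j] = np.bincount(idx, weights=omega[:, j] * sample.y, minlength=4)
    old_means = old_model.means if old_model is not None else np.zeros((4, 2))
    means = _solve_constrained_means(W, S, old_means, constraints)

    resid2 = (sample.y[:, None] - means[idx]) ** 2
    sigma2 = float((omega * resid2).sum() / sample.n)
    sigma2 = max(sigma2, sigma2_floor)
    if sigma2 <= 0.0:
        raise ValueError("degenerate zero residual variance (constant phenotypes?)")
    return ParentalDuplicationRates(u, v), ConfigurationModel(means, sigma2)


class _EMKernel:
    """Vectorised EM sweeps for one sample, reusing precomputed index state.

    Produces updates identical to ``e_step`` followed by ``m_step``; exists
    so the multi-start fit does not rebuild index arrays every iteration.
    """

    def __init__(
        self,
        sample: PhenotypeSample,
        constraints: FitConstraints | None,
        sigma2_floor: float,
    ) -> None:
        self.y = sample.y
        self.n = sample.n
        self.idx = sample.genotype_k - 1
        self.mask_u = self.idx <= 1
        self.n_u = int(self.mask_u.sum())
        self.n_v = self.n - self.n_u
        self.counts_k = np.bincount(self.idx, minlength=4).astype(float)
        self.sum_y_k = np.bincount(self.idx, weights=self.y, minlength=4)
        self.constraints = constraints
        self.sigma2_floor = sigma2_floor
        c = constraints
        self.upd_u = not (c is not None and c.fixed_u is not None)
        self.upd_v = not (c is not None and c.fixed_v is not None)

    def run(
        self,
        u: float,
        v: float,
        means: np.ndarray,
        sigma2: float,
        tol: float,
        max_iter: int,
    ) -> tuple[float, float, np.ndarray, float, list[float], bool]:
        y, idx = self.y, self.idx
        trace: list[float] = []
        ll_prev = -np.inf
        converged = False
        for _ in range(max_iter):
            # E-step in log space.
            with np.errstate(divide="ignore"):
                lw_u1, lw_u2 = np.log(u), np.log1p(-u) if u < 1 else -np.inf
                lw_v1, lw_v2 = np.log(v), np.log1p(-v) if v < 1 else -np.inf
            inv2 = 0.5 / sigma2
            d1 = y - means[idx, 0]
            d2 = y - means[idx, 1]
            a1 = np.where(self.mask_u, lw_u1, lw_v1) - d1 * d1 * inv2
            a2 = np.where(self.mask_u, lw_u2, lw_v2) - d2 * d2 * inv2
            hi = np.maximum(a1, a2)
            e1 = np.exp(a1 - hi)
            e2 = np.exp(a2 - hi)
            denom = e1 + e2
            ll = float((hi + np.log(denom)).sum()) - self.n * 0.5 * (
                _LOG_2PI + np.log(sigma2)
            )
            trace.append(ll)
            omega1 = e1 / denom

            # M-step.
            if self.upd_u:
                u = float(omega1[self.mask_u].sum() / self.n_u) if self.n_u else 0.5
            if self.upd_v:
                v = float(omega1[~self.mask_u].sum() / self.n_v) if self.n_v else 0.5
            W1 = np.bincount(idx, weights=omega1, minlength=4)
            S1 = np.bincount(idx, weights=omega1 * y, minlength=4)
            W = np.stack([W1, self.counts_k - W1], axis=1)
            S = np.stack([S1, self.sum_y_k - S1], axis=1)
            means = _solve_constrained_means(W, S, means, self.constraints)
            d1 = y - means[idx, 0]
            d2 = y - means[idx, 1]
            sigma2 = float((omega1 * d1 * d1 + (1.0 - omega1) * d2 * d2).sum() / self.n)
            sigma2 = max(sigma2, self.sigma2_floor, 1e-300)

            if abs(ll - ll_prev) < tol * (1.0 + abs(ll)):
                converged = True
                break
            ll_prev = ll
        # Log-likelihood of the final parameter state (after the last M-step),
        # so the reported value matches the returned parameters exactly.
        with np.errstate(divide="ignore"):
            lw_u1, lw_u2 = np.log(u), np.log1p(-u) if u < 1 else -np.inf
            lw_v1, lw_v2 = np.log(v), np.log1p(-v) if v < 1 else -np.inf
        inv2 = 0.5 / sigma2
        d1 = y - means[idx, 0]
        d2 = y - means[idx, 1]
        a1 = np.where(self.mask_u, lw_u1, lw_v1) - d1 * d1 * inv2
        a2 = np.where(self.mask_u, lw_u2, lw_v2) - d2 * d2 * inv2
        ll = float(np.logaddexp(a1, a2).sum()) - self.n * 0.5 * (
            _LOG_2PI + np.log(sigma2)
        )
        trace.append(ll)
        return u, v, means, sigma2, trace, converged


def _initial_state(
    sample: PhenotypeSample,
    constraints: FitConstraints | None,
    rng: np.random.Generator | None,
) -> tuple[ParentalDuplicationRates, ConfigurationModel, tuple[int, ...]]:
    y, k = sample.y, sample.genotype_k
    overall_mean = float(y.mean())
    overall_sd = float(y.std()) or 1.0
    means = np.empty((4, 2))
    within_ss = 0.0
    empty: list[int] = []
    for g in range(4):
        yk = y[k == g + 1]
        if yk.size == 0:
            empty.append(g + 1)
            m, s = overall_mean, overall_sd
        else:
            m, s = float(yk.mean()), float(yk.std())
            within_ss += float(((yk - m) ** 2).sum())
        # Maternal component starts above the stratum mean: fixes the
        # labelling basin (see module docstring).
        means[g] = (m + 0.5 * s, m - 0.5 * s)
    if rng is not None:
        means = means + rng.normal(0.0, 0.25 * overall_sd, size=(4, 2))
    sigma2 = within_ss / sample.n if within_ss > 0 else overall_sd**2
    sigma2 = max(sigma2, 1e-8 * overall_sd**2, 1e-300)

    u0 = v0 = 0.5
    if constraints is not None:
        if constraints.fixed_u is not None:
            u0 = constraints.fixed_u
        if constraints.fixed_v is not None:
            v0 = constraints.fixed_v
        if constraints.fixed_effects:
            beta = means_to_effects(means).as_array()
            fixed = constraints.fixed_mask
            beta[fixed] = constraints.fixed_values[fixed]
            means = (DESIGN_MATRIX @ beta).reshape(4, 2)
    return (
        ParentalDuplicationRates(u0, v0),
        ConfigurationModel(means, sigma2),
        tuple(empty),
    )


def fit_mixture(
    sample: PhenotypeSample,
    constraints: FitConstraints | None = None,
    tol: float = 1e-8,
    max_iter: int = 2000,
    n_starts: int = 5,
    seed: int | None = 0,
    initial: tuple[ParentalDuplicationRates, ConfigurationModel] | None = None,
    burn_iter: int = 200,
) -> MixtureFit:
    """Maximum-likelihood fit of the configuration mixture by multi-start EM.

    The first start uses the deterministic stratum-moment initialisation
    (u = v = 0.5, means at stratum mean +/- 0.5 sd, pooled within-stratum
    sigma2); the remaining ``n_starts - 1`` jitter the starting means with a
    seeded generator to escape local optima.  An explicit ``initial`` state
    adds one further start.  Each start runs for up to ``burn_iter`` sweeps;
    the start with the best log-likelihood is then polished to full
    convergence (relative log-likelihood change below ``tol`` within
    ``max_iter`` sweeps).  Non-convergent runs return the best iterate with
    ``converged=False``.
    """
    if sample.n < 2:
        raise ValueError("need at least two subjects to fit the mixture")
    y_var = float(sample.y.var())
    if y_var <= 0.0:
        raise ValueError("phenotypes are constant; the mixture is degenerate")
    sigma2_floor = 1e-12 * y_var

    kernel = _EMKernel(sample, constraints, sigma2_floor)
    rng = np.random.default_rng(seed)
    starts: list[tuple[ParentalDuplicationRates, ConfigurationModel]] = []
    r0, m0, empty_strata = _initial_state(sample, constraints, rng=None)
    starts.append((r0, m0))
    for _ in range(max(n_starts - 1, 0)):
        r_j, m_j, _ = _initial_state(sample, constraints, rng=rng)
        starts.append((r_j, m_j))
    if initial is not None:
        if constraints is not None:
            initial = constraints.project(*initial)
        starts.append(initial)

    best_state = None
    best_ll = -np.inf
    burn = min(burn_iter, max_iter) if len(starts) > 1 else max_iter
    for rates0, model0 in starts:
        state = kernel.run(
            rates0.u, rates0.v, model0.means.copy(), model0.sigma2, tol, burn
        )
        if state[4][-1] > best_ll:
            best_ll = state[4][-1]
            best_state = state
    assert best_state is not None
    u, v, means, sigma2, trace, converged = best_state
    it = len(trace)
    if not converged and it < max_iter:
        u, v, means, sigma2, trace2, converged = kernel.run(
            u, v, means, sigma2, tol, max_iter - it
        )
        trace = trace + trace2
        it = len(trace)

    fit = MixtureFit(
        rates=ParentalDuplicationRates(u, v),
        config_model=ConfigurationModel(means, sigma2),
        effects=means_to_effects(means),
        loglik=trace[-1],
        trace=np.asarray(trace),
        converged=converged,
        n_iter=it,
        n_starts_used=len(starts),
        empty_strata=empty_strata,
    )
    if not fit.converged:
        warnings.warn(
            f"EM did not converge in {max_iter} iterations; best iterate returned",
            RuntimeWarning,
            stacklevel=2,
        )
    if abs(fit.rates.u - 0.5) < 0.02 and abs(fit.rates.v - 0.5) < 0.02:
        imprint = abs(fit.effects.lam) + abs(fit.effects.I_a_lam)
        if imprint > 1e-8:
            warnings.warn(
                "u and v are both near 0.5: the sign of the imprinting effect "
                "and its interactions is only weakly identified",
                RuntimeWarning,
                stacklevel=2,
            )
    return fit
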