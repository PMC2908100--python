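"""Monte-Carlo experiments: parameter recovery, power and false-positive rates.

Runs a grid of (sample size, heritability) cells under a common generating
scenario, replicating each cell with independently seeded datasets, and
tabulates per-cell means, standard deviations and standard errors of every
estimated parameter, or per-cell rejection rates of a chosen test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .hypothesis_tests import lrt_association, lrt_effects
from .mixture_em import fit_mixture
from .model_core import EFFECT_NAMES
from .popgen import estimate_popgen
from .simulator import (
    SimulationScenario,
    reference_scenario,
    simulate_null_sample,
    simulate_sample,
)

__all__ = ["StudyGrid", "StudyResult", "run_recovery_study", "run_power_study"]

PARAM_COLUMNS = ("p", "D1", "D2", "u", "v") + EFFECT_NAMES[1:]


@dataclass(frozen=True)
class StudyGrid:
    """Specification of a (sample size x heritability) Monte-Carlo grid."""

    sample_sizes: tuple[int, ...] = (400, 800, 2000)
    heritabilities: tuple[float, ...] = (0.05, 0.1, 0.2)
    n_replicates: int = 200
    alpha: float = 0.05
    master_seed: int = 0
    scenario_template: SimulationScenario = field(
        default_factory=lambda: reference_scenario()
    )

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    def scenario(self, n: int, h2: float, seed: int) -> SimulationScenario:
        return replace(self.scenario_template, n=n, h2=h2, seed=seed)


@dataclass(frozen=True)
class StudyResult:
    """Per-cell summaries plus replicate-level raw values."""

    cells: pd.DataFrame
    replicates: pd.DataFrame
    n_excluded: int = 0


def _replicate_seed(master_seed: int, cell: int, rep: int) -> int:
    ss = np.random.SeedSequence([master_seed, cell, rep])
    return int(ss.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)


def _cache_path(cache_dir: Path | None, tag: str, cell: int) -> Path | None:
    if cache_dir is None:
        return None
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    return cache_dir / f"{tag}_cell{cell}.csv"


def _run_cell(
    grid: StudyGrid,
    cell_index: int,
    one_replicate: Callable[[int, int], dict],
    cache: Path | None,
) -> pd.DataFrame:
    if cache is not None and cache.exists():
        return pd.read_csv(cache)
    rows = []
    for rep in range(grid.n_replicates):
        seed = _replicate_seed(grid.master_seed, cell_index, rep)
        row = one_replicate(rep, seed)
        if row is not None:
            rows.append(row)
    df = pd.DataFrame(rows)
    if cache is not None:
        df.to_csv(cache, index=False)
    return df


def run_recovery_study(
    grid: StudyGrid,
    cache_dir: Path | str | None = None,
    fit_kwargs: dict | None = None,
) -> StudyResult:
    """Estimate every model parameter on simulated cohorts across the grid.

    Each replicate simulates a cohort, estimates (p, D1, D2) from the
    genotype counts, fits the configuration mixture by EM and converts the
    fitted means to genetic effects.  Cells report the mean, standard
    deviation across replicates and standard error of the mean for each
    parameter.  Replicates whose fit raises are logged and excluded.
    """
    fit_kwargs = fit_kwargs or {}
    all_reps = []
    n_excluded = 0
    cell_rows = []
    for cell_index, (n, h2) in enumerate(
        (n, h2) for n in grid.sample_sizes for h2 in grid.heritabilities
    ):

        def one_replicate(rep: int, seed: int) -> dict | None:
            scenario = grid.scenario(n, h2, seed)
            sim = simulate_sample(scenario)
            try:
                pg = estimate_popgen(sim.sample.counts())
                fit = fit_mixture(sim.sample, seed=seed, **fit_kwargs)
            except (ValueError, RuntimeError):
                return None
            eff = fit.effects.as_array()
            row = {
                "n": n, "h2": h2, "replicate": rep, "seed": seed,
                "p": pg.params.p, "D1": pg.params.D1, "D2": pg.params.D2,
                "u": fit.rates.u, "v": fit.rates.v,
            }
            row.update(dict(zip(EFFECT_NAMES[1:], eff[1:].tolist())))
            return row

        df = _run_cell(
            grid, cell_index, one_replicate,
            _cache_path(None if cache_dir is None else Path(cache_dir),
                        "recovery", cell_index),
        )
        n_excluded += grid.n_replicates - len(df)
        all_reps.append(df)
        summary = {"n": n, "h2": h2, "n_replicates": len(df)}
        for col in PARAM_COLUMNS:
            vals = df[col].to_numpy()
            summary[f"{col}_mean"] = float(vals.mean())
            summary[f"{col}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            summary[f"{col}_se"] = (
                summary[f"{col}_sd"] / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
            )
        cell_rows.append(summary)
    return StudyResult(
        cells=pd.DataFrame(cell_rows),
        replicates=pd.concat(all_reps, ignore_index=True),
        n_excluded=n_excluded,
    )


def _test_replicate(
    test: str,
    sample,
    seed: int,
    fit_kwargs: dict,
) -> float:
    if test == "association":
        return lrt_association(sample, seed=seed, **fit_kwargs).p_value
    if test == "imprinting":
        return lrt_effects(sample, which=("lam",), seed=seed, **fit_kwargs).p_value
    if test == "imprinting_joint":
        return lrt_effects(
            sample,
            which=("lam", "I_a_lam", "I_d_lam", "I_dprime_lam"),
            seed=seed,
            **fit_kwargs,
        ).p_value
    raise ValueError(
        f"unknown test {test!r}; expected 'association', 'imprinting' or "
        "'imprinting_joint'"
    )


_NULL_FOR_TEST = {
    "association": "no_effect",
    "imprinting": "no_imprinting",
    "imprinting_joint": "no_imprinting",
}


def run_power_study(
    grid: StudyGrid,
    test: str = "imprinting",
    generator: str = "alternative",
    cache_dir: Path | str | None = None,
    fit_kwargs: dict | None = None,
) -> StudyResult:
    """Empirical rejection rate of a named test across the grid.

    With ``generator='alternative'`` the rejection fraction is the power of
    the test at level ``grid.alpha``; with ``generator='null'`` the data are
    drawn under the test's own null (all-effects-null for the association
    test, imprinting-null for the imprinting tests) and the fraction is the
    empirical type-I error.
    """
    if generator not in ("alternative", "null"):
        raise ValueError(f"unknown generator {generator!r}")
    if test not in _NULL_FOR_TEST:
        raise ValueError(
            f"unknown test {test!r}; expected one of {sorted(_NULL_FOR_TEST)}"
        )
    fit_kwargs = fit_kwargs or {}
    all_reps = []
    n_excluded = 0
    cell_rows = []
    for cell_index, (n, h2) in enumerate(
        (n, h2) for n in grid.sample_sizes for h2 in grid.heritabilities
    ):

        def one_replicate(rep: int, seed: int) -> dict | None:
            scenario = grid.scenario(n, h2, seed)
            if generator == "alternative":
                sim = simulate_sample(scenario)
            else:
                sim = simulate_null_sample(scenario, null=_NULL_FOR_TEST[test])
            try:
                p_value = _test_replicate(test, sim.sample, seed, fit_kwargs)
            except (ValueError, RuntimeError):
                return None
            return {
                "n": n, "h2": h2, "replicate": rep, "seed": seed,
                "p_value": p_value, "reject": p_value < grid.alpha,
            }

        df = _run_cell(
            grid, cell_index, one_replicate,
            _cache_path(None if cache_dir is None else Path(cache_dir),
                        f"power_{test}_{generator}", cell_index),
        )
        n_excluded += grid.n_replicates - len(df)
        all_reps.append(df)
        rate = float(df["reject"].mean()) if len(df) else float("nan")
        cell_rows.append(
            {
                "n": n, "h2": h2, "n_replicates": len(df),
                "rejection_rate": rate,
                "mc_se": float(np.sqrt(rate * (1 - rate) / len(df)))
                if len(df) else float("nan"),
                "test": test, "generator": generator,
            }
        )
    return StudyResult(
        cells=pd.DataFrame(cell_rows),
        replicates=pd.concat(all_reps, ignore_index=True),
        n_excluded=n_excluded,
    )
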