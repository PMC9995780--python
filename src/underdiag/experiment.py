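"""Scenario runner: the full simulation grid and its summary table.

``run_scenario`` executes the Monte-Carlo loop for one grid cell — simulate a
cohort, fit the logistic model to the true status and to the misclassified
status, test the slope at the chosen level — and aggregates the replicate
results into the five summary statistics the study reports per cell: mean
estimated slope under each outcome, the bias of the misclassified estimate
(true slope minus its mean estimate, so positive numbers mean attenuation
toward the null), and power under each outcome.

``run_study`` maps this over a grid of scenarios with per-scenario seeds
derived from a single root seed, so the full study is reproducible and its
results do not depend on execution order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import Scenario, simulate_cohort, simulate_genotypes
from .errors import DegenerateOutcomeError, InvalidParameterError
from .inference import FitResult, fit_logistic, wald_test

__all__ = [
    "ScenarioSummary",
    "PAPER_GRID_CONFIG",
    "build_grid",
    "load_config",
    "run_scenario",
    "run_study",
    "replicates_frame",
    "summarize_replicates",
    "render_report",
]

# The study's default grid: 3 intercepts x 3 misclassification rates,
# slope 0.1, MAF 0.3, n = 20 000, 1000 replicates.
PAPER_GRID_CONFIG: dict = {
    "beta0_list": [-1.5, -1.0, -0.5],
    "pi_list": [0.4, 0.6, 0.8],
    "betag": 0.1,
    "maf": 0.3,
    "n": 20_000,
    "reps": 1000,
    "seed": 20221215,
    "alpha": 0.05,
}


@dataclass(frozen=True)
class ScenarioSummary:
    """The per-cell summary statistics of the simulation study.

    Means are taken over converged fits only; powers count non-converged fits
    as non-significant and divide by all replicates. ``*_mc_se`` fields carry
    the Monte-Carlo standard errors of the corresponding estimates.
    """

    scenario: Scenario
    mean_betag_true: float
    mean_betag_obs: float
    bias_obs: float
    power_true: float
    power_obs: float
    n_converged_true: int
    n_converged_obs: int
    mean_betag_true_mc_se: float
    mean_betag_obs_mc_se: float
    power_true_mc_se: float
    power_obs_mc_se: float


def build_grid(
    beta0_list: Sequence[float],
    pi_list: Sequence[float],
    betag: float,
    maf: float,
    n: int,
    reps: int,
    seed: int,
) -> list[Scenario]:
    """Cross product of intercepts and misclassification rates.

    Per-scenario seeds are derived deterministically from the root ``seed``
    (one spawned stream per grid cell, in grid order), so any subset of the
    grid reproduces exactly the same cells as the full run.
    """
    cells = [(b0, pi) for b0 in beta0_list for pi in pi_list]
    # 32-bit child seeds, kept below 2**31 so they survive any int round-trip
    child_seeds = (
        np.random.SeedSequence(seed).generate_state(len(cells)) % (2**31)
    )
    return [
        Scenario(
            beta0=b0, betag=betag, maf=maf, pi=pi,
            n=n, reps=reps, seed=int(s),
        )
        for (b0, pi), s in zip(cells, child_seeds)
    ]


def load_config(path: str | Path) -> dict:
    """Read a YAML study configuration; missing keys fall back to defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    unknown = set(user) - set(PAPER_GRID_CONFIG)
    if unknown:
        raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
    cfg = {**PAPER_GRID_CONFIG, **user}
    return cfg


def _grid_from_config(cfg: dict) -> list[Scenario]:
    return build_grid(
        cfg["beta0_list"], cfg["pi_list"], cfg["betag"], cfg["maf"],
        cfg["n"], cfg["reps"], cfg["seed"],
    )


def run_scenario(
    scenario: Scenario,
    alpha: float = 0.05,
    redraw_genotypes: bool = True,
    keep_replicates: bool = False,
) -> ScenarioSummary | tuple[ScenarioSummary, pd.DataFrame]:
    """Monte-Carlo loop for one grid cell.

    Each replicate simulates a cohort, fits the logistic model to the true and
    to the observed (misclassified) status, and applies the two-sided Wald
    test at level ``alpha``. ``redraw_genotypes=False`` freezes the genotype
    vector of the first replicate across all replicates (the study default
    redraws it, making replicates fully independent).

    A replicate whose observed outcome is degenerate (no observed cases, as
    happens for every replicate when pi = 1) contributes a non-significant,
    non-converged observed fit rather than an error; if no observed fit
    converges the observed mean is reported as NaN with power 0.
    """
    rngs = scenario.replicate_rngs()
    fixed_genotype = None
    if not redraw_genotypes:
        fixed_genotype = simulate_genotypes(
            scenario.n, scenario.maf, np.random.default_rng(scenario.seed)
        )

    rows = []
    for rep, rng in enumerate(rngs):
        if fixed_genotype is None:
            cohort = simulate_cohort(scenario, rng)
        else:
            from .cohort import (
                Cohort, apply_misclassification, disease_probability,
                simulate_true_status,
            )

            p = disease_probability(fixed_genotype, scenario.beta0, scenario.betag)
            d = simulate_true_status(p, rng)
            obs = apply_misclassification(d, scenario.pi, rng)
            cohort = Cohort(fixed_genotype, d, obs)

        fits: dict[str, FitResult] = {}
        for label, outcome in (
            ("true", cohort.true_status),
            ("obs", cohort.observed_status),
        ):
            try:
                fits[label] = fit_logistic(cohort.genotype, outcome)
            except DegenerateOutcomeError:
                fits[label] = FitResult(np.nan, np.nan, np.nan, np.nan, False, 0)

        row = {"rep": rep}
        for label, fr in fits.items():
            sig = False
            if fr.converged:
                sig, _ = wald_test(fr.betag_hat, fr.se_betag, alpha)
            row.update(
                {
                    f"betag_hat_{label}": fr.betag_hat,
                    f"se_{label}": fr.se_betag,
                    f"pvalue_{label}": fr.pvalue,
                    f"converged_{label}": fr.converged,
                    f"significant_{label}": sig,
                }
            )
        rows.append(row)

    reps = pd.DataFrame(rows)
    summary = summarize_replicates(scenario, reps)
    if keep_replicates:
        return summary, reps
    return summary


def summarize_replicates(scenario: Scenario, reps: pd.DataFrame) -> ScenarioSummary:
    """Aggregate a per-replicate table into a ScenarioSummary."""
    out: dict[str, float | int] = {}
    n_reps = len(reps)
    for label in ("true", "obs"):
        conv = reps[f"converged_{label}"].to_numpy(dtype=bool)
        est = reps.loc[conv, f"betag_hat_{label}"].to_numpy()
        out[f"n_converged_{label}"] = int(conv.sum())
        if conv.any():
            out[f"mean_betag_{label}"] = float(est.mean())
            out[f"mean_betag_{label}_mc_se"] = (
                float(est.std(ddof=1) / np.sqrt(len(est))) if len(est) > 1 else np.nan
            )
        else:
            out[f"mean_betag_{label}"] = np.nan
            out[f"mean_betag_{label}_mc_se"] = np.nan
        p = float(reps[f"significant_{label}"].mean())
        out[f"power_{label}"] = p
        out[f"power_{label}_mc_se"] = float(np.sqrt(p * (1 - p) / n_reps))
    return ScenarioSummary(
        scenario=scenario,
        mean_betag_true=out["mean_betag_true"],
        mean_betag_obs=out["mean_betag_obs"],
        bias_obs=scenario.betag - out["mean_betag_obs"],
        power_true=out["power_true"],
        power_obs=out["power_obs"],
        n_converged_true=out["n_converged_true"],
        n_converged_obs=out["n_converged_obs"],
        mean_betag_true_mc_se=out["mean_betag_true_mc_se"],
        mean_betag_obs_mc_se=out["mean_betag_obs_mc_se"],
        power_true_mc_se=out["power_true_mc_se"],
        power_obs_mc_se=out["power_obs_mc_se"],
    )


def run_study(
    grid: Iterable[Scenario],
    alpha: float = 0.05,
    keep_replicates: bool = False,
) -> list[ScenarioSummary] | tuple[list[ScenarioSummary], pd.DataFrame]:
    """Run every scenario in the grid; one summary per cell.

    Replicate seeding is per-scenario (each Scenario carries its own seed), so
    cells may be run in any order — or concurrently — with identical results.
    """
    grid = list(grid)
    if not grid:
        raise InvalidParameterError("grid must be non-empty")
    summaries = []
    rep_frames = []
    for scenario in grid:
        result = run_scenario(
            scenario, alpha=alpha, keep_replicates=keep_replicates
        )
        if keep_replicates:
            summary, reps = result
            reps = reps.assign(
                beta0=scenario.beta0, pi=scenario.pi, betag=scenario.betag,
                maf=scenario.maf, n=scenario.n, seed=scenario.seed,
            )
            rep_frames.append(reps)
        else:
            summary = result
        summaries.append(summary)
    if keep_replicates:
        return summaries, pd.concat(rep_frames, ignore_index=True)
    return summaries


def replicates_frame(reps: pd.DataFrame, path: str | Path) -> None:
    """Write the per-replicate long table as CSV."""
    reps.to_csv(path, index=False)


def render_report(
    summaries: Sequence[ScenarioSummary],
) -> tuple[pd.DataFrame, str]:
    """Summary table mirroring the study's reporting conventions.

    Returns the numeric DataFrame (full precision) and a formatted text table
    with estimates and bias printed to 3 decimals and power to 2, grouped by
    prevalence block (intercept). Unavailable means render as "NA".
    """
    if not summaries:
        raise InvalidParameterError("summaries must be non-empty")
    df = pd.DataFrame(
        {
            "beta0": s.scenario.beta0,
            "pi": s.scenario.pi,
            "mean_betag_true": s.mean_betag_true,
            "mean_betag_obs": s.mean_betag_obs,
            "bias_obs": s.bias_obs,
            "power_true": s.power_true,
            "power_obs": s.power_obs,
            "power_true_mc_se": s.power_true_mc_se,
            "power_obs_mc_se": s.power_obs_mc_se,
            "n_converged_true": s.n_converged_true,
            "n_converged_obs": s.n_converged_obs,
        }
        for s in summaries
    )

    def f3(x: float) -> str:
        return "NA" if not np.isfinite(x) else f"{x:.3f}"

    def f2(x: float) -> str:
        return "NA" if not np.isfinite(x) else f"{x:.2f}"

    lines = [
        "pi    mean_bg(true)  mean_bg(obs)  bias(obs)  power(true)  power(obs)"
    ]
    for beta0, block in df.groupby("beta0", sort=True):
        lines.append(f"-- intercept beta0 = {beta0:g} --")
        for _, r in block.sort_values("pi").iterrows():
            lines.append(
                f"{r['pi']:<6g}{f3(r['mean_betag_true']):>13}"
                f"{f3(r['mean_betag_obs']):>14}{f3(r['bias_obs']):>11}"
                f"{f2(r['power_true']):>13}{f2(r['power_obs']):>12}"
            )
    return df, "\n".join(lines)
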