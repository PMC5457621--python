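"""Monte-Carlo ensembles of agreement-map trajectories.

Repeated runs of the stochastic recurrence characterise the two absorbing
branches: their symmetry (the branch choice is random, null proportion 1/2),
the distribution of absorption steps across N and fluctuation scales, and
the effect of designating ``Pcb0`` as the experimental control — which
eliminates the reverse-relationship branch (stable position #2), because the
control label cannot be associated both with change and with the unchanged
resting state.  That elimination is realised here as post-selection:
zero-branch trajectories are discarded and the surviving ensemble has
empirical Prob(direct) = 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import FluctuationSpec, ModelParams
from .dynamics import Trajectory, simulate_trajectory

__all__ = [
    "EnsembleSummary",
    "SymmetryTest",
    "simulate_many",
    "run_ensemble",
    "branch_symmetry_test",
    "binom_exact_pvalue",
    "apply_control_constraint",
    "sweep",
]

logger = logging.getLogger("placebosim")


@dataclass(frozen=True)
class EnsembleSummary:
    """Branch counts and absorption-step statistics for one ensemble."""

    n_runs: int
    n_absorbed_one: int
    n_absorbed_zero: int
    n_unabsorbed: int
    step_min: Optional[int]
    step_median: Optional[float]
    step_max: Optional[int]
    params: ModelParams
    base_seed: int
    constrained: bool = False
    n_discarded: int = 0
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.n_absorbed_one + self.n_absorbed_zero + self.n_unabsorbed != self.n_runs:
            raise ValueError("branch counts must partition n_runs")
        if self.constrained and self.n_absorbed_zero != 0:
            raise ValueError("a constrained ensemble cannot contain zero-branch runs")

    def to_dict(self) -> dict:
        p = self.params
        return {
            "n_runs": self.n_runs,
            "n_absorbed_one": self.n_absorbed_one,
            "n_absorbed_zero": self.n_absorbed_zero,
            "n_unabsorbed": self.n_unabsorbed,
            "absorption_steps": {
                "min": self.step_min,
                "median": self.step_median,
                "max": self.step_max,
            },
            "params": {
                "n_observers": p.n_observers,
                "p_direct": p.p_direct,
                "d_param": p.d_param,
                "p0": p.p0,
                "fluct": {
                    "distribution": p.fluct.distribution,
                    "half_width_or_sd": p.fluct.half_width_or_sd,
                },
            },
            "base_seed": self.base_seed,
            "constrained": self.constrained,
            "n_discarded": self.n_discarded,
            "degenerate": self.degenerate,
        }


def simulate_many(
    params: ModelParams,
    n_runs: int,
    max_steps: int,
    base_seed: int,
    **kwargs,
) -> list[Trajectory]:
    """Simulate ``n_runs`` independent trajectories, run i seeded base_seed + i."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    return [
        simulate_trajectory(params, max_steps, base_seed + i, **kwargs)
        for i in range(n_runs)
    ]


def summarize(
    trajectories: Sequence[Trajectory],
    base_seed: int,
    *,
    constrained: bool = False,
    n_discarded: int = 0,
    degenerate: bool = False,
) -> EnsembleSummary:
    """Aggregate branch counts and absorption-step statistics."""
    if not trajectories and not degenerate:
        raise ValueError("empty trajectory list")
    n_one = sum(t.absorbed_at == "one" for t in trajectories)
    n_zero = sum(t.absorbed_at == "zero" for t in trajectories)
    n_none = sum(t.absorbed_at == "none" for t in trajectories)
    steps = [t.absorption_step for t in trajectories if t.absorption_step is not None]
    params = trajectories[0].params if trajectories else ModelParams()
    return EnsembleSummary(
        n_runs=len(trajectories),
        n_absorbed_one=n_one,
        n_absorbed_zero=n_zero,
        n_unabsorbed=n_none,
        step_min=min(steps) if steps else None,
        step_median=float(np.median(steps)) if steps else None,
        step_max=max(steps) if steps else None,
        params=params,
        base_seed=base_seed,
        constrained=constrained,
        n_discarded=n_discarded,
        degenerate=degenerate,
    )


def run_ensemble(
    params: ModelParams,
    n_runs: int,
    max_steps: int,
    base_seed: int,
    **kwargs,
) -> EnsembleSummary:
    """Simulate and summarize an ensemble; deterministic given base_seed."""
    trajs = simulate_many(params, n_runs, max_steps, base_seed, **kwargs)
    summary = summarize(trajs, base_seed)
    logger.info(
        "ensemble base_seed=%d N=%d runs=%d: one=%d zero=%d unabsorbed=%d median_step=%s",
        base_seed,
        params.n_observers,
        n_runs,
        summary.n_absorbed_one,
        summary.n_absorbed_zero,
        summary.n_unabsorbed,
        summary.step_median,
    )
    return summary


# ---------------------------------------------------------------------------
# Branch symmetry
# ---------------------------------------------------------------------------

def binom_exact_pvalue(k: int, n: int, p0: float = 0.5) -> float:
    """Two-sided exact binomial p-value from first principles.

    Sums the point masses of Binomial(n, p0) that do not exceed the observed
    mass (with a 1 + 1e-7 relative tolerance against rounding, the standard
    convention for this minimum-likelihood two-sided test).
    """
    if not (0 <= k <= n):
        raise ValueError("k must lie in [0, n]")
    if n == 0:
        return 1.0
    logp0 = math.log(p0)
    logq0 = math.log1p(-p0)
    lgn = math.lgamma(n + 1)

    def logpmf(i: int) -> float:
        return lgn - math.lgamma(i + 1) - math.lgamma(n - i + 1) + i * logp0 + (n - i) * logq0

    obs = logpmf(k)
    cut = obs + 1e-7
    total = sum(math.exp(lp) for lp in (logpmf(i) for i in range(n + 1)) if lp <= cut)
    return min(1.0, total)


@dataclass(frozen=True)
class SymmetryTest:
    """Exact test of the one-branch proportion against the null 1/2."""

    n_absorbed: int
    n_one: int
    proportion: float
    p_value: float
    ci_low: float
    ci_high: float


def branch_symmetry_test(summary: EnsembleSummary) -> SymmetryTest:
    """Test whether the absorbing-branch choice is a fair coin.

    Requires an unconstrained, fully absorbed ensemble.  Returns the
    one-branch proportion, the exact two-sided binomial p-value against 1/2,
    and the 95% Clopper-Pearson interval.
    """
    if summary.constrained:
        raise ValueError("symmetry test requires an unconstrained ensemble")
    if summary.n_unabsorbed:
        raise ValueError("symmetry test requires a fully absorbed ensemble")
    n = summary.n_runs
    k = summary.n_absorbed_one
    lo = 0.0 if k == 0 else float(stats.beta.ppf(0.025, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(0.975, k + 1, n - k))
    return SymmetryTest(
        n_absorbed=n,
        n_one=k,
        proportion=k / n,
        p_value=binom_exact_pvalue(k, n),
        ci_low=lo,
        ci_high=hi,
    )


# ---------------------------------------------------------------------------
# Control constraint (post-selection of stable position #1)
# ---------------------------------------------------------------------------

def apply_control_constraint(trajectories: Sequence[Trajectory]) -> EnsembleSummary:
    """Discard zero-branch runs: Pcb0 designated as control.

    The control label must stay associated with the unchanged resting state,
    so the reverse-relationship branch (absorption at 0) eliminates itself.
    The surviving ensemble has empirical Prob(direct) = 1.  An ensemble with
    no survivors yields a degenerate summary (flagged, not raised).
    """
    survivors = [t for t in trajectories if t.absorbed_at != "zero"]
    n_discarded = len(trajectories) - len(survivors)
    if not survivors:
        return EnsembleSummary(
            n_runs=0,
            n_absorbed_one=0,
            n_absorbed_zero=0,
            n_unabsorbed=0,
            step_min=None,
            step_median=None,
            step_max=None,
            params=trajectories[0].params if trajectories else ModelParams(),
            base_seed=trajectories[0].seed if trajectories else 0,
            constrained=True,
            n_discarded=n_discarded,
            degenerate=True,
        )
    base_seed = min(t.seed for t in survivors)
    return summarize(
        survivors, base_seed, constrained=True, n_discarded=n_discarded
    )


# ---------------------------------------------------------------------------
# Parameter sweep
# ---------------------------------------------------------------------------

def sweep(
    n_values: Sequence[int],
    widths: Sequence[float],
    n_runs_per_cell: int,
    base_seed: int,
    *,
    max_steps: int = 1000,
    distribution: str = "uniform",
) -> pd.DataFrame:
    """Median absorption step across observer counts and fluctuation scales.

    Returns a long-format table (columns N, half_width, n_runs, median_step,
    q25, q75, frac_absorbed).  Transitions speed up both with more observers
    (deviation amplified ~N per step) and with larger fluctuations (less
    distance to cover), so medians are non-increasing along each axis.  Cells
    with N < 2 are no-transition regimes and report NaN medians.
    """
    rows = []
    cell = 0
    for n_obs in n_values:
        for w in widths:
            spec = FluctuationSpec(distribution=distribution, half_width_or_sd=w)
            params = ModelParams(n_observers=n_obs, fluct=spec)
            cell_seed = base_seed + cell * n_runs_per_cell
            cell += 1
            trajs = simulate_many(params, n_runs_per_cell, max_steps, cell_seed)
            steps = [t.absorption_step for t in trajs if t.absorption_step is not None]
            rows.append(
                {
                    "N": n_obs,
                    "half_width": w,
                    "n_runs": n_runs_per_cell,
                    "median_step": float(np.median(steps)) if steps else float("nan"),
                    "q25": float(np.percentile(steps, 25)) if steps else float("nan"),
                    "q75": float(np.percentile(steps, 75)) if steps else float("nan"),
                    "frac_absorbed": len(steps) / n_runs_per_cell,
                }
            )
    return pd.DataFrame(rows)
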