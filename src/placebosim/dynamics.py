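"""Stochastic recurrence of the agreement map: metastability and absorption.

In a real experiment the direct-relationship probability is perturbed each
elementary time interval by a tiny random fluctuation eps (|eps| << 1, by
default uniform on ±0.5e-15), and the team of N observers re-establishes
agreement at every step:

    p_{n+1} = f_N(p_n + eps_{n+1}),    p_0 = 1/2.

For N >= 2 the map amplifies any deviation from the metastable point 1/2 by
a factor ~N per step, so after a quiet stretch whose length is roughly
log_N(0.25 / eps-scale) the trajectory crosses over sharply ("dramatic
transition") and is absorbed at exactly 0 or 1.  N = 0 pins p at 1/2, N = 1
is a neutral random walk, and eps = 0 leaves the fixed point untouched — the
no-transition regimes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .core import (  # noqa: F401  (FluctuationSpec re-exported here by design)
    DEFAULT_FLUCT_SCALE,
    FluctuationSpec,
    ModelParams,
    agreement_prob,
)

__all__ = [
    "FluctuationSpec",
    "Trajectory",
    "make_rng",
    "step",
    "simulate_trajectory",
    "transition_step",
]

logger = logging.getLogger("placebosim")

#: A trajectory is absorbed once p is within this distance of 0 or 1; the
#: final value is then snapped onto the exact boundary, which is invariant
#: under the map.
DEFAULT_ATOL = 1e-12

#: Default "dramatic transition" threshold: halfway between the metastable
#: point 1/2 and either boundary.
DEFAULT_TRANSITION_THRESHOLD = 0.25

Branch = Literal["zero", "one", "none"]


def make_rng(base_seed: int, index: int = 0) -> np.random.Generator:
    """Counter-based generator for trajectory ``index`` of an ensemble.

    Uses the Philox bit generator keyed by ``base_seed + index``: distinct
    keys give statistically independent streams, and identical
    (base_seed, index) pairs reproduce the stream bit for bit.
    """
    return np.random.Generator(np.random.Philox(key=np.uint64(base_seed + index)))


def step(p: float, eps: float, n_observers: int) -> float:
    """One update of the fluctuation-perturbed agreement recurrence.

    Returns ``f_N(clamp(p + eps))`` where the clamp confines the perturbed
    probability to [0, 1] (a value pushed outside maps to the nearer
    boundary, which is absorbing).  With eps = 0 the metastable point 1/2 is
    an exact fixed point for every N.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must lie in [0, 1], got {p!r}")
    if not math.isfinite(eps):
        raise ValueError("eps must be finite")
    if abs(eps) >= 1.0:
        raise ValueError("eps must satisfy |eps| < 1")
    x = p + eps
    if x < 0.0:
        x = 0.0
    elif x > 1.0:
        x = 1.0
    return agreement_prob(x, n_observers)


@dataclass(frozen=True)
class Trajectory:
    """One realisation p_0 ... p_T of the stochastic recurrence.

    ``values[k]`` is the probability after k steps; ``eps_applied[k]`` is the
    fluctuation consumed by step k+1 (len(values) = len(eps_applied) + 1).
    ``absorbed_at`` records the absorbing branch ("one", "zero", or "none" if
    the run hit max_steps first), ``absorption_step`` the step index at which
    the snap occurred, and ``transition_step`` the first step at which
    |p - 1/2| exceeded the transition threshold.
    """

    values: np.ndarray
    eps_applied: np.ndarray
    absorbed_at: Branch
    absorption_step: Optional[int]
    transition_step: Optional[int]
    seed: int
    params: ModelParams

    @property
    def final_value(self) -> float:
        return float(self.values[-1])

    @property
    def n_steps(self) -> int:
        return len(self.values) - 1

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns step, p, eps_applied."""
        eps = np.concatenate([[np.nan], self.eps_applied])
        return pd.DataFrame(
            {"step": np.arange(len(self.values)), "p": self.values, "eps_applied": eps}
        )


def simulate_trajectory(
    params: ModelParams,
    max_steps: int,
    seed: int,
    *,
    atol: float = DEFAULT_ATOL,
    threshold: float = DEFAULT_TRANSITION_THRESHOLD,
) -> Trajectory:
    """Iterate the recurrence from p0 with freshly drawn fluctuations.

    Stops early once p is within ``atol`` of a boundary, snapping the final
    value to exactly 0 or 1 (both are invariant under the map, so all further
    iterates would be unchanged).  Fully reproducible from (params, seed).
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    rng = make_rng(seed)
    eps = params.fluct.sample(rng, max_steps)
    values = [params.p0]
    absorbed_at: Branch = "none"
    absorption_step: Optional[int] = None
    p = params.p0
    n_used = 0
    for i in range(max_steps):
        p = step(p, float(eps[i]), params.n_observers)
        n_used = i + 1
        if p <= atol:
            p = 0.0
            absorbed_at = "zero"
            absorption_step = n_used
        elif p >= 1.0 - atol:
            p = 1.0
            absorbed_at = "one"
            absorption_step = n_used
        values.append(p)
        if absorbed_at != "none":
            break
    arr = np.asarray(values, dtype=float)
    traj = Trajectory(
        values=arr,
        eps_applied=np.asarray(eps[:n_used], dtype=float),
        absorbed_at=absorbed_at,
        absorption_step=absorption_step,
        transition_step=_first_crossing(arr, threshold),
        seed=seed,
        params=params,
    )
    logger.debug(
        "trajectory seed=%d: %d steps, absorbed_at=%s (step %s)",
        seed,
        traj.n_steps,
        absorbed_at,
        absorption_step,
    )
    return traj


def _first_crossing(values: np.ndarray, threshold: float) -> Optional[int]:
    hits = np.flatnonzero(np.abs(values - 0.5) > threshold)
    return int(hits[0]) if hits.size else None


def transition_step(traj: Trajectory, threshold: float = DEFAULT_TRANSITION_THRESHOLD) -> Optional[int]:
    """First step index at which |p - 1/2| exceeds ``threshold``, or None.

    Formalizes the "dramatic transition" out of the metastable point; the
    default threshold 0.25 is halfway between 1/2 and either boundary.
    """
    if not (0.0 < threshold < 0.5):
        raise ValueError("threshold must lie in (0, 0.5)")
    return _first_crossing(traj.values, threshold)
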