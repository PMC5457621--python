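"""Agreement probabilities and amplitude calculus for a two-placebo experiment.

The model describes a minimal experiment in which every sample is an inert
placebo carrying one of two labels (``Pcb0``, ``Pcb1``) and a biological
system shows either no change ("down", the resting state) or a change ("up").
A *direct* relationship pairs ``Pcb0`` with no change and ``Pcb1`` with
change; the *reverse* relationship is the opposite pairing.

A team of N interacting observers is described from the standpoint of an
uninvolved participant: each observer holds an independent probabilistic
expectation ``p`` for the direct relationship, and intersubjective agreement
discards joint configurations in which observers disagree.  Renormalising the
surviving configurations yields the agreement map

    f_N(p) = p^N / (p^N + q^N),    q = 1 - p,

algebraically identical to 1 / (1 + (1/p - 1)^N) but exact at the boundaries.
This module holds everything closed form:

* the agreement map and its brute-force-checkable two-observer joint table;
* the covariance-like independence parameter ``d`` interpolating between
  fully independent observer expectations (d = 0) and classical probability
  (d = pq), for the two-observer case;
* the path-amplitude calculus that distinguishes local from remote (i.e.
  centralized) blind assessment of the label-outcome correlations;
* the law-of-total-probability result for observers who perceive the
  relationship only as uncoupled sub-events;
* numerical fixed-point analysis of the agreement map.

Iteration of the agreement map under tiny random fluctuations lives in
:mod:`placebosim.dynamics`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal

__all__ = [
    "FluctuationSpec",
    "ModelParams",
    "AmplitudePair",
    "FixedPoint",
    "FixedPointResult",
    "agreement_prob",
    "agreement_prob_d",
    "joint_outcome_table",
    "coherent_path_probs",
    "classical_path_probs",
    "assessment_prediction",
    "total_prob_unstructured",
    "fixed_points",
]

#: Default fluctuation half-width: uniform draws on [-0.5e-15, +0.5e-15].
DEFAULT_FLUCT_SCALE = 0.5e-15

#: Fluctuation scales above this trigger a warning — the model assumes |eps| << 1.
FLUCT_WARN_SCALE = 1e-3


@dataclass(frozen=True)
class FluctuationSpec:
    """Distribution of the elementary probability fluctuations eps_i.

    The default is uniform on ``[-0.5e-15, +0.5e-15]``, the scale of the
    elementary fluctuations perturbing the metastable point in the reference
    simulations.  For a Gaussian spec, ``half_width_or_sd`` is the standard
    deviation.
    """

    distribution: Literal["uniform", "gaussian"] = "uniform"
    half_width_or_sd: float = DEFAULT_FLUCT_SCALE

    def __post_init__(self) -> None:
        if self.distribution not in ("uniform", "gaussian"):
            raise ValueError(f"unknown distribution: {self.distribution!r}")
        if not (self.half_width_or_sd > 0):
            raise ValueError("half_width_or_sd must be positive")
        if self.half_width_or_sd > FLUCT_WARN_SCALE:
            warnings.warn(
                "fluctuation scale %g is large; the model assumes |eps| << 1"
                % self.half_width_or_sd,
                stacklevel=2,
            )

    def sample(self, rng, size: int):
        """Draw ``size`` fluctuations from this spec using generator ``rng``."""
        if self.distribution == "uniform":
            w = self.half_width_or_sd
            return rng.uniform(-w, w, size)
        return rng.normal(0.0, self.half_width_or_sd, size)


def _check_prob(x: float, name: str) -> None:
    if not (0.0 <= x <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {x!r}")


@dataclass(frozen=True)
class ModelParams:
    """Full parameterization of the agreement model.

    Parameters
    ----------
    n_observers
        Number N of interacting observers (N >= 0).  N = 0 means no one
        observes and the direct-relationship probability is pinned at 1/2.
    p_direct
        Per-observer probability p of expecting the direct relationship;
        q = 1 - p is derived.
    d_param
        Independence parameter d in [0, pq] (two-observer interpolation).
    p0
        Initial probability of the direct relationship for trajectory
        simulation; 1/2 is the observer-free metastable value.
    fluct
        Fluctuation distribution for the stochastic recurrence.
    """

    n_observers: int = 2
    p_direct: float = 0.5
    d_param: float = 0.0
    p0: float = 0.5
    fluct: FluctuationSpec = field(default_factory=FluctuationSpec)

    def __post_init__(self) -> None:
        if self.n_observers < 0 or int(self.n_observers) != self.n_observers:
            raise ValueError("n_observers must be a non-negative integer")
        _check_prob(self.p_direct, "p_direct")
        _check_prob(self.p0, "p0")
        pq = self.p_direct * (1.0 - self.p_direct)
        if not (0.0 <= self.d_param <= pq + 1e-12):
            raise ValueError(
                f"d_param must lie in [0, p*(1-p)] = [0, {pq!r}], got {self.d_param!r}"
            )

    @property
    def q_direct(self) -> float:
        """q = 1 - p, the per-observer reverse-relationship probability."""
        return 1.0 - self.p_direct


@dataclass(frozen=True)
class AmplitudePair:
    """Real probability amplitudes (a, b) with a^2 = Prob(Pcb0), b^2 = Prob(Pcb1)."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.a) and math.isfinite(self.b)):
            raise ValueError("amplitudes must be finite")

    @property
    def norm_sq(self) -> float:
        return self.a * self.a + self.b * self.b

    @classmethod
    def symmetric(cls) -> "AmplitudePair":
        """The equal-label pair a = b = 1/sqrt(2) (normalized)."""
        r = 1.0 / math.sqrt(2.0)
        return cls(r, r)


# ---------------------------------------------------------------------------
# Agreement probabilities
# ---------------------------------------------------------------------------

def agreement_prob(p: float, n_observers: int) -> float:
    """Probability that N agreeing observers record the direct relationship.

    Evaluates ``f_N(p) = p^N / (p^N + q^N)`` with ``q = 1 - p``: each of N
    observers independently expects the direct relationship with probability
    p, disagreeing joint configurations are discarded, and the all-direct
    weight is renormalized against the all-reverse weight.

    Boundary behaviour: N = 0 returns 1/2 for every p (no observers, no
    preference); p = 0 and p = 1 return 0 and 1 for N >= 1 (continuity
    limits — these are the absorbing states).
    """
    _check_prob(p, "p")
    if n_observers < 0 or int(n_observers) != n_observers:
        raise ValueError("n_observers must be a non-negative integer")
    n = int(n_observers)
    if n == 0:
        return 0.5
    q = 1.0 - p
    pn = p**n
    qn = q**n
    denom = pn + qn
    if denom == 0.0:  # deep underflow; decide by which side dominates
        return 1.0 if p > q else 0.0
    return pn / denom


def agreement_prob_d(p: float, d: float) -> float:
    """Two-observer direct-relationship probability with independence parameter d.

    ``(p^2 + d) / (p^2 + q^2 + 2 d)``: d = 0 recovers fully independent
    observer expectations (``agreement_prob(p, 2)``); d = p q recovers the
    classical value p, with the observers' attention fully drawn away from
    the joint relationship.
    """
    _check_prob(p, "p")
    q = 1.0 - p
    pq = p * q
    if not (0.0 <= d <= pq + 1e-12):
        raise ValueError(f"d must lie in [0, p*q] = [0, {pq!r}], got {d!r}")
    num = p * p + d
    den = p * p + q * q + 2.0 * d
    if den == 0.0:
        return 0.5
    return num / den


def joint_outcome_table(p: float, d: float) -> dict[tuple[str, str], float]:
    """Joint weights of the two observers' outcomes at independence parameter d.

    Returns the four cell weights ``{(direct, direct): p^2 + d,
    (direct, reverse): pq - d, (reverse, direct): pq - d,
    (reverse, reverse): q^2 + d}``, which sum to one.  The off-diagonal cells
    are the disagreement configurations barred by intersubjective agreement;
    renormalizing the agreement diagonal reproduces :func:`agreement_prob_d`.
    """
    _check_prob(p, "p")
    q = 1.0 - p
    pq = p * q
    if not (0.0 <= d <= pq + 1e-12):
        raise ValueError(f"d must lie in [0, p*q] = [0, {pq!r}], got {d!r}")
    return {
        ("direct", "direct"): p * p + d,
        ("direct", "reverse"): pq - d,
        ("reverse", "direct"): pq - d,
        ("reverse", "reverse"): q * q + d,
    }


# ---------------------------------------------------------------------------
# Path-amplitude calculus (local vs. remote blind assessment)
# ---------------------------------------------------------------------------

def coherent_path_probs(amps: AmplitudePair) -> tuple[float, float]:
    """(direct, reverse) probabilities when paths are indistinguishable.

    Without a remote supervisor the two label "paths" interfere: the
    direct-relationship probability is the *square of the sum* of the path
    amplitudes, ``(a*a + b*b)^2``, and the reverse component ``(b*a - a*b)^2``
    cancels identically.  For normalized amplitudes the pair is (1, 0).
    """
    a, b = amps.a, amps.b
    direct = (a * a + b * b) ** 2
    reverse = (b * a - a * b) ** 2
    return direct, reverse


def classical_path_probs(amps: AmplitudePair) -> tuple[float, float]:
    """(direct, reverse) probabilities when a remote supervisor tags the paths.

    Each path contributes its squared amplitude separately (*sum of squares*):
    direct is ``(a*a)^2 + (b*b)^2`` and reverse is ``(b*a)^2 + (a*b)^2``.
    The interference cross-term 2(ab)^2 moves from the direct component to
    the reverse component relative to :func:`coherent_path_probs`.
    """
    a, b = amps.a, amps.b
    direct = (a * a) ** 2 + (b * b) ** 2
    reverse = (b * a) ** 2 + (a * b) ** 2
    return direct, reverse


def assessment_prediction(mode: str) -> float:
    """Predicted direct-relationship probability under an assessment mode.

    ``"local"`` (open-label or local blind: someone inside the experiment
    assesses the correlations first) uses the coherent calculation and
    predicts 1; ``"remote"`` (centralized blind: an outside supervisor
    assesses first) uses the classical calculation and predicts 1/2.  Both
    are evaluated at the symmetric amplitudes a = b = 1/sqrt(2).
    """
    amps = AmplitudePair.symmetric()
    if mode == "local":
        return coherent_path_probs(amps)[0]
    if mode == "remote":
        return classical_path_probs(amps)[0]
    raise ValueError(f"mode must be 'local' or 'remote', got {mode!r}")


def total_prob_unstructured(
    prior_pcb0: float,
    cond_direct_given_pcb0: float,
    cond_direct_given_pcb1: float,
) -> float:
    """Direct-relationship probability for observers who see only sub-events.

    When the label-outcome relationship is not perceived as a structured
    whole, the two conditional sub-events evolve independently and the law of
    total probability applies:
    ``Prob(direct) = Prob(Pcb0) * Prob(direct | Pcb0)
    + Prob(Pcb1) * Prob(direct | Pcb1)``.
    With the stable conditionals (1 and 0) and equal label priors this gives
    1/2: no transition occurs for an unstructured perception.
    """
    _check_prob(prior_pcb0, "prior_pcb0")
    _check_prob(cond_direct_given_pcb0, "cond_direct_given_pcb0")
    _check_prob(cond_direct_given_pcb1, "cond_direct_given_pcb1")
    prior_pcb1 = 1.0 - prior_pcb0
    return prior_pcb0 * cond_direct_given_pcb0 + prior_pcb1 * cond_direct_given_pcb1


# ---------------------------------------------------------------------------
# Fixed-point analysis of the agreement map
# ---------------------------------------------------------------------------

Stability = Literal["attracting", "repelling", "neutral"]


@dataclass(frozen=True)
class FixedPoint:
    p_star: float
    derivative_magnitude: float
    stability: Stability


@dataclass(frozen=True)
class FixedPointResult:
    """Fixed points of the agreement map f_N and their linear stability."""

    n_observers: int
    points: tuple[FixedPoint, ...]
    identity_map: bool = False


def _map_derivative(n: int, p: float, h: float = 1e-5) -> float:
    """Finite-difference derivative of f_N at p (one-sided at the boundaries)."""
    if p - h < 0.0:
        return (agreement_prob(p + h, n) - agreement_prob(p, n)) / h
    if p + h > 1.0:
        return (agreement_prob(p, n) - agreement_prob(p - h, n)) / h
    return (agreement_prob(p + h, n) - agreement_prob(p - h, n)) / (2.0 * h)


def fixed_points(
    n_observers: int,
    *,
    grid_size: int = 2001,
    tol: float = 1e-12,
    neutral_tol: float = 1e-9,
) -> FixedPointResult:
    """Locate and classify the fixed points of the agreement map f_N.

    Scans ``f_N(p) - p`` on a dense grid for sign changes, refines each by
    bisection to ``tol``, and classifies stability from the magnitude of the
    numerically estimated derivative (attracting < 1, repelling > 1, neutral
    within ``neutral_tol`` of 1).  For N >= 2 the map has exactly three fixed
    points: the metastable point 1/2 (repelling, derivative magnitude N) and
    the absorbing boundaries 0 and 1 (attracting).  For N = 1 the map is the
    identity — every p is fixed — and the result is flagged accordingly.
    """
    if n_observers < 1 or int(n_observers) != n_observers:
        raise ValueError("n_observers must be an integer >= 1")
    n = int(n_observers)
    if n == 1:
        return FixedPointResult(
            n_observers=1,
            points=(FixedPoint(0.5, 1.0, "neutral"),),
            identity_map=True,
        )

    def g(p: float) -> float:
        return agreement_prob(p, n) - p

    roots: list[float] = []
    xs = [i / (grid_size - 1) for i in range(grid_size)]
    gs = [g(x) for x in xs]
    for i in range(grid_size - 1):
        x0, x1 = xs[i], xs[i + 1]
        g0, g1 = gs[i], gs[i + 1]
        if g0 == 0.0:
            roots.append(x0)
            continue
        if g0 * g1 < 0.0:
            lo, hi, glo = x0, x1, g0
            while hi - lo > tol:
                mid = 0.5 * (lo + hi)
                gm = g(mid)
                if gm == 0.0:
                    lo = hi = mid
                    break
                if glo * gm < 0.0:
                    hi = mid
                else:
                    lo, glo = mid, gm
            roots.append(0.5 * (lo + hi))
    if gs[-1] == 0.0:
        roots.append(xs[-1])

    # dedupe near-identical roots from adjacent grid cells
    deduped: list[float] = []
    for r in sorted(roots):
        if not deduped or r - deduped[-1] > 1e-9:
            deduped.append(r)

    pts = []
    for r in deduped:
        # snap near-boundary refinements onto the exact absorbing values
        if r < tol:
            r = 0.0
        elif r > 1.0 - tol:
            r = 1.0
        dmag = abs(_map_derivative(n, r))
        if abs(dmag - 1.0) < neutral_tol:
            stab: Stability = "neutral"
        elif dmag < 1.0:
            stab = "attracting"
        else:
            stab = "repelling"
        pts.append(FixedPoint(r, dmag, stab))
    return FixedPointResult(n_observers=n, points=tuple(pts))
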