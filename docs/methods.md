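# Methods

## Model and assumptions

The simulator implements a probabilistic model of correlations between
placebo labels and binary biological outcomes. Its ingredients, and the
assumptions they carry:

* **Two labels, two outcomes.** Every sample is inert; only the label
  (`Pcb0`/`Pcb1`) differs. The outcome is binary (no change ↓ vs. change ↑),
  e.g. a continuous endpoint dichotomised at a cut-off. The *direct*
  relationship pairs `Pcb0` with ↓ and `Pcb1` with ↑.
* **Independent expectations + intersubjective agreement.** Each of N
  interacting observers independently expects the direct relationship with
  probability p. Joint configurations in which observers disagree are
  discarded and the remainder renormalised, giving the agreement map
  f_N(p) = p^N / (p^N + q^N). Implemented in this algebraic form rather than
  1/(1 + (1/p − 1)^N): the two are identical for p in (0,1) but the former
  needs no special-casing at the absorbing boundaries p = 0, 1.
* **Temporal autocorrelation.** Each iterate is built from the previous one
  plus a tiny fluctuation: p_{n+1} = f_N(p_n + ε_{n+1}), p_0 = 1/2 (the
  observer-free value, since f_0 ≡ 1/2). This is the stated condition for
  transitions: systems whose successive states are uncorrelated (strong
  restoring forces), or not fluctuating at all (ε ≡ 0), or unobserved
  (N = 0), or observed by a single observer (f_1 = identity, a neutral
  random walk), never leave the neighbourhood of 1/2 — all four regimes are
  exercised by the test suite.
* **Real amplitudes.** The path calculus uses real probability amplitudes
  (a, b) with a² = Prob(Pcb0), b² = Prob(Pcb1). Coherent (local assessment)
  combination squares the summed amplitudes; classical (remote assessment)
  combination sums the squared amplitudes. Complex amplitudes are out of
  scope — the model only ever uses real ones, including the sign device for
  the reverse-branch stable position, which we do not develop beyond its
  sign-free probabilities.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `n_observers` (N) | interacting observers | 2 | minimal team showing metastability |
| `p_direct` (p) | per-observer expectation of the direct relationship | 0.5 | symmetric prior; q = 1 − p |
| `d_param` (d) | independence parameter, d ∈ [0, pq] | 0 | fully independent expectations; d = pq recovers classical probability |
| `p0` | initial probability | 0.5 | observer-free value f_0(p) = 1/2 |
| fluctuation law | distribution of ε | uniform on ±0.5×10⁻¹⁵ | the reference simulations draw uniformly in this range; the alternative reading of that range as ±0.5 would contradict the stated \|ε\| ≪ 1. Distribution (uniform/gaussian) and scale are configurable; scales above 10⁻³ trigger a warning |
| `atol` | absorption tolerance | 10⁻¹² | near a boundary the iterates converge quadratically (q_{n+1} ≈ q_n² for N = 2), so the trajectory reaches any such neighbourhood within a few steps of the transition and the boundary itself is treated as the exact stable position; the final value is snapped to exactly 0 or 1, both invariant under the map |
| transition threshold | defines the "dramatic transition" step | 0.25 | halfway between the metastable point and either boundary; no numeric definition exists in the model, so this is a package choice |
| `alpha` | significance level of the exact test | 0.05 | convention |
| `background_rate`, `flip_noise` | spontaneous change in the untreated state; outcome misclassification | 0 | extensions for power curves, not part of the core model |

The valid domain of d is [0, pq] (not [0, 1]): the off-diagonal cells of the
two-observer joint table carry weight pq − d, which must be non-negative for
the table to be a probability distribution.

## Dynamics and ensembles

A perturbed probability p + ε falling outside [0, 1] is clamped to the
nearer boundary; this is only reachable within ε of a boundary, where the
state is already decided, and the boundary is absorbing. For N ≥ 2 the
deviation from 1/2 is amplified by ≈ N per step, so the transition completes
after roughly log_N(0.25/ε-scale) steps — about 50 for N = 2 at the 10⁻¹⁵
scale, at most ~65 across 2000 seeded runs — plus a handful of quadratic
steps to absorption.

Randomness uses numpy's Philox counter-based generator; trajectory i of an
ensemble is keyed `base_seed + i`, so ensembles are reproducible bit for bit
and individual trajectories can be regenerated in isolation. Ensemble
summaries report branch counts and the min/median/max absorption step; the
median (not the mean) is the sweep statistic because early near-cancelling
fluctuations give the step distribution a long right tail.

Designating `Pcb0` as the experimental control eliminates the
reverse-relationship branch: the control label cannot be associated both
with change (when its samples are tested) and with no change (the resting
state whose stability defines the control). This is implemented as
post-selection — zero-branch trajectories are discarded and counted — which
is the minimal reading; no modified (e.g. reflecting) update rule is
implied by the model, so none is implemented. An ensemble with no survivors
yields a flagged degenerate summary rather than an exception.

The branch-symmetry test treats 1/2 as the null hypothesis for the branch
proportion. The symmetry of the map and of the fluctuation law implies it,
but it is a null under test, not an assumed constant: the test is an exact
two-sided binomial test built from log-factorial point masses (summing
masses not exceeding the observed one, with a 1 + 10⁻⁷ relative guard
against rounding), with a 95% Clopper–Pearson interval.

## Virtual trials

Local mode realises the constrained stable position: every `Pcb1` sample
shows a change, every `Pcb0` sample does not; noise perturbations follow.
Remote mode takes the same outcome vector and permutes it across all 2n
samples — the most literal reading of changes being "randomly distributed"
across the placebos — preserving both arm sizes and the total number of
changes (which equals half the samples in the noise-free case; the remote
marginal rate is not pinned down by the model, and preserving the
local-mode total is our inference). An independent-Bernoulli(1/2) variant
is exposed (`remote_style="bernoulli"`) but is not the default.

Association is tested with a two-sided fixed-margin exact test: the first
cell is hypergeometric under the null Prob(↑|Pcb0) = Prob(↑|Pcb1); point
probabilities are computed with log-factorials and summed over tables as or
less probable than the observed one. An exact test keeps single-sample arms
valid (with arm sizes of 1 the smallest two-sided p is 1, so such trials can
never reject). An all-zero table returns the degenerate p-value 1.

`trial_power` runs paired local/remote trials over consecutive seeds. With
no noise the local rejection rate is 1 once arms hold ≥ 4 samples
(the smallest attainable p is 2/C(2n, n), below 0.05 from n = 4), while the remote rate estimates the
exact test's type-I error and stays at or below the nominal level (the test
is conservative). The local-minus-remote gap is the model's testable
signature.

## What the generator emulates — and what it does not

The synthetic trials emulate the model's own idealised conditions: binary
outcomes, equal arms, perfectly realised stable positions, and (optionally)
simple independent noise. They do not emulate real clinical data — no
covariates, no longitudinal structure, no dropout, no continuous endpoints,
no inter-site heterogeneity — so passing tests show internal consistency of
the model and the correctness of its implementation, not that real
two-placebo experiments behave this way. External trial datasets and their
re-analyses are explicitly out of scope; in particular the reported
local-vs-centralized interaction from a published plant-model experiment is
not a reproduction target at this scale.

## Numerical choices

* Fixed points are located by a dense-grid (2001-point) sign-change scan of
  f_N(p) − p with bisection refinement to 10⁻¹², rather than symbolically:
  this generalises to any N, and for every N ≥ 2 finds exactly
  {0, 1/2, 1}. Near-boundary roots are snapped onto the exact boundary.
* Stability is classified from a finite-difference derivative (central,
  step 10⁻⁵, one-sided at the boundaries; truncation error ≈ 8×10⁻¹⁰ at the
  midpoint): attracting below 1, repelling above, neutral within 10⁻⁹ of 1.
  The derivative magnitude at 1/2 equals N, confirmed for N = 2…6.
* At the metastable point the float64 update is exact for dyadic
  fluctuations (e.g. ε = 2⁻⁵¹ is doubled without any rounding); the
  linearized growth rate is additionally cross-checked against a 50-digit
  mpmath evaluation of the recurrence, since a decimal ε near 10⁻¹⁵ is
  itself quantized by binary floating point to within ~10% of its value.
* N-observer generalisation of d: the d-interpolation is defined (and
  exposed) for the two-observer geometry only; how d should enter for N > 2
  is not specified by the model, and we do not invent an extension.

## Problem sizes

The shipped tests and the acceptance script use the model's own reference
scales: 8-run and 2000-run ensembles at 200-step horizons, 200 runs per
sweep cell over N ∈ {2, 3, 4} × half-widths {0.5×10⁻¹⁵, 10⁻¹⁰, 10⁻⁵}, and
500 paired virtual trials with 20 samples per arm. The full suite completes
in a few seconds on one CPU.

## Known limitations

* The model is a hypothesis generator, not an estimator: nothing is fitted
  to data, and the package makes no claim about real placebo responses.
* Amplitudes are real and two-path only; no density matrices, Hilbert-space
  states, or agent-level modelling of the observers.
* The recurrence is discrete-time; no continuous-time or SDE reformulation,
  and no "elastic" (non-autocorrelated) system variants beyond the
  documented no-transition regimes.
* Remote-mode margins rest on the inference noted above; both realisations
  (margin-preserving permutation, independent Bernoulli) are provided so
  the choice is visible.
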