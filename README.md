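# placebosim

A simulator for a probabilistic model of how *two inert placebos, differing
only by their labels, can become associated with different biological
outcomes* — and of why that association should appear under local assessment
of a blind experiment yet vanish under remote (centralized) assessment.

The package is aimed at methodologists and modellers studying experimenter
effects, blind-trial design, and quantum-like probability outside physics.
It implements the model as tested, reproducible code: closed-form
probability and amplitude calculus, the stochastic fixed-point dynamics, Monte-Carlo
ensembles, and a virtual two-placebo trial generator with an exact 2×2 test.

## The model

An experiment with two placebo labels (`Pcb0`, `Pcb1`) and a binary outcome
(no change ↓ vs. change ↑) admits two pairings: the **direct** relationship
(`Pcb0`↔↓, `Pcb1`↔↑) and the **reverse** one. A team of *N* interacting
observers is described from the standpoint of an uninvolved participant:
each observer independently expects the direct relationship with probability
*p*, and intersubjective agreement discards joint configurations in which
observers disagree. Renormalising gives the agreement map

    f_N(p) = p^N / (p^N + q^N),   q = 1 − p,

equivalently 1 / (1 + (1/p − 1)^N). Its fixed points are 0, 1/2 and 1; the
derivative at 1/2 equals *N*, so for N ≥ 2 the observer-free value 1/2 is
**metastable**. Iterating the map with tiny random fluctuations ε (uniform
on ±0.5×10⁻¹⁵ by default),

    p_{n+1} = f_N(p_n + ε_{n+1}),   p_0 = 1/2,

drives every trajectory through a sharp transition into one of the
**absorbing** states 0 or 1 — each branch chosen with probability 1/2.
Designating `Pcb0` as the experimental control eliminates the reverse branch
(the control label cannot be associated both with change and with the
unchanged resting state), leaving Prob(direct) = 1.

Writing Prob(Pcb0) = a², Prob(Pcb1) = b², the direct-relationship
probability is `(a·a + b·b)²` when the label "paths" are indistinguishable
(**local** assessment — square of the summed amplitudes) but
`(a·a)² + (b·b)²` when a remote supervisor tags them (**remote** assessment
— sum of squared amplitudes). At a = b = 1/√2 these give 1 and 1/2: a
perfectly separated 2×2 table locally, a null association remotely. A
covariance-like parameter *d* ∈ [0, pq] interpolates between the fully
independent-observer regime (d = 0) and classical probability
(d = pq, where the two-observer probability reduces to *p*).

## Worked example

```python
from placebosim import (ModelParams, run_ensemble, branch_symmetry_test,
                        TrialConfig, simulate_trial, trial_power)

summary = run_ensemble(ModelParams(), n_runs=2000, max_steps=200, base_seed=0)
print(summary.n_absorbed_one, summary.n_absorbed_zero,
      summary.step_median, summary.step_max)
# 1000 1000 55.0 65

test = branch_symmetry_test(summary)
print(test.proportion, test.p_value)
# 0.5 1.0

local = simulate_trial(TrialConfig(n_per_arm=20, assessment="local", seed=7))
print(local.table.tolist(), local.p_value, local.relationship_called)
# [[20, 0], [0, 20]] 1.45e-11 direct

remote = simulate_trial(TrialConfig(n_per_arm=20, assessment="remote", seed=7))
print(remote.table.tolist(), remote.p_value, remote.relationship_called)
# [[7, 13], [13, 7]] 0.113 none

power = trial_power(TrialConfig(n_per_arm=20, seed=0), n_sims=500)
print(power.rejection_rate_local, power.rejection_rate_remote)
# 1.0 0.026
```

All 2000 trajectories are absorbed within 200 steps (median 55), split
exactly 1000/1000 between the two branches here (exact binomial p = 1).
Under local assessment the virtual trial is perfectly separated (exact-test
p ≈ 1.5×10⁻¹¹, relationship called "direct"); under remote assessment the
same number of ↑ outcomes scatters across arms and the association
disappears (p = 0.113). Over 500 paired trials the local design rejects the
null every time while the remote design rejects at 2.6% — within the 5%
nominal level of the exact test.

The same runs are available from the shell:

```sh
placebosim trajectory --N 2 --seed 1 --steps 200 --out results/
placebosim ensemble --N 2 --runs 2000 --steps 200 --seed 0 --out results/
placebosim fixed-points --N 2 --out results/
placebosim trial --mode local --n 20 --seed 7 --out results/
placebosim sweep --N-values 2,3,4 --widths 0.5e-15,1e-10,1e-5 --out results/
```

Every subcommand writes its CSV/JSON artifact plus a run manifest (resolved
configuration, seed, package version); feeding a manifest back through
`--config` reproduces the payload byte for byte.

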