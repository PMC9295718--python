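# Methods

## Model and assumptions

The simulator is a deterministic-skeleton stochastic stock-flow model in
discrete daily time. Its behavioral assumptions:

* **Cybernetic stress regulation.** Employees compare perceived challenge
  stress (an identity map of the stressor stock) with the maximum stress
  they are willing to accept (*E_s*). Above that expectation the full gap
  drives appraisal, strain and coping; between zero and the expectation
  only half the (negative) gap drives coping, via `exp(disc)`, modeling
  reduced motivation; once the stressor is eliminated all three channels
  shut off.
* **Opponent process.** Job satisfaction is pulled back toward an
  equilibrium level *L* at rate *r* per day, so affect displacements are
  transient. Under unit-step Euler this yields the exact geometric decay
  J(t) − L = (J₀ − L)(1 − r)^t, which the tests assert bitwise for
  r = 0.5 (binary-exact arithmetic).
* **Social exchange with a ratchet.** OCB arises only while satisfaction
  exceeds the expected satisfaction stock, and every unit of OCB raises
  that expectation by *x* per day. The expectation never decays, so
  sustained OCB is self-limiting by construction.
* **Limited daily resources with coping priority.** The resource stock
  integrates restored minus consumed resources. When it is negative the
  coping weight rises (bounded by twice its base) and the OCB weight
  falls toward zero — in-role coping is prioritized over discretionary
  OCB under scarcity. Both weights are continuous at a zero balance.

Within each Euler step all auxiliaries are evaluated from the current
stocks in dependency order (the within-step graph is acyclic), then every
stock is advanced by Δt times its net flow. The trajectory stores
steps + 1 records; the last carries a terminal auxiliary evaluation of
the final stocks (consuming one extra random draw) so each stored state
has a matching auxiliary row. Cumulative OCB is the left Riemann sum over
the first `steps` records, consistent with flow semantics.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| S₀ | 2.71 | stressor | initial stressor (published scale mean); 0 in task-assignment mode |
| E_s | 0 | stressor | maximum acceptable challenge stress (2 in the revised scenario) |
| L | 0 | satisfaction | equilibrium job satisfaction (4 in conditions 1–2) |
| r | 0.5 | 1/day | opponent-process rate |
| c_a | 0.23 | — | challenge-appraisal importance (0.4 / 0.2 in conditions) |
| c_s | 0.29 | — | strain importance |
| w_c0 | 0.29 | — | base coping importance |
| w_o0 | 0.2 | — | base OCB importance |
| x | 0.51 | — | exchange orientation |
| E_J₀ | 0 | satisfaction | initial expected satisfaction (2 in conditions) |
| W | 0 | stressor | workload delivered per new-task pulse |
| f | 0 | pulses/100 days | new-task frequency; period 100/f, pulses start at day 1 |

The importance parameters are correlation coefficients from prior
empirical studies, used as fixed weights. "Resource" units are an
abstract daily budget: restored resources ~ U(0, 2) per day and other
activities ~ U(0, 1) per day, redrawn every step; mean mode substitutes
the exact means (1.0, 0.5) for deterministic runs. The third argument
printed with the uniform random calls in the originating modeling tool is
a legacy stream token, not a distribution parameter; seeding here is
engine-level (NumPy `default_rng`, accepting ints or tuples).

## Randomness and reproducibility

A run is bit-reproducible from (parameters, grid, mode, seed). Grid
experiments derive one stream per (workload, frequency, replicate) cell
from `SeedSequence((base_seed, round(W·1e6), round(f·1e6), replicate))`,
so cells are independent of execution order, and the whole grid is
simulated as one vectorized batch stepping every cell's stocks together
through the same elementwise equations as the scalar stepper (a test pins
batch ≡ scalar per cell).

Whether the study's published curves are single stochastic runs or
representative summaries is not stated; both entry points are provided
(seeded stochastic mode and mean mode), and deterministic regression
tests use mean mode.

## Numerical choices

* Euler only, Δt = 1 day by default; the grid validates that the horizon
  is an integer number of steps. No adaptive integration.
* Pulse windows are computed in continuous time (`100/f` is often
  non-integer) and sampled at grid points; each one-day window contains
  exactly one unit grid point, so a frequency-f train delivers one
  increment per pulse. The train switches off at t = 100, so f = 100
  yields pulses on days 1–99.
* Branch boundaries are strict (`> 0`) as in the defining equations; the
  coping and importance functions are continuous across their branch
  points, so boundary choice does not create jumps.
* Non-finite intermediates abort integration with an error naming the
  offending variable and step.
* Tidy CSVs write floats with shortest round-tripping repr and are read
  back with round-trip parsing, so write→read→write is byte-identical.

## Shape classification

Curve labels are made reproducible by run-length-encoding the signs of
consecutive differences (|Δ| ≤ 1e−6 counts as a plateau and merges into
the adjacent run): `flat_zero` (max ≤ tol), `monotone_decline` ("−" from
a positive start), `inverted_U` ("+−" from a zero start), `M_shape`
("+−+−"), `inverted_N` ("−+−" from a positive start), else `other`.
`first_zero_day` reports 1-based day indices (t = 0 is day 1, matching
the convention that baseline coping first reaches zero "on the fourth
day").

Two caveats, both properties of the model rather than of the classifier:

* **The M-shaped regime needs stochastic resources.** Under mean-mode
  resources, condition 1 with any initial stressor ≥ 1 consumes more
  than the mean restored rate on day one (coping ≥ 0.58 + OCB 0.204 +
  other 0.5 > 1.0), so the resource balance goes negative immediately,
  the OCB weight drops, and OCB falls at step 1. Deterministic
  condition-1 curves are therefore always fall–rise–fall (`inverted_N`
  by the rule above) with a valley that deepens and lengthens as S₀
  grows. An early *rising* OCB segment — the first peak of a true
  rise–fall–rise–fall "M" — occurs only when early random draws leave a
  resource surplus (probability ≈ 0.14 on day one at S₀ = 3), so
  M-labeled curves are a feature of individual stochastic runs at small
  S₀, not of the mean dynamics.
* **The condition-3 workload threshold is almost-sure, not sure.** With
  equilibrium satisfaction below its expectation, new tasks of workload
  ≤ 4 essentially never lift satisfaction above expectation — but at
  workload 4 and high frequency, rare resource streams let satisfaction
  graze its expectation, producing trace accumulations on the order of
  1e−3 OCB-days per 100 days in roughly one replicate per several
  hundred. Reported thresholds from stochastic grids can therefore
  flicker between 4 and 5 at trace level.
* The boundary S₀ = 6–7 between the small- and large-stressor regimes in
  condition 1 is not labeled by the narrative the presets come from; the
  classifier simply reports what the rule yields there.

## Synthetic-data scope

There is no external data: the model itself generates all trajectories,
and the only stochastic elements are the two daily uniform resource
draws. Mean mode removes them; passing deterministic tests therefore
validates the equation set and integrator, not the distributional
assumptions. The pulse-train experiments assume perfectly periodic task
assignment with fixed workload — deliberately stylized; irregular
real-world task arrival is out of scope.

## Problem sizes

Default experiment sizes: 100-day horizon at Δt = 1; condition sweeps
over S₀ ∈ {1..18} ∪ {2.71}; grids over workload 1–8 × frequency 1–100
with 20 seed replicates per cell (16,000 runs, vectorized, ~1 s). The
acceptance script uses 100 seeds for baseline statistics and 40 fuzzed
scenarios for the condition-4 impossibility check.

## Known limitations

Only the reciprocity motive for OCB is modeled; hindrance stressors,
alternative motivation mechanisms, parameter estimation from empirical
data, and non-periodic task schedules are out of scope. Parameters are
point values from prior literature, not fitted quantities; the model's
claims are qualitative (shapes, thresholds, orderings), not calibrated
magnitudes.
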