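# Methods

## Model summary and assumptions

The simulator couples a micro model (heterogeneous fuzzy agents) and a
macro model (an institutional stock-flow system) in a staged loop.
Assumptions baked into the implementation:

- Each linguistic variable has exactly three terms (Low/Medium/High)
  with triangular membership functions sharing breakpoints b < c < d.
  This yields a partition of unity: the three degrees of any base value
  sum to 1, which the clustering and inference layers exploit.
  Trapezoidal or bell shapes are a deliberate non-goal.
- Exactly two linguistic variables are supported per scenario, mapped
  one-to-one onto the two capacity stocks (COASF, CSSHF). Scenarios with
  a different count are rejected at validation.
- The base signal per variable is *shared* across agents (the realised
  stock value); heterogeneity enters only through the per-agent
  membership constants.
- Peer influence acts only on the Low term: targeting scarce resources
  at the worst-off makes Low membership the operative quantity, and the
  socially negotiated value is a shadow variable that the next
  perception step overwrites. This replacement semantics (rather than
  letting social updates persist) is a genuine design choice and the
  main sensitivity point of the agent layer: with persistence, peer
  consensus would accumulate across periods instead of being re-anchored
  by the intervention each period.

## Parameters

| parameter | meaning | units | default (small preset) |
|---|---|---|---|
| n | agents | count | 50 |
| b̄, c̄, d̄ | mean membership constants | base-variable units | 2, 5, 8 |
| σ_b, σ_c, σ_d | constant spread | base-variable units | 0.3 |
| k | contacts per agent per time unit | count | 3 (cap 5) |
| q | scale-free degree exponent | – | 2.5, restricted to (2, 3) |
| C | initial investment fund | currency | 300 |
| d₁, d₂ | capacity lifetimes | time units | 10 |
| d₃ | investment delay | time units | 2 |
| p | allocation fraction to COASF | – | 0.5, adaptive |
| dt | Euler step | time units | 1/16 |
| τ_len | time units per stage | count | 5 |
| max stages / threshold | stop conditions | – | 10 / 0.9 |

The fund C = 300 with lifetimes 10 and delay 2 is sized to be *adequate*:
sustained investment pushes both stocks far past the upper perception
threshold d, so homogenisation expresses the model's feedback structure
rather than a knife-edge. With C = 0 the stocks decay exponentially with
their lifetimes and agent memberships follow the declining-path closed
forms — the engine tests cross-check this against the trajectory module.

## Numerical choices

- **Integration**: explicit Euler with dt = 1/16 time unit, guarded by
  dt ≤ min(d₁, d₂, d₃)/4 so decay terms cannot overshoot. For frozen
  controller output z the fund obeys dρ/dt = −zρ/d₃ exactly, giving
  ρ(t) = C·e^(−zt/d₃); the integrator is validated against this closed
  form (error halves when dt halves, as first order demands). The spend
  rate is truncated at ρ/dt so the fund cannot go negative.
- **Mamdani operators**: conjunction = min, implication = clipping
  (min), aggregation = pointwise max, defuzzification = centre of
  gravity by trapezoidal quadrature on a 1,001-point grid over [0, 1].
  Consequent terms are the symmetric partition Low = tri(0, 0, 0.5),
  Medium = tri(0, 0.5, 1), High = tri(0.5, 1, 1), whose analytic
  centroids (1/6, 1/2, 5/6) anchor the quadrature tests. If no rule
  fires (identically zero aggregate) the controller holds its previous
  output (0 at start) and logs a warning, since the centroid is
  undefined.
- **Constant sampling**: B, C, D are drawn independently per agent and
  the whole triple is rejection-resampled (≤1,000 rounds) until
  0 < b < c < d; sorting was rejected because it distorts the stated
  marginals more aggressively.
- **Binning**: bin 0 requires |μ| ≤ 1e-12 so floating-point dust does
  not register as resource demand; the interval edges (m−1)/10 < μ ≤
  m/10 are evaluated as ceil(10μ − 1e-9) to honour closed upper
  endpoints under rounding (0.1 → bin 1, 0.1 + ε → bin 2).
- **Pair processing** within an interaction round is sequential in a
  randomised order (later pairs see earlier updates), matching the
  left-to-right form of the min/max update equations; seeding fixes the
  order, so runs are bit-reproducible.
- **Realistic weights**: the model only constrains φ_i < ω_i when the
  peer's constant is larger; we use ω_i = b_r/(b_i + b_r) per variable,
  the simplest symmetric convention with that property, reducing to
  0.5/0.5 for equal constants. The peer's weights are derived
  independently from its own perspective.
- **Scale-free contacts**: configuration model on degrees drawn from
  P(deg) ∝ deg^(−q), minimum degree 1, collapsed to a simple graph
  (self-loops and parallel edges dropped). Collapsing slightly truncates
  hub degrees but preserves the tail: a discrete maximum-likelihood fit
  on a 5,000-node graph recovers the generating exponent. Each time unit
  an agent activates at most k incident edges.
- **Degenerate inputs**: a fund of 0 is allowed (pure-decay scenarios);
  breakpoints that fall outside the horizon are reported but flagged
  uncrossed; derivative signs are reported only on open intervals inside
  one regime, because the trajectories kink at the breakpoints.

## Trajectory analytics as oracle

The module `trajectories` implements the per-regime closed forms of the
membership paths under linear and exponential declines directly, not by
composing the static membership function with the base path. Equality of
the two routes at 1,000 grid points (to 1e-12) is therefore a real
consistency check, and the analytic derivative signs (linear: affine
segments, zero curvature; exponential: Low rising concave-down, High
falling concave-up) are verified against central finite differences.

## What the scenario generator emulates — and what it does not

The built-in presets emulate the study conditions of a two-capacity
community intervention: normally distributed perception constants,
random or scale-free contact, adequate funding, stage-lagged adaptive
allocation. They do **not** emulate real survey-calibrated membership
constants, empirically measured contact networks, fund replenishment, or
any behavioural response beyond the three stylised inference rules.
Passing tests therefore demonstrate internal consistency of the model's
mathematics and the qualitative feedback behaviour (capacity growth →
membership collapse → homogenisation), not predictive validity for any
real intervention.

## Problem sizes

The default test run uses 50-agent scenarios over ≤10 stages of 5 time
units (16 Euler sub-steps per unit) and a 1,000-agent scenario for the
paper-like preset; the stochastic homogenisation check runs the small
scenario across 20 seeds. These sizes keep the full suite under a few
seconds while leaving every mechanism (controller saturation, fund
draw-down, membership fans, binning feedback) active.

## Known limitations

- The allocation feedback formula (mean Low membership of non-zero-bin
  agents, needs normalised into p) is one reasonable monotone choice; the
  framework does not prescribe a unique form, and need could plausibly
  scale with bin depth.
- Homogenisation is driven by the shared signal exceeding every agent's
  c constant; scenarios whose funds cannot reach that regime will cycle
  at the max-stage cap.
- Perception is instantaneous (the institution fuzzifies current stocks;
  agents read current stocks); no perception smoothing or extra delay
  beyond d₃ is modelled.
- Takagi–Sugeno inference, >2 stocks, optimisation of allocations and
  live-data ingestion are out of scope.
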