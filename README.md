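# fuzzyhybrid

A hybrid fuzzy agent-based / system-dynamics simulator for the
implementation of health interventions. It targets implementation
researchers and policy modellers who want to study how an institution's
resource-allocation decisions interact with a heterogeneous population's
*perceptions* of those interventions — for example, building outdoor
activity spaces and healthy-food stores in a community and watching
perceived adequacy converge.

## Model

Every agent *i* perceives each intervention outcome *x<sub>j</sub>(t)*
through a personal **linguistic variable** with terms {Low, Medium, High}
defined by triangular membership functions with agent-specific constants
0 < b<sub>ij</sub> < c<sub>ij</sub> < d<sub>ij</sub>:

```
μ_Low(x)  = 1 on [0,b];  (c−x)/(c−b) on [b,c];  0 beyond
μ_Med(x)  = (x−b)/(c−b) on [b,c];  (d−x)/(d−c) on [c,d];  0 beyond
μ_High(x) = (x−c)/(d−c) on [c,d];  1 on [d,∞);  0 below
```

The shared breakpoints make the three degrees sum to 1 for every x ≥ 0.
The constants are drawn per agent from normal distributions
B ~ N(b̄, σ_b²), C ~ N(c̄, σ_c²), D ~ N(d̄, σ_d²) (rejection-sampled to
respect the ordering), so a common signal produces a *fan* of
heterogeneous memberships.

Three dynamics run each time unit, in order:

1. **Institutional intervention.** A stock-flow model maintains two
   capacities, COASF (safe outdoor activity space and facilities, s₁)
   and CSSHF (stores serving healthy food, s₂), with inflows
   φ₁ = ω·p, φ₂ = ω·(1−p) and decay outflows λ_k = s_k/d_k. The spend
   rate ω = z_COG · ρ / d₃ draws down a fixed fund ρ(0) = C, where z_COG
   is produced by a **Mamdani fuzzy controller**: the institution
   fuzzifies its perceived stocks, fires a 9-rule base
   (COASF-term × CSSHF-term → impact term) by min-conjunction, clips and
   max-aggregates the consequents on z ∈ [0,1], and defuzzifies by
   centre of gravity z_COG = ∫zμ(z)dz / ∫μ(z)dz.
2. **Perception.** Agents read the updated stocks as their base values
   and recompute memberships.
3. **Peer influence.** Agents contact k peers (uniformly at random or on
   a scale-free network with degree law P(k) ~ k^(−q), 2 < q < 3) and
   renegotiate the *Low* membership only — the term that signals unmet
   need — by a pessimistic (min), optimistic (max) or realistic
   (constants-weighted mean) rule.

After each stage (a block of time units) agents are binned by Low
membership into the intervals 0, (0,0.1], …, (0.9,1.0]; the mean Low
membership of the agents outside bin 0 is each variable's unmet *need*,
and the normalised needs set the next stage's allocation fraction p. The
run stops when the bin-0 fraction reaches the homogenisation threshold —
the population no longer registers unmet need.

## Worked example

```
$ fuzzyhybrid demo --preset small --seed 7 --out demo_out
stages=1 homogenization=1.000 invested=260.00
  agents: demo_out/agents.csv
  sd_trace: demo_out/sd_trace.csv
  summary: demo_out/summary.json
  scenario: demo_out/scenario.yaml
```

The small preset simulates 50 agents, two linguistic variables with
constants (b̄, c̄, d̄) = (2, 5, 8) and σ = 0.3, a fund C = 300, capacity
lifetimes d₁ = d₂ = 10, investment delay d₃ = 2, and 5 time units per
stage. The run above homogenises within one stage: the controller starts
at z_COG ≈ 1/6 (both stocks perceived Low) and spends ω ≈ 25 per time
unit, the stocks climb past every agent's upper constant d, all Low
memberships collapse to 0 (`homogenization=1.000`), and 260.00 of the 300
fund was invested. `sd_trace.csv` records the stock/flow trajectory per
integration step; `agents.csv` records each agent's base value,
geometric and socially updated Low membership, Medium/High memberships
and cluster bin per time unit.

The same scenario can be edited as YAML and re-run:

```
fuzzyhybrid run --config demo_out/scenario.yaml --seed 11 --out out2
fuzzyhybrid validate --config demo_out/scenario.yaml
```

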