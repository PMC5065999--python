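# Methods

## Model

A discrete-time Markov cohort model with 3-month cycles follows a cohort of
moderate-to-severe, corticosteroid-dependent ulcerative colitis patients who
have failed or cannot tolerate thiopurines. Two management strategies are
compared:

- **no-adalimumab arm** — biologic therapy unavailable; the cohort starts
  100% in *Unwell on steroids* and can progress to steroid complications,
  colectomy, post-surgical response, surgical complications, chronic
  pouchitis and its sub-model, or death;
- **adalimumab arm** — the cohort starts 100% in a 3-month *induction*
  state; responders enter a maintenance state whose stay-probability follows
  a real-life retention series, non-responders and those losing response
  return to the unwell-on-steroids pathway.

States carry a cost per cycle (CA$, physician + hospital + outpatient drug)
and an annual utility weight in [0, 1]. QALYs accrue as
`utility × 0.25` per cycle of occupancy. Membership is counted at cycle
start; no half-cycle correction is applied. Costs and QALYs are discounted
at 5% per year with the cycle-start factor `1.05^(−0.25·k)`. Death carries
no recurring cost or utility, but the transition into death is charged once
with the predecessor state's per-cycle cost, discounted at the arrival
cycle. A horizon of `H` cycles accrues cycles `0 … H−1`.

### Transition rows and the complement entry

Each non-absorbing state has one outgoing row whose entries are either fixed
percentages (as printed in the input tables, with optional 95% CIs), a
retention-series reference, or the row's unique complement `"#"`, which
absorbs the remaining probability so every resolved row sums to exactly 1.
Rows whose fixed entries alone exceed 100% are rejected at validation.

### Retention series and clocks

Maintenance of response is time-varying: a retention series gives the
probability (%) of remaining in response at cycles 0–20, with the cycle-20
value held as a plateau thereafter. Series values are used **directly as
per-cycle maintenance probabilities**. The series clock for the primary
response state is `model cycle − 1` (response begins after the one-cycle
induction); for states that can be entered at any time (the pouchitis
response state), the clock is time-in-state, implemented by expanding the
state into 21 tunnel copies. A series referenced with the `entry` role (the
chronic-pouchitis → pouchitis-response transition) contributes its cycle-0
value, i.e. the induction response probability, at every cycle.

An alternative reading of such series — cumulative survival points converted
to conditional per-cycle retention `S(k+1)/S(k)` — is implemented
(`retention_to_conditional`, `retention_mode: conditional`) but is not used
by the fixtures: conditional ratios approach 1 at the plateau and, combined
with the response row's fixed 7.88% complication exit, would force a
negative loss-of-response complement; they also produce a far slower loss of
response than the published series describes. The per-cycle reading keeps
every row feasible at every cycle and reproduces the published totals.

Where a series value would still exceed the mass left by a row's fixed
entries (the dose-escalated series starts at 93.8% next to a fixed 7.88%
complication exit), fixed exits take precedence as competing risks and the
maintenance probability is capped at `1 − Σ fixed`; the engine additionally
resolves rows lazily, so rows of unoccupied states are never resolved at
cycles where they cannot apply.

The pouchitis retention series for the adalimumab arm is the anti-TNF-naive
series discounted by 15% (prior biologic exposure reduces response), with
values rounded half-up to one decimal — `apply_retention_discount`
reproduces the shipped series exactly at all 21 cycles.

## Scenarios

- **Utility variant.** The response-to-adalimumab utility was elicited two
  ways — 0.79 (time trade-off) and 0.82 (visual rating scale). The variant
  substitutes the primary response state's utility only; the pouchitis
  response state keeps its own printed utility (0.58).
- **Dose escalation.** Roughly half of maintained UC patients require
  escalation to weekly 40 mg dosing, after a mean 59.3 (±70.5) weeks (≈
  cycle 5; the rounding helper is provided, and the mean/SD are kept as
  policy metadata). Because the escalated retention series is itself
  measured on an escalation-managed population, the scenario is applied
  structurally from treatment start: the response state's retention follows
  the Crohn's-derived dose-escalated series, and its cost is re-priced at
  weekly dosing — standard cost plus six additional 40 mg doses per cycle at
  $740.36 each ($4,442 → $8,884.16). A one-time mid-simulation transfer of
  responders was evaluated and discarded: response occupancy is nearly
  exhausted by cycle 5, so the policy would have almost no cost consequence,
  contradicting the roughly doubled published scenario ICERs.
- **Dose de-escalation.** De-escalation is attempted in 54% of escalated
  responders and succeeds in 63% of attempts; the effective 34.02% return to
  standard-dose pricing while retention is unchanged (de-escalation succeeds
  precisely in those who keep responding). In a cohort model this is exactly
  a blended response-state cost, applied from scenario start.

## Sensitivity analyses

**One-way.** Every uncertain input is varied alone: costs ±25%,
probabilities across their printed 95% CI (±25% relative where no CI is
printed), utilities ± their printed half-width clipped to [0, 1]. A
probability's upper bound is additionally clipped so its row's complement
stays non-negative. Parameters shared by both arms move together; a
probability whose base value differs by arm (the pouchitis complication
row) moves to each arm's own bound. Entries are ranked by ICER spread
(tornado order); the response state with no printed utility interval uses
±0.21, the half-width printed for the identical time-trade-off utility of
the steroid-response state.

**Probabilistic.** Costs are sampled from normal distributions truncated at
0 with `SD = 0.25 × mean / 1.96`; utilities ≥ 0.4 from moment-matched beta
distributions with `SD = half-width / 1.96`; utilities < 0.4 are transformed
to decrements `1 − u` and sampled from moment-matched gammas (samples
clipped to [0, 1]). Transition probabilities stay fixed, so each arm's
cohort trace is computed once and each draw re-prices it via discounted
occupancy weights — 10,000 draws run in well under a second. Each arm's
parameters are drawn **independently** (no common random numbers): with
shared draws the acceptability curve rises far too steeply, whereas
independent arms reproduce the published plateau (≈ 30% of draws show no
QALY gain, bounding the curve near 60%). The default draw count is 10,000
and a seed is mandatory.

**CEAC.** For each willingness-to-pay λ, the probability that adalimumab is
cost-effective is the fraction of draws with `λ·ΔQALY − ΔCost > 0`.

## Synthetic models and the microsimulation oracle

The generator draws random state graphs (Dirichlet row probabilities with
the largest entry as complement, every alive state keeping an edge to death,
optional residence-clock states with random non-increasing retention series)
inside the cost ($0–$37,159/cycle) and utility (0.16–0.82) ranges of the UC
fixtures, and is deterministic given its seed. The microsimulation walks
individual patients through the same resolved per-cycle probabilities,
charging costs, utilities and the one-time death cost per trajectory. Cohort
trace and microsimulation are independent estimators of the same
expectation; tests require agreement within 3 Monte-Carlo standard errors on
both fixture arms (100,000 patients) and, family-wise, across 25 random
models (at most one z-score in 50 beyond 3, none beyond 4.5).

The generator exercises structural validity, conservation, and accounting —
it does not emulate disease-specific features (no literature-weighted
probabilities, no clinically meaningful graph shapes), so passing synthetic
tests demonstrates the engine's correctness, not the UC model's clinical
validity.

## Problem sizes and numerical conventions

Horizons are 20/40/60 cycles on ~19 collapsed states (39 after tunnel
expansion); a full arm evaluation is a few milliseconds, the complete
tornado a few seconds, the 10,000-draw PSA under a second, and the 100,000
patient microsimulation under a minute. Resolved rows sum to 1 within 1e-12
and trace rows within 1e-10. Reported dollar figures are rounded to the
nearest $1,000 and QALYs to three decimals. The retention-discount rounding
is decimal half-up (banker's rounding on binary floats would drop the 39.95
→ 40.0 case).

## Known limitations

- The state-graph wiring is reconstructed from transition tables and prose;
  a published structure figure was not machine-readable. Two states
  (*Ongoing steroids*, *Response to steroids*) have no inbound edges under
  this reconstruction and carry no cohort mass; they are retained in the
  fixtures and flagged in the model dump's audit block.
- The no-adalimumab arm's pouchitis sub-model treats refractory pouchitis
  with adalimumab even though the arm is defined by its unavailability; the
  source tables specify exactly this and it is implemented as printed.
- No background (age/sex-specific) mortality; death arises only through the
  modelled complication pathways.
- No concomitant-therapy modelling, no indirect or societal costs, no
  currency conversion, and no switching between anti-TNF agents.
- The escalated-dose price and the de-escalation timing are modelling
  choices (documented above) — the one-way cost interval (±25%) is the
  instrument for exploring them.
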