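# uccea

Markov cohort cost-utility analysis of adalimumab availability in
moderate-to-severe ulcerative colitis (UC).

Patients who are corticosteroid-dependent and have failed thiopurines face a
stark choice when biologic therapy is unavailable: colectomy, or remaining
chronically unwell on medical therapy. Many choose the latter. This package
models that comparison as a discrete-time Markov cohort: one arm stays in a
chronically unwell state (with steroid complications, eventual colectomy, and
its sequelae — including chronic pouchitis — as downstream states), the other
receives adalimumab induction (160/80 mg, then 40 mg every other week) with
real-life, time-varying maintenance-of-response probabilities. The model
prices each 3-month cycle in CA$, weights each cycle by health-state utility,
and reports the incremental cost-effectiveness ratio (ICER),

```
ICER = (C_ada − C_no_ada) / (Q_ada − Q_no_ada)    [CA$ per QALY gained]
```

with costs and QALYs discounted at 5% per year over 5-, 10-, or 15-year
horizons. Around the base case it provides:

- **One-way (tornado) sensitivity analysis** — probabilities across their 95%
  CIs, costs ±25%, utilities ± their interval half-widths;
- **Probabilistic sensitivity analysis** — normal costs, beta utilities
  (gamma on the decrement `1 − u` for utilities near 0), 10,000 seeded draws;
- **Cost-effectiveness acceptability curves** — P(net monetary benefit > 0)
  across willingness-to-pay thresholds;
- **Dose-escalation / de-escalation scenarios** — weekly 40 mg dosing with
  Crohn's-derived retention, and partial return to standard-dose pricing;
- A **synthetic-model generator** and a per-patient **microsimulation
  oracle**, so the cohort engine and the economic accounting can be validated
  on arbitrary random state graphs, independently of the UC fixtures.

The model structure (states, transition rows with complement entries,
cycle-indexed retention series, tunnel states for residence-time clocks) is
declared in YAML; the four shipped fixtures (`uc_no_ada`, `uc_ada`,
`uc_ada_escalation`, `uc_ada_deescalation`) contain every input value.

## Worked example

The 10-year base case, with the response-to-adalimumab utility at its
time-trade-off value 0.79:

```sh
$ uccea icer --horizon 10 --utility 0.79
{
  "horizon_years": 10,
  "utility": 0.79,
  "scenario": "base",
  "no_ada": { "cost": 102661.09684755573, "qalys": 3.1733738852491804 },
  "ada":    { "cost": 118860.06391521386, "qalys": 3.4448347850500034 },
  "delta_cost": 16198.96706765813,
  "delta_qalys": 0.271460899800823,
  "icer": 59673.29762608051,
  "icer_rounded_to_1000": 60000.0,
  "label": "ratio"
}
```

Reading: a patient without access to adalimumab accrues ≈ $103,000 in
discounted costs and 3.173 QALYs over ten years; with adalimumab available,
≈ $119,000 and 3.445 QALYs. The extra $16,199 buys 0.271 extra QALYs, i.e.
≈ $60,000 per QALY gained — below an $80,000 willingness-to-pay threshold
but above the classical $50,000 one. The same comparison from Python:

```python
from uccea import AnalysisRequest, run_analysis

res = run_analysis(AnalysisRequest(horizon_cycles=40, response_utility=0.79))
print(res.icer.rounded_icer)   # 60000.0
```

Other subcommands: `uccea run` (one arm), `uccea dsa` (tornado table),
`uccea psa` / `uccea ceac` (probabilistic analysis; always seeded),
`uccea table1` (horizon × utility ICER grid with one-way ranges),
`uccea synth` / `uccea oracle` (random models and the microsimulation
cross-check). Scenario variants are selected with
`--scenario escalation|deescalation`.

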