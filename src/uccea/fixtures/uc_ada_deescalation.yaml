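# Dose de-escalation scenario: as the escalation scenario, but the fraction
# of escalated responders in whom de-escalation is attempted (54%) and
# succeeds (63%) returns to standard-dose pricing.
name: uc_ada_deescalation
cycle_length_years: 0.25
annual_discount_rate: 0.05
horizon_cycles: 40
retention_mode: per_cycle
initial_distribution:
  ada_induction: 1.0
series:
  ada_maintenance:
    values:
    - 86.8
    - 73.3
    - 66.5
    - 62.0
    - 58.7
    - 56.2
    - 54.1
    - 52.4
    - 50.9
    - 49.6
    - 48.5
    - 47.5
    - 46.5
    - 45.7
    - 45.0
    - 44.3
    - 43.6
    - 43.0
    - 42.4
    - 41.9
    - 41.4
  pouchitis_exposed:
    values:
    - 53.2
    - 52.0
    - 50.9
    - 49.8
    - 48.7
    - 47.7
    - 46.7
    - 45.6
    - 44.6
    - 43.7
    - 42.8
    - 41.8
    - 40.9
    - 40.0
    - 39.1
    - 38.3
    - 37.4
    - 36.6
    - 35.8
    - 35.0
    - 34.2
  dose_escalated:
    values:
    - 93.8
    - 80.5
    - 73.7
    - 69.1
    - 65.8
    - 63.2
    - 61.1
    - 59.4
    - 57.8
    - 56.5
    - 55.3
    - 54.3
    - 53.3
    - 52.5
    - 51.7
    - 51.0
    - 50.3
    - 49.7
    - 49.1
    - 48.5
    - 48.0
states:
- id: ongoing_steroids
  label: Ongoing steroids
  cost_per_cycle: 917.0
  annual_utility: 0.32
  cost_uncertainty: 0.25
  utility_halfwidth: 0.31
  transitions:
  - to: steroid_response
    p: 33.92
    ci:
    - 28.09
    - 40.33
  - to: unwell_steroids
    p: 57.11
    ci:
    - 50.5
    - 63.27
  - to: steroid_complication
    p: 2.8
    ci:
    - 0.56
    - 7.63
  - to: surgery
    p: '#'
- id: steroid_response
  label: Response to steroids
  cost_per_cycle: 0.0
  annual_utility: 0.79
  cost_uncertainty: 0.25
  utility_halfwidth: 0.21
  transitions:
  - to: steroid_response
    p: 53.3
    ci:
    - 46.81
    - 59.67
  - to: unwell_steroids
    p: '#'
- id: unwell_steroids
  label: Unwell on steroids
  cost_per_cycle: 917.0
  annual_utility: 0.32
  cost_uncertainty: 0.25
  utility_halfwidth: 0.31
  transitions:
  - to: unwell_steroids
    p: '#'
  - to: steroid_complication
    p: 2.8
    ci:
    - 0.56
    - 7.63
  - to: surgery
    p: 10.0
    ci:
    - 6.4
    - 14.28
- id: steroid_complication
  label: Steroid complication
  cost_per_cycle: 23919.0
  annual_utility: 0.16
  cost_uncertainty: 0.25
  utility_halfwidth: 0.16
  transitions:
  - to: surgery
    p: 98.0
    ci:
    - 93.7
    - 99.78
  - to: death
    p: '#'
- id: surgery
  label: Surgery (colectomy)
  cost_per_cycle: 37159.0
  annual_utility: 0.16
  cost_uncertainty: 0.25
  utility_halfwidth: 0.16
  transitions:
  - to: surgery_response
    p: '#'
  - to: surgical_complication
    p: 12.8
    ci:
    - 8.76
    - 17.91
  - to: death
    p: 2.5
    ci:
    - 0.98
    - 5.69
- id: surgery_response
  label: Response to surgery
  cost_per_cycle: 0.0
  annual_utility: 0.58
  cost_uncertainty: 0.25
  utility_halfwidth: 0.15
  transitions:
  - to: surgery_response
    p: 85.8
  - to: surgical_complication
    p: '#'
  - to: chronic_pouchitis
    p: 11.7
- id: chronic_pouchitis
  label: Chronic pouchitis
  cost_per_cycle: 8144.0
  annual_utility: 0.32
  cost_uncertainty: 0.25
  utility_halfwidth: 0.31
  transitions:
  - to: pouch_ada_response
    series: pouchitis_exposed
    role: entry
  - to: chronic_pouchitis
    p: '#'
  - to: pouch_ada_complication
    p: 4.2
- id: surgical_complication
  label: Surgical complication
  cost_per_cycle: 17586.0
  annual_utility: 0.49
  cost_uncertainty: 0.25
  utility_halfwidth: 0.32
  transitions:
  - to: surgery_response
    p: 99.5
    ci:
    - 97.22
    - 99.99
  - to: death
    p: '#'
- id: ada_induction
  label: Adalimumab induction
  cost_per_cycle: 8144.0
  annual_utility: 0.32
  cost_uncertainty: 0.25
  utility_halfwidth: 0.31
  transitions:
  - to: ada_response
    p: 86.8
    ci:
    - 75.74
    - 97.86
  - to: ada_complication
    p: 3.04
  - to: unwell_steroids
    p: '#'
- id: ada_response
  label: Response to adalimumab
  cost_per_cycle: 7372.937167999999
  annual_utility: 0.79
  cost_uncertainty: 0.25
  utility_halfwidth: 0.21
  transitions:
  - to: ada_response
    series: dose_escalated
    role: stay
  - to: ada_complication
    p: 7.88
  - to: unwell_steroids
    p: '#'
- id: ada_complication
  label: Adalimumab complication
  cost_per_cycle: 12059.0
  annual_utility: 0.16
  cost_uncertainty: 0.25
  utility_halfwidth: 0.16
  transitions:
  - to: ada_response
    p: 70.0
  - to: unwell_steroids
    p: 14.0
  - to: surgery
    p: 14.0
  - to: death
    p: '#'
- id: pouch_ada_response
  label: Pouchitis response to adalimumab
  cost_per_cycle: 4442.0
  annual_utility: 0.58
  cost_uncertainty: 0.25
  utility_halfwidth: 0.15
  residence_clock: true
  transitions:
  - to: pouch_ada_response
    series: pouchitis_exposed
    role: stay
  - to: pouch_unwell
    p: '#'
  - to: pouch_ada_complication
    p: 4.2
- id: pouch_unwell
  label: Pouchitis unwell
  cost_per_cycle: 917.0
  annual_utility: 0.32
  cost_uncertainty: 0.25
  utility_halfwidth: 0.31
  transitions:
  - to: pouch_unwell
    p: '#'
  - to: pouch_surgery
    p: 10.0
  - to: pouch_steroid_complication
    p: 2.8
- id: pouch_ada_complication
  label: Pouchitis adalimumab complication
  cost_per_cycle: 12059.0
  annual_utility: 0.16
  cost_uncertainty: 0.25
  utility_halfwidth: 0.16
  transitions:
  - to: pouch_ada_response
    p: 51.0
  - to: pouch_unwell
    p: 23.5
  - to: pouch_surgery
    p: 23.5
  - to: death
    p: '#'
- id: pouch_surgery
  label: Pouch surgery (permanent ileostomy)
  cost_per_cycle: 37159.0
  annual_utility: 0.16
  cost_uncertainty: 0.25
  utility_halfwidth: 0.16
  transitions:
  - to: pouch_surgery_response
    p: '#'
  - to: pouch_surgical_complication
    p: 12.8
  - to: death
    p: 2.5
- id: pouch_steroid_complication
  label: Pouchitis steroid complication
  cost_per_cycle: 23919.0
  annual_utility: 0.16
  cost_uncertainty: 0.25
  utility_halfwidth: 0.16
  transitions:
  - to: pouch_surgery
    p: 98.0
  - to: death
    p: '#'
- id: pouch_surgery_response
  label: Response to pouch surgery
  cost_per_cycle: 0.0
  annual_utility: 0.44
  cost_uncertainty: 0.25
  utility_halfwidth: 0.11
  transitions:
  - to: pouch_surgery_response
    p: '#'
  - to: pouch_surgical_complication
    p: 2.5
- id: pouch_surgical_complication
  label: Pouch surgical complication
  cost_per_cycle: 17586.0
  annual_utility: 0.37
  cost_uncertainty: 0.25
  utility_halfwidth: 0.24
  transitions:
  - to: pouch_surgery_response
    p: '#'
  - to: death
    p: 0.5
- id: death
  label: Death
  cost_per_cycle: 0.0
  annual_utility: 0.0
  cost_uncertainty: 0.0
  utility_halfwidth: 0.0
  is_death: true
metadata:
  scenario: deescalation
  standard_response_cost: 4442.0
  escalated_response_cost: 8884.16
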