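# Comparator arm: adalimumab not available; corticosteroid-dependent cohort
# remains in a chronically unwell state, with colectomy and its sequelae as
# the only escape. All probabilities are percentages per 3-month cycle; "#"
# marks the row's complement entry. Costs are CA$ per cycle; utilities are
# annual weights with 95%-interval half-widths.
name: uc_no_ada
cycle_length_years: 0.25
annual_discount_rate: 0.05
horizon_cycles: 40
retention_mode: per_cycle
initial_distribution:
  unwell_steroids: 1.0
series:
  ada_maintenance:
    values: [86.8, 73.3, 66.5, 62.0, 58.7, 56.2, 54.1, 52.4, 50.9, 49.6, 48.5,
             47.5, 46.5, 45.7, 45.0, 44.3, 43.6, 43.0, 42.4, 41.9, 41.4]
  pouchitis_naive:
    values: [62.6, 61.2, 59.9, 58.6, 57.3, 56.1, 54.9, 53.7, 52.5, 51.4, 50.3,
             49.2, 48.1, 47.0, 46.0, 45.0, 44.0, 43.1, 42.1, 41.2, 40.2]
states:
  - id: ongoing_steroids
    label: Ongoing steroids
    cost_per_cycle: 917
    annual_utility: 0.32
    utility_halfwidth: 0.31
    transitions:
      - {to: steroid_response, p: 33.92, ci: [28.09, 40.33]}
      - {to: unwell_steroids, p: 57.11, ci: [50.5, 63.27]}
      - {to: steroid_complication, p: 2.80, ci: [0.56, 7.63]}
      - {to: surgery, p: "#"}
  - id: steroid_response
    label: Response to steroids
    cost_per_cycle: 0
    annual_utility: 0.79
    utility_halfwidth: 0.21
    transitions:
      - {to: steroid_response, p: 53.30, ci: [46.81, 59.67]}
      - {to: unwell_steroids, p: "#"}
  - id: unwell_steroids
    label: Unwell on steroids
    cost_per_cycle: 917
    annual_utility: 0.32
    utility_halfwidth: 0.31
    transitions:
      - {to: unwell_steroids, p: "#"}
      - {to: steroid_complication, p: 2.80, ci: [0.56, 7.63]}
      - {to: surgery, p: 10.00, ci: [6.40, 14.28]}
  - id: steroid_complication
    label: Steroid complication
    cost_per_cycle: 23919
    annual_utility: 0.16
    utility_halfwidth: 0.16
    transitions:
      - {to: surgery, p: 98.00, ci: [93.70, 99.78]}
      - {to: death, p: "#"}
  - id: surgery
    label: Surgery (colectomy)
    cost_per_cycle: 37159
    annual_utility: 0.16
    utility_halfwidth: 0.16
    transitions:
      - {to: surgery_response, p: "#"}
      - {to: surgical_complication, p: 12.8, ci: [8.76, 17.91]}
      - {to: death, p: 2.50, ci: [0.98, 5.69]}
  - id: surgery_response
    label: Response to surgery
    cost_per_cycle: 0
    annual_utility: 0.58
    utility_halfwidth: 0.15
    transitions:
      - {to: surgery_response, p: 85.80}
      - {to: surgical_complication, p: "#"}
      - {to: chronic_pouchitis, p: 11.70}
  - id: chronic_pouchitis
    label: Chronic pouchitis
    cost_per_cycle: 8144
    annual_utility: 0.32
    utility_halfwidth: 0.31
    transitions:
      - {to: pouch_ada_response, series: pouchitis_naive, role: entry}
      - {to: chronic_pouchitis, p: "#"}
      - {to: pouch_ada_complication, p: 4.20}
  - id: surgical_complication
    label: Surgical complication
    cost_per_cycle: 17586
    annual_utility: 0.49
    utility_halfwidth: 0.32
    transitions:
      - {to: surgery_response, p: 99.50, ci: [97.22, 99.99]}
      - {to: death, p: "#"}
  - id: ada_induction
    label: Adalimumab induction
    cost_per_cycle: 8144
    annual_utility: 0.32
    utility_halfwidth: 0.31
    transitions:
      - {to: ada_response, p: 86.80, ci: [75.74, 97.86]}
      - {to: ada_complication, p: 3.04}
      - {to: unwell_steroids, p: "#"}
  - id: ada_response
    label: Response to adalimumab
    cost_per_cycle: 4442
    annual_utility: 0.79
    utility_halfwidth: 0.21
    transitions:
      - {to: ada_response, series: ada_maintenance, role: stay}
      - {to: ada_complication, p: 7.88}
      - {to: unwell_steroids, p: "#"}
  - id: ada_complication
    label: Adalimumab complication
    cost_per_cycle: 12059
    annual_utility: 0.16
    utility_halfwidth: 0.16
    transitions:
      - {to: ada_response, p: 70.00}
      - {to: unwell_steroids, p: 14.00}
      - {to: surgery, p: 14.00}
      - {to: death, p: "#"}
  - id: pouch_ada_response
    label: Pouchitis response to adalimumab
    cost_per_cycle: 4442
    annual_utility: 0.58
    utility_halfwidth: 0.15
    residence_clock: true
    transitions:
      - {to: pouch_ada_response, series: pouchitis_naive, role: stay}
      - {to: pouch_unwell, p: "#"}
      - {to: pouch_ada_complication, p: 4.20}
  - id: pouch_unwell
    label: Pouchitis unwell
    cost_per_cycle: 917
    annual_utility: 0.32
    utility_halfwidth: 0.31
    transitions:
      - {to: pouch_unwell, p: "#"}
      - {to: pouch_surgery, p: 10.00}
      - {to: pouch_steroid_complication, p: 2.80}
  - id: pouch_ada_complication
    label: Pouchitis adalimumab complication
    cost_per_cycle: 12059
    annual_utility: 0.16
    utility_halfwidth: 0.16
    transitions:
      - {to: pouch_ada_response, p: 60.00}
      - {to: pouch_unwell, p: 19.00}
      - {to: pouch_surgery, p: 19.00}
      - {to: death, p: "#"}
  - id: pouch_surgery
    label: Pouch surgery (permanent ileostomy)
    cost_per_cycle: 37159
    annual_utility: 0.16
    utility_halfwidth: 0.16
    transitions:
      - {to: pouch_surgery_response, p: "#"}
      - {to: pouch_surgical_complication, p: 12.80}
      - {to: death, p: 2.50}
  - id: pouch_steroid_complication
    label: Pouchitis steroid complication
    cost_per_cycle: 23919
    annual_utility: 0.16
    utility_halfwidth: 0.16
    transitions:
      - {to: pouch_surgery, p: 98.00}
      - {to: death, p: "#"}
  - id: pouch_surgery_response
    label: Response to pouch surgery
    cost_per_cycle: 0
    annual_utility: 0.44
    utility_halfwidth: 0.11
    transitions:
      - {to: pouch_surgery_response, p: "#"}
      - {to: pouch_surgical_complication, p: 2.50}
  - id: pouch_surgical_complication
    label: Pouch surgical complication
    cost_per_cycle: 17586
    annual_utility: 0.37
    utility_halfwidth: 0.24
    transitions:
      - {to: pouch_surgery_response, p: "#"}
      - {to: death, p: 0.50}
  - id: death
    label: Death
    cost_per_cycle: 0
    annual_utility: 0.0
    cost_uncertainty: 0.0
    is_death: true
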