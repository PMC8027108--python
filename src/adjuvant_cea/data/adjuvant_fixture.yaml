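# Two-arm baseline configuration: adjuvant gefitinib vs vinorelbine+cisplatin
# for resected stage II-IIIA EGFR-mutant NSCLC, Chinese health-system
# perspective.  Costs are USD; survival curves are exponential fits
# calibrated to the trial's printed median DFS/OS (the original digitized
# Kaplan-Meier coordinates are not public).
schema_version: 1
wtp_usd_per_qaly: 30828.0
cycles:
  cycle_length_days: 21.0
  horizon_years: 10.0
discount:
  annual_rate: 0.03
patient:
  height_m: 1.64
  weight_kg: 65.0
  bsa_m2: 1.72
psa:
  n_iterations: 1000
  seed: 20210325
strategies:
  - name: gefitinib
    role: intervention
    survival:
      dfs: {median_months: 30.8, shape: 1.0}
      os: {median_months: 75.5, shape: 1.0}
    schedule:
      kind: oral
      unit_cost_usd: 23.33   # one 0.25 g tablet
      units_per_day: 1
      duration_months: 24.0
    followup_cost_usd: 55.60
    supportive_cost_usd: 337.50
    pd_entry_cost_usd: 1877.25
    ae_cost_usd: 507.40
    ae_incidence_g34: 0.12
    ae_disutility: 0.0731
    dfs_utility: 0.80        # oral therapy
    pd_utility: 0.70
  - name: chemotherapy
    role: comparator
    survival:
      dfs: {median_months: 19.8, shape: 1.0}
      os: {median_months: 62.8, shape: 1.0}
    schedule:
      kind: infusion
      n_regimen_cycles: 4
      interval_days: 21.0
      components:
        - {drug: vinorelbine, dose_mg_per_m2: 25.0, vial_mg: 10.0, vial_cost_usd: 8.16, administrations_per_cycle: 2}
        - {drug: cisplatin, dose_mg_per_m2: 75.0, vial_mg: 30.0, vial_cost_usd: 2.80, administrations_per_cycle: 1}
    followup_cost_usd: 55.60
    supportive_cost_usd: 337.50
    pd_entry_cost_usd: 1877.25
    ae_cost_usd: 507.40
    ae_incidence_g34: 0.48
    ae_disutility: 0.0731
    dfs_utility: 0.76        # intravenous therapy
    pd_utility: 0.70
metadata:
  exchange_rate_cny_per_usd: 6.8409
  trial: "phase 3 adjuvant trial, stage II-IIIA EGFR-mutant NSCLC, median follow-up 80 months"
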