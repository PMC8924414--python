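# Total population, second-line advanced/metastatic esophageal cancer
# (KEYNOTE-181). Monthly transition probabilities calibrated to the trial's
# published OS/PFS Kaplan-Meier curves.
schema_version: 1
subgroup: total
label: "Total population"
arms: [pembrolizumab, chemotherapy]
transitions:
  pembrolizumab: {pfs_pfs: 0.781, pfs_pd: 0.130, pfs_death: 0.089, pd_pd: 0.900, pd_death: 0.100}
  chemotherapy:  {pfs_pfs: 0.812, pfs_pd: 0.124, pfs_death: 0.064, pd_pd: 0.806, pd_death: 0.194}
# Per-month cost components (2021 US$, West China Hospital fee standards /
# published sources). PFS-state cost per cycle = drug + tests + ae;
# PD-state cost per cycle = subsequent_therapy.
costs:
  pembrolizumab: {drug: 7370.14, tests: 916.94, ae: 12.23, subsequent_therapy: 150.14}
  chemotherapy: {drug: 2231.66, tests: 727.18, ae: 131.79, subsequent_therapy: 150.14}
# Health-state utilities (per year of life), literature-derived.
utilities: {pfs: 0.75, pd: 0.67, death: 0.0}
model:
  cycle_length_months: 1
  horizon_cycles: 60            # 5-year horizon
  annual_discount_rate: 0.03
  discount_compounding: geometric   # monthly rate (1+r)^(1/12)-1; alternative: simple (r/12)
  half_cycle_correction: true
  wtp_usd_per_qaly: 11105.8     # 1x China 2020 GDP per capita
  cny_per_usd: 6.4831           # reporting metadata only; all amounts stored in USD
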