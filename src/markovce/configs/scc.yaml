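# Esophageal squamous cell carcinoma subgroup, second-line advanced/
# metastatic disease (KEYNOTE-181). Monthly transition probabilities
# calibrated to the trial's published OS/PFS curves.
schema_version: 1
subgroup: scc
label: "Squamous cell carcinoma"
arms: [pembrolizumab, chemotherapy]
transitions:
  pembrolizumab: {pfs_pfs: 0.812, pfs_pd: 0.106, pfs_death: 0.082, pd_pd: 0.911, pd_death: 0.089}
  chemotherapy:  {pfs_pfs: 0.803, pfs_pd: 0.122, pfs_death: 0.075, pd_pd: 0.832, pd_death: 0.168}
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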