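# Non-epithelioid subgroup configuration.
# Costs, utilities and AE inputs follow the whole population (the trial does
# not report them separately by histology); only the survival blocks differ.
# Costs in 2023 USD (converted at $1 = 7.0467 CNY); time in months; 21-day cycles.
population: non_epithelioid
wtp: 38042.49            # 3x China's 2023 per-capita GDP, USD/QALY
discount_rate: 0.05
horizon_years: 10.0
cycle_days: 21.0
curve_basis: cycle_months   # survival curves advance one month per cycle (see docs/methods.md)
half_cycle: false
exchange_rate_cny_per_usd: 7.0467
price_year: 2023
seed: 20230101

utilities:
  pfs: 0.706
  pd: 0.565

costs:                    # USD per cycle / per administration / per event
  pembrolizumab: 4654.66
  pemetrexed: 143.53
  cisplatin: 35.03
  nivolumab: 3279.69
  bevacizumab: 496.69
  gemcitabine: 153.21
  carboplatin: 43.94
  laboratory: 120.96
  ct: 268.88
  end_of_life: 1460.30
  premedication: 93.93
  infusion: 1.86
  secondary_premedication: 39.14

# printed ranges that depart from the +/-20% default
ranges:
  disutility_ae_anemia: [0.01, 0.14]

adverse_events:           # grade >=3 events with incidence > 5% in either arm
  fatigue:
    cost: 103.00
    disutility: 0.29
    incidence: {pembrolizumab_chemotherapy: 0.0676, chemotherapy: 0.0569}
  anemia:
    cost: 921.10
    disutility: 0.12
    incidence: {pembrolizumab_chemotherapy: 0.2387, chemotherapy: 0.1327}
  thrombocytopenia:
    cost: 1523.82
    disutility: 0.11
    incidence: {pembrolizumab_chemotherapy: 0.1081, chemotherapy: 0.0474}
  neutropenia:
    cost: 411.93
    disutility: 0.09
    incidence: {pembrolizumab_chemotherapy: 0.3198, chemotherapy: 0.1577}
  lipase_increase:
    cost: 44.30
    disutility: 0.47
    incidence: {pembrolizumab_chemotherapy: 0.0721, chemotherapy: 0.0237}
  hyperglycemia:
    cost: 361.91
    disutility: 0.20
    incidence: {pembrolizumab_chemotherapy: 0.0631, chemotherapy: 0.0427}

arms:
  pembrolizumab_chemotherapy:
    os_model:  {family: gengamma_prentice, params: {mu: 2.3140, sigma: 0.9550, Q: -0.8350}}
    pfs_model: {family: gengamma_prentice, params: {mu: 1.6226, sigma: 0.9186, Q: -0.9420}}
    drugs:
      # paid_cycles: cycles actually charged -- the assistance program
      # supplies pembrolizumab beyond the initial self-paid phase
      - {name: pembrolizumab, paid_cycles: 6}
      - {name: pemetrexed, paid_cycles: 6}
      - {name: cisplatin, paid_cycles: 6}
    chemo_cycles: 6
    antibody_cycles: 29     # cycles 7-35: pembrolizumab administration only
    subsequent:
      name: bevacizumab_gemcitabine_carboplatin
      components: [bevacizumab, gemcitabine, carboplatin]
      n_cycles: 6.040934     # whole-population calibrated value (shared by assumption)
      mode: one_time
  chemotherapy:
    os_model:  {family: lognormal, params: {meanlog: 2.114, sdlog: 0.9690}}
    pfs_model: {family: gamma, params: {shape: 2.1439, rate: 0.3955}}
    drugs:
      - {name: pemetrexed, paid_cycles: 6}
      - {name: cisplatin, paid_cycles: 6}
    chemo_cycles: 6
    antibody_cycles: 0
    subsequent:
      name: nivolumab
      components: [nivolumab]
      n_cycles: 6.314155     # whole-population calibrated value (shared by assumption)
      mode: one_time

psa:
  n_draws: 10000
  sd_rule: range95          # sd = (high - low) / (2 * 1.96)
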