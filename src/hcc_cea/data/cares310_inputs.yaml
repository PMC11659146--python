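# Default model inputs: first-line camrelizumab + rivoceranib vs sorafenib for
# advanced HCC in China (CARES-310 trial). All monetary values in 2024 USD
# (converted at 1 USD = 7.05 RMB upstream; the rate is metadata only).
# Each stochastic row carries: baseline value, deterministic-sensitivity range,
# and the PSA sampling distribution (gamma: shape/scale; beta: alpha/beta).

settings:
  cycle_length_months: 1.0
  horizon_cycles: 120            # 10-year horizon at monthly cycles
  annual_discount_rate: 0.03
  discount_rate_range: [0.0, 0.05]
  discount_rate_dist: {family: beta, p1: 5.5572, p2: 179.6828}
  wtp_thresholds:                # USD per QALY, regional thresholds for China
    low: 16426.80
    medium: 34319.01
    high: 81036.63
  half_cycle_correction: false
  days_per_cycle: 30.4375        # 365.25 / 12; 28.0 mirrors the 28-day regimen cycle
  subsequent_duration_cycles: null   # null = second-line therapy until death
  exchange_rate_rmb_per_usd: 7.05
  seed: 20240

costs:   # USD per unit (drugs) or per cycle / per episode (management)
  camrelizumab_200mg:
    value: 438.19
    range: [350.55, 525.83]
    dist: {family: gamma, p1: 99.9954, p2: 4.3821}
  rivoceranib_250mg:
    value: 15.67
    range: [12.53, 18.80]
    dist: {family: gamma, p1: 99.9362, p2: 0.1568}
  sorafenib_200mg:
    value: 13.36
    range: [10.69, 16.03]
    dist: {family: gamma, p1: 100.1499, p2: 0.1334}
  hypertension:
    value: 1.39
    range: [1.11, 1.67]
    dist: {family: gamma, p1: 98.5765, p2: 0.0141}
  palmar_plantar_erythrodysaesthesia:
    value: 17.13
    range: [13.70, 20.55]
    dist: {family: gamma, p1: 100.0584, p2: 0.1712}
  increased_ast:
    value: 181.85
    range: [145.48, 218.22]
    dist: {family: gamma, p1: 100.0, p2: 1.8185}
  increased_alt:
    value: 89.92
    range: [71.94, 107.90]
    dist: {family: gamma, p1: 100.0445, p2: 0.8988}
  decreased_platelet_count:
    value: 342.11
    range: [273.69, 410.54]
    dist: {family: gamma, p1: 99.9912, p2: 3.4214}
  subsequent_lenvatinib:
    value: 650.76
    range: [520.61, 780.92]
    dist: {family: gamma, p1: 99.9954, p2: 6.5079}
  subsequent_sintilimab_bevacizumab:
    value: 455.56
    range: [364.45, 546.67]
    dist: {family: gamma, p1: 100.0044, p2: 4.5554}
  follow_up:
    value: 60.98
    range: [48.78, 73.17]
    dist: {family: gamma, p1: 100.0164, p2: 0.6097}
  best_supportive_care:
    value: 367.71
    range: [294.17, 441.25]
    dist: {family: gamma, p1: 100.0054, p2: 3.6769}

utilities:
  progression_free:
    value: 0.76
    range: [0.61, 0.91]
    dist: {family: beta, p1: 23.8843, p2: 7.5424}
  progressed:
    value: 0.68
    range: [0.54, 0.82]
    dist: {family: beta, p1: 29.5176, p2: 13.8906}
  death:
    value: 0.0
    dist: {family: fixed}

disutilities:   # additive one-cycle QALY-weight decrements for grade 3/4 AEs
  hypertension:
    value: 0.016
    range: [0.013, 0.02]
    dist: {family: beta, p1: 82.2384, p2: 5057.6596}
  palmar_plantar_erythrodysaesthesia:
    value: 0.15
    range: [0.12, 0.18]
    dist: {family: beta, p1: 84.85, p2: 480.8167}
  decreased_platelet_count:
    value: 0.14
    range: [0.11, 0.17]
    dist: {family: beta, p1: 74.7756, p2: 459.3356}
  increased_ast:          # no published disutility; cost-only AE
    value: 0.0
    dist: {family: fixed}
  increased_alt:
    value: 0.0
    dist: {family: fixed}

strategies:
  combination:
    display_name: camrelizumab plus rivoceranib
    # log-logistic S(t) = 1 / (1 + lam * t^gamma), t in months
    os: {gamma: 1.516, lam: 0.008}
    pfs: {gamma: 1.916, lam: 0.036}
    p_subsequent_therapy: 0.33     # 90/272 progressors received second-line therapy
    subsequent_mix: {lenvatinib: 0.5, sintilimab_bevacizumab: 0.5}
    adverse_events:                # grade 3/4 events at >10% frequency
      hypertension:
        incidence: 0.38
        range: [0.30, 0.46]
        dist: {family: gamma, p1: 90.25, p2: 0.0042}
      increased_ast:
        incidence: 0.16
        range: [0.13, 0.19]
        dist: {family: gamma, p1: 113.7778, p2: 0.0014}
      increased_alt:
        incidence: 0.14
        range: [0.11, 0.17]
        dist: {family: gamma, p1: 87.1111, p2: 0.0016}
      decreased_platelet_count:
        incidence: 0.11
        range: [0.09, 0.13]
        dist: {family: gamma, p1: 121.0, p2: 0.0009}
      palmar_plantar_erythrodysaesthesia:
        incidence: 0.12
        range: [0.10, 0.14]
        dist: {family: gamma, p1: 144.0, p2: 0.0008}
  sorafenib:
    display_name: sorafenib
    os: {gamma: 1.675, lam: 0.010}
    pfs: {gamma: 2.277, lam: 0.063}
    p_subsequent_therapy: 0.48     # 130/269
    subsequent_mix: {lenvatinib: 0.5, sintilimab_bevacizumab: 0.5}
    adverse_events:
      hypertension:
        incidence: 0.15
        range: [0.12, 0.18]
        dist: {family: gamma, p1: 100.0, p2: 0.0015}
      increased_ast:
        incidence: 0.05
        range: [0.04, 0.06]
        dist: {family: gamma, p1: 100.0, p2: 0.0005}
      increased_alt:
        incidence: 0.03
        range: [0.02, 0.04]
        dist: {family: gamma, p1: 36.0, p2: 0.0008}
      decreased_platelet_count:
        incidence: 0.01
        range: [0.01, 0.01]      # printed as fixed; still sampled in PSA
        dist: {family: gamma, p1: 100.0, p2: 0.0001}
      palmar_plantar_erythrodysaesthesia:
        incidence: 0.15
        range: [0.12, 0.18]
        dist: {family: gamma, p1: 100.0, p2: 0.0015}
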