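# Base-case model configuration: Iranian primary-prevention cohort, age 35+,
# polypill versus its four component monotherapies (and valsartan).
# Probabilities and utilities carry Beta uncertainty, costs Gamma,
# relative effects log-normal; SMRs use Gamma (their means exceed 1, which
# the Beta family cannot represent).  Costs in USD, cycle length one year.

settings:
  start_age: 35
  max_age: 100
  discount_cost: 0.058
  discount_qaly: 0.03
  wtp: 21768.0
  cohort_size: 10000
  half_cycle_correction: true
  lognormal_convention: arithmetic   # printed effect = arithmetic mean
  cost_model: calibrated             # per_tablet_daily | per_pack_monthly | calibrated
  # Calibrated per-tablet-daily scale factor (calibration.calibrate_drug_cost_scale,
  # anchor: polypill lifetime total 871 USD).  The anchor lies below the arm's
  # state-cost floor, so the solve clamps at the zero lower bound.
  drug_cost_scale: 0.0
  polypill_variant: V
  male_fraction: 0.5
  risk_span_end: 85   # ranged risks/fatality reach their upper endpoint here

life_table:
  kind: gompertz
  target_life_expectancy: 42.0   # remaining years at age 35
  doubling_years: 8.0
  terminal_age: 100

baseline_risks:   # annual probability of a first event from the event-free state
  stroke: {mean: 0.005, sd: 0.003, dist: beta}
  hf:     {mean: 0.004, sd: 0.0023, dist: beta}
  mi:     {low: 0.011, high: 0.094, sd_low: 0.0091, sd_high: 0.087, dist: beta}
  angina: {low: 0.015, high: 0.133, sd_low: 0.012, sd_high: 0.113, dist: beta}
  pvd:    {low: 0.007, high: 0.062, sd_low: 0.004, sd_high: 0.054, dist: beta}

utilities:
  stroke:       {mean: 0.63, sd: 0.56, dist: beta}
  hf:           {mean: 0.68, sd: 0.49, dist: beta}
  acute_mi:     {mean: 0.76, sd: 0.65, dist: beta}
  post_mi:      {mean: 0.88, sd: 0.74, dist: beta}
  acute_angina: {mean: 0.77, sd: 0.65, dist: beta}
  post_angina:  {mean: 0.88, sd: 0.64, dist: beta}
  pvd:          {mean: 0.9, sd: 0.7, dist: beta}
  event_free:   {mean: 1.0, sd: 0.0, dist: fixed}

state_costs:    # USD per year in the state (acute states: the event year)
  stroke:       {mean: 1215.5, sd: 1350.0, dist: gamma}
  hf:           {mean: 419.9, sd: 351.8, dist: gamma}
  acute_mi:     {mean: 11461.6, sd: 8376.0, dist: gamma}
  acute_angina: {mean: 370.4, sd: 228.0, dist: gamma}
  pvd:          {mean: 261.94, sd: 183.0, dist: gamma}

cost_components:   # audit detail behind the averaged state costs
  acute_angina:
    cardiac_stress_test: 9.4
    electrocardiography: 13.6
    angiography: 299.1
    visit: 48.3
  acute_mi:
    direct: 259.7
    aspirin: 1.6
    tissue_plasminogen_activator: 11200.2
  hf:
    medications: 136.7
    inpatient: 128.9
    outpatient: 1.4
    hospitalization: 153.0

drug_prices:    # USD per pack of 10 tablets, by dose (mg)
  enalapril:
    "5":  {mean: 14.82, sd: 8.0, dist: gamma}
    "20": {mean: 24.68, sd: 10.0, dist: gamma}
  aspirin:
    "80":  {mean: 17.14, sd: 12.0, dist: gamma}
    "81":  {mean: 8.57, sd: 7.0, dist: gamma}
    "100": {mean: 19.71, sd: 14.0, dist: gamma}
  atorvastatin:
    "10": {mean: 14.57, sd: 9.0, dist: gamma}
    "20": {mean: 21.42, sd: 18.0, dist: gamma}
    "40": {mean: 28.28, sd: 20.0, dist: gamma}
  hydrochlorothiazide:
    "25": {mean: 12.42, sd: 8.0, dist: gamma}
    "50": {mean: 6.77, sd: 5.0, dist: gamma}
  polypill_e:
    "1": {mean: 50.71, sd: 43.0, dist: gamma}
  polypill_v:
    "1": {mean: 42.85, sd: 29.0, dist: gamma}

effects:    # relative effect on annual event risk, by arm and event
  polypill:
    stroke: {mean: 0.43, sd: 0.23, dist: lognormal, kind: HR}
    hf:     {mean: 0.83, sd: 0.54, dist: lognormal, kind: HR}
    angina: {mean: 0.77, sd: 0.65, dist: lognormal, kind: HR}
    mi:     {mean: 0.66, sd: 0.53, dist: lognormal, kind: HR}
  atorvastatin:
    stroke: {mean: 0.80, sd: 0.6, dist: lognormal, kind: RR}
    mi:     {mean: 0.72, sd: 0.53, dist: lognormal, kind: RR}
    hf:     {mean: 0.72, sd: 0.53, dist: lognormal, kind: RR}
    angina: {mean: 0.72, sd: 0.53, dist: lognormal, kind: RR}
    pvd:    {mean: 0.85, sd: 0.41, dist: lognormal, kind: RR}
  enalapril:
    stroke: {mean: 0.77, sd: 0.34, dist: lognormal, kind: RR}
    mi:     {mean: 0.72, sd: 0.45, dist: lognormal, kind: RR}
    angina: {mean: 0.74, sd: 0.48, dist: lognormal, kind: RR}
    hf:     {mean: 0.79, sd: 0.51, dist: lognormal, kind: HR}
  aspirin:
    hf:     {mean: 0.71, sd: 0.61, dist: lognormal, kind: RR}
    stroke: {mean: 0.76, sd: 0.67, dist: lognormal, kind: RR}
    mi:     {mean: 1.01, sd: 0.97, dist: lognormal, kind: RR}
    angina: {mean: 1.0, sd: 1.0, dist: lognormal, kind: RR}
    pvd:    {mean: 0.82, sd: 0.75, dist: lognormal, kind: RR}
  hydrochlorothiazide:
    mi:     {mean: 0.34, sd: 0.23, dist: lognormal, kind: HR}
    stroke: {mean: 0.73, sd: 0.64, dist: lognormal, kind: HR}
    angina: {mean: 0.71, sd: 0.63, dist: lognormal, kind: HR}
    hf:     {mean: 1.05, sd: 0.94, dist: lognormal, kind: HR}

mortality:
  fatal_stroke: {mean: 0.19, sd: 0.12, dist: beta}
  fatal_hf:     {mean: 0.17, sd: 0.09, dist: beta}
  fatal_mi:     # case fatality of an incident MI, age-ranged by sex
    male:   {low: 0.19, high: 0.36, sd_low: 0.14, sd_high: 0.29, dist: beta}
    female: {low: 0.23, high: 0.40, sd_low: 0.19, sd_high: 0.34, dist: beta}
  smr:          # excess all-cause mortality multipliers after an event
    stroke: {mean: 2.72, sd: 1.43, dist: gamma}
    mi:     {mean: 2.68, sd: 1.54, dist: gamma}
    hf:     {mean: 2.17, sd: 1.98, dist: gamma}
    angina: {mean: 2.19, sd: 2.0, dist: gamma}
    pvd:    {mean: 2.44, sd: 2.01, dist: gamma}
  disease_specific_death: {mean: 0.015, sd: 0.003, dist: beta}
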