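# Run configuration template.
#
# Every key shown here is optional except the units header, which must match
# the package-wide convention (time in days, concentrations in nmol/l,
# volumes in l, amounts in nmol) — any other declaration is rejected so that
# parameter sets in other unit systems are never silently misread.
# Unknown keys anywhere in the file are errors.

units:
  time: day
  concentration: nmol/l
  volume: l
  amount: nmol

# Adult TMDD micro-parameters.  Omitted keys fall back to the shipped
# reference set, whose provenance is logged at load time: R0 (= ksyn/kdeg),
# Vmax (= kint*R0) and Km (= (koff+kint)/kon) are anchored to published
# values; kel, kdeg, kon, v1, v2 and q are surrogate defaults in the typical
# monoclonal-antibody range.  Users holding the original adult disposition
# set for the source antibody should enter it here.
parameters:
  kel: 0.08928571428571429    # 1/day (CL_linear 0.25 l/day over V1)
  kon: 20.0                   # 1/(nmol/l)/day
  koff: 3.69                  # 1/day
  kint: 4.37                  # 1/day
  ksyn: 3.48                  # nmol/l/day
  kdeg: 2.0                   # 1/day
  v1: 2.8                     # l
  v2: 2.8                     # l
  q: 0.6                      # l/day

# Allometric scaling policy (adult reference 70 kg, plasma volume 2.8 l).
scaling:
  cl_exponent: 0.75
  v_exponent: 1.0
  reference_bw: 70.0
  reference_plasma_volume: 2.8

# Scenario grid axes.  Doses are mg/kg (per_kg) and mg (fixed); target
# sensitivity levels are concentrations (nmol/l) for the same-concentration
# policy and amounts (nmol) for the same-amount policy, in fourfold steps.
scenario:
  ages: [2y, 6y, 12y, 18y]
  per_kg_doses: [0.5, 1.0, 2.0, 3.0, 4.5]
  fixed_doses: [35.0, 70.0, 140.0, 210.0, 315.0]
  target_concentrations: [6.96, 1.74, 0.44, 0.11, 0.027, 0.0068, 0.0017]
  target_amounts: [19.5, 4.87, 1.23, 0.31, 0.076, 0.019, 0.005]
  target_policies: [same_concentration, same_amount]
  dose_policies: [per_kg, fixed]
  model_kinds: [tmdd, mm]
  molecular_weight: 150000.0
  occupancy_threshold: 0.9

# Synthetic-data generation (virtual cohorts and noisy observations).
synthetic:
  seed: 0
  cohort_sizes: {2y: 20, 6y: 20, 12y: 20, 18y: 20}
  bw_cv: 0.15       # lognormal body-weight CV around the age-group mean
  obs_cv: 0.10      # proportional observation-error CV
  schedule: [0.25, 0.5, 1.0, 2.0, 4.0, 7.0, 14.0, 21.0, 28.0, 42.0, 56.0, 84.0]

output_dir: pedtmdd_output
log_level: INFO
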