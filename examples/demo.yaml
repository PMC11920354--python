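# Desk-scale demo pipeline: simulate a small hexaploid population, build a
# Beta-Binomial-scaled G, estimate variance components, predict GEBV and
# validate by forward prediction. Completes in well under five minutes.
seed: 11
simulation:
  n_mothers: 80
  n_markers: 400
  n_families: 8
  n_repeat_samples: 6
  n_years: 6
  trials_per_year: 3
  n_locations: 2
  progeny_per_mother: 2
  records_per_progeny: 2
  V_M: [[15085.7]]
  V_C: [[79075.3]]
  V_E: [[482725.8]]
  trait_names: [yield_cut1]
filters:
  maf: 0.05
  min_depth: 10
  max_depth: 200
  call_rate: 0.7
grm:
  method: betabinomial
  ploidy: 6
model:
  mode: multi
variance_components:
  source: em_reml
  tol: 1.0e-4
  max_iter: 60
validation:
  strategy: forward
  cutoff_year: 2005
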