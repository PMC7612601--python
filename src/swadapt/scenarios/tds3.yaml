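# Closed-cohort SW-CRT modeled on a school self-esteem program: C=12 clusters,
# four switching in each of periods 2-4, m=10 individuals measured every
# period.  The conventional design attains 80% power at delta=2 with
# one-sided alpha=0.025.
name: TDS3
design:
  clusters: 12
  periods: 4
  m: 10
  cohort: closed_cohort
  allocation: "0111,0111,0111,0111,0011,0011,0011,0011,0001,0001,0001,0001"
  interim_periods: [2]
  alpha: 0.025
  beta: 0.2
  delta: 2.0
variance:
  sigma2_c: 7.425
  sigma2_pi: 0.825
  sigma2_s: 11.725
  sigma2_e: 5.025
policy:
  w: 0.5
  eta: 0.0
  gamma: 2.5
  restriction: none
simulation:
  theta: 2.0
  n_reps: 10000
  seed: 1
  analysis_mode: collapsed
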