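# Cross-sectional SW-CRT with C=20 clusters over P=9 periods: three clusters
# switch in each of periods 2-5 and two in each of periods 6-9.  Variance
# components give a larger intra-cluster correlation; m=7 attains 80% power
# at delta=0.24 with one-sided alpha=0.05 under the Hussey-Hughes calculation.
name: TDS1
design:
  clusters: 20
  periods: 9
  m: 7
  cohort: cross_sectional
  allocation: "011111111,011111111,011111111,001111111,001111111,001111111,000111111,000111111,000111111,000011111,000011111,000011111,000001111,000001111,000000111,000000111,000000011,000000011,000000001,000000001"
  interim_periods: [3, 6]
  alpha: 0.05
  beta: 0.2
  delta: 0.24
variance:
  sigma2_c: 0.1111111111111111
  sigma2_pi: 0.0
  sigma2_s: 0.0
  sigma2_e: 1.0
policy:
  w: 0.5
  eta: 0.0
  gamma: 2.5
  restriction: none
simulation:
  theta: 0.24
  n_reps: 10000
  seed: 1
  analysis_mode: collapsed
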