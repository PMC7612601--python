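# Cross-sectional SW-CRT modeled on a four-cluster maternity-care training
# trial: one cluster switches per period over P=5 periods.  m=70 attains 90%
# power at delta=0.2 with one-sided alpha=0.05.
name: TDS2
design:
  clusters: 4
  periods: 5
  m: 70
  cohort: cross_sectional
  allocation: "01111,00111,00011,00001"
  interim_periods: [3]
  alpha: 0.05
  beta: 0.1
  delta: 0.2
variance:
  sigma2_c: 0.02
  sigma2_pi: 0.0
  sigma2_s: 0.0
  sigma2_e: 0.51
policy:
  w: 0.5
  eta: 0.0
  gamma: 2.5
  restriction: none
simulation:
  theta: 0.2
  n_reps: 10000
  seed: 1
  analysis_mode: collapsed
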