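# Desk-scale demonstration run: simulate a 2,000-gene world with the
# default covariate/DFE structure, then run every analysis stage on it.
stages: [simulate, fit, correlate, bgc, go-analysis]

simulate:
  n_genes: 2000
  n_go_categories: 8
  go_membership_mean: 1.5
  vip_fraction: 0.2          # enough VIP genes per category at this scale

fit:
  bootstrap: 0               # set to 100 for percentile CIs

correlate:
  factors: [rec_rate, age, expression, length]
  bins: 10                   # fewer, better-populated bins at 2,000 genes

go_analysis:
  min_genes: 50
  shuffles: 50
  balance_sites: 50000

fit_options:
  n_starts: 5
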