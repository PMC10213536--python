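# Full analysis run: synthetic survey -> tie indices -> care-choice models -> SIRS
seed: 2018
out_dir: results/full_run
log_level: INFO
stages: [generate, indices, fit, sirs]

generator:
  n: 20000
  missing_rate: 0.0

models:
  batteries: [baseline, robustness, heterogeneity, mechanism]

sirs:
  alpha: 1.0    # tie-strength (social contact) rate
  beta: 0.2     # adoption rate I -> R
  lam: 0.3      # abandonment rate R -> S
  delta: 0.1    # reversion rate I -> S
  N: 1.0
  alpha_grid: {start: 0.35, stop: 2.0, num: 34}
  init: {S: 0.98, I: 0.02, R: 0.0}
  t_end: 400.0
  dt: 0.01
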