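# Published component-model parameters for Delia antiqua.
#
# sdt:   summer-diapause termination (Phase I) — Lactin rate curve fitted to
#        1/P50 vs temperature, and the Weibull distribution of completion
#        time over normalized time.
# pupal: non-diapausing pupal development (Phase II) — Lactin rate curve
#        fitted to 1/development-days, and the Weibull distribution of
#        development time over physiological age.
sdt:
  lactin:
    rho: 0.16978
    t_max: 22.13802
    delta_t: 5.67016
  weibull:
    alpha: 1.15460
    beta: 1.71717
pupal:
  lactin:
    rho: 0.151932200
    t_max: 37.88922166
    delta_t: 6.572996371
  weibull:
    alpha: 1.121146325
    beta: 3.155020615
degree_days:
  # common lower threshold: mean of the stage-specific lower thresholds,
  # rounded to one decimal
  t_cb: 3.9
  lower_thresholds: [3.1, 3.8, 4.3, 4.0, 4.4]
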