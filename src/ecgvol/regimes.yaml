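# Default synthetic regimes. Volatility dynamics are EGARCH; "apnea_like"
# carries stronger volatility persistence and shock loading than
# "normal_like". Innovation scale is ~1 uV so the integrated baseline
# wander stays small against the ~1 mV beats (heavy tails require the
# spikes to dominate the marginal, as in real ECG).
# "homoskedastic_control" zeroes every dynamic (pure i.i.d. Gaussian
# amplitudes) and exists for test calibration, not realism.
apnea_like:
  label: apnea
  mean:
    d: 1
    ar: [0.5, -0.2]
    ma: [0.3]
  egarch:
    alpha0: -0.69078              # (1 - beta) * log(0.001^2)
    theta: [-0.15]
    lam: [0.35]
    beta: [0.95]
  beats:
    rate_hz: 1.1
    amplitude_mv: 1.0
    width_s: 0.025
    jitter_s: 0.05
normal_like:
  label: normal
  mean:
    d: 1
    ar: [0.5, -0.2]
    ma: [0.3]
  egarch:
    alpha0: -2.76311              # (1 - beta) * log(0.001^2)
    theta: [-0.05]
    lam: [0.15]
    beta: [0.80]
  beats:
    rate_hz: 1.0
    amplitude_mv: 1.0
    width_s: 0.025
    jitter_s: 0.03
homoskedastic_control:
  label: unknown
  mean:
    d: 0
    ar: []
    ma: []
  egarch:
    alpha0: -6.43775              # log(0.04^2): constant variance
    theta: [0.0]
    lam: [0.0]
    beta: [0.0]
  beats: null
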