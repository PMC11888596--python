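# Healthy-lifestyle criteria (primary analysis) and the one-factor-at-a-time
# alternative criteria used by the sensitivity suite.
primary:
  healthy_smoking_levels: [never]
  alcohol_max_freq: 1.0          # healthy iff drinking occasions/week < this
  diet_quantile: 0.5             # healthy iff aMED >= this population quantile
  healthy_exercise_levels: [1-2_per_week, 3-5_per_week, daily]
  sleep_range: [7.0, 8.0]        # closed interval, hours/night
alternatives:
  smoking:
    healthy_smoking_levels: [never, former]
  alcohol:
    alcohol_max_freq: 3.0
  diet:
    diet_quantile: 0.6
  exercise:
    healthy_exercise_levels: [3-5_per_week, daily]
  sleep:
    sleep_range: [6.0, 9.0]
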