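hi_threshold: 0.5
lo_threshold: -0.1
rules:
- phenotype: proliferating
  high:
  - Ki-67
  low: []
  priority: 0
  hi_override: null
  lo_override: null
- phenotype: transition
  high:
  - CD69
  - TIM3
  low: []
  priority: 1
  hi_override: null
  lo_override: null
- phenotype: active
  high:
  - CD69
  low:
  - TIM3
  - LAG3
  priority: 2
  hi_override: null
  lo_override: 0.3
- phenotype: exhausted
  high:
  - TIM3
  low:
  - CD69
  - OX40
  priority: 3
  hi_override: null
  lo_override: 0.3
- phenotype: exhausted
  high:
  - LAG3
  low:
  - CD69
  - OX40
  priority: 4
  hi_override: null
  lo_override: 0.3
- phenotype: anergic
  high: []
  low:
  - CD69
  - OX40
  - LAG3
  - TIM3
  - Ki-67
  priority: 5
  hi_override: null
  lo_override: 0.25
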