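# top-down, high diversity; angina; LCN and sensory stressed, alive
network:
  connectedness: top_down
  diversity: high
pathology:
  mode: angina
  lcn_affected: true
  derangement: false
run:
  label: fig07
  description: top-down, high diversity; angina; LCN and sensory stressed, alive
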