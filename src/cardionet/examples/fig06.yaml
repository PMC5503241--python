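# top-down, low diversity; angina; LCN and sensory stressed, alive
network:
  connectedness: top_down
  diversity: low
pathology:
  mode: angina
  lcn_affected: true
  derangement: false
run:
  label: fig06
  description: top-down, low diversity; angina; LCN and sensory stressed, alive
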