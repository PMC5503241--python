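# stratified, low diversity; angina; LCN and sensory stressed, alive
network:
  connectedness: stratified
  diversity: low
pathology:
  mode: angina
  lcn_affected: true
  derangement: false
run:
  label: fig04
  description: stratified, low diversity; angina; LCN and sensory stressed, alive
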