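# stratified, low diversity; infarction; LCN and sensory die
network:
  connectedness: stratified
  diversity: low
pathology:
  mode: infarction
  lcn_affected: true
  derangement: false
run:
  label: fig10
  description: stratified, low diversity; infarction; LCN and sensory die
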