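# stratified, high diversity; infarction; LCN and sensory die; autonomic derangement
network:
  connectedness: stratified
  diversity: high
pathology:
  mode: infarction
  lcn_affected: true
  derangement: true
run:
  label: fig13
  description: stratified, high diversity; infarction; LCN and sensory die; autonomic
    derangement
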