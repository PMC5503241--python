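# stratified, high diversity; infarction; LCN unaffected, sensory die
network:
  connectedness: stratified
  diversity: high
pathology:
  mode: infarction
  lcn_affected: false
  derangement: false
run:
  label: fig12
  description: stratified, high diversity; infarction; LCN unaffected, sensory die
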