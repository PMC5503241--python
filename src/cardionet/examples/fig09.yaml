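# stratified, high diversity; angina; LCN unaffected, sensory stressed; autonomic derangement
network:
  connectedness: stratified
  diversity: high
pathology:
  mode: angina
  lcn_affected: false
  derangement: true
run:
  label: fig09
  description: stratified, high diversity; angina; LCN unaffected, sensory stressed;
    autonomic derangement
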