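# miniature three-level network for fast tests
network:
  lcn_per_level: 10
  parasym_pool_size: 10
  out_degree: 4
run:
  label: toy
  description: miniature network for fast tests
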